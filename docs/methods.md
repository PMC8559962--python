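# Methods

## Karyotype model

The male *D. melanogaster* karyotype is encoded as five chromosome types
(chr2, chr3, chr4 as homolog pairs; X and Y single-copy). The fluorescence
model assigns one relative intensity unit to every chromatid centromere and
two units to each chrY chromatid centromere. Whether the twofold chrY
weight is exact or an empirical average cannot be decided from intensity
data alone; the default is exactly 2.0 and the weight is configurable on
`ChromosomeSpec` for sensitivity analyses. In G2 every chromosome carries
two chromatids, so the full complement is 16 centromere units totalling 18
intensity units, 32 telomere ends, and the four canonical bivalent clusters
carry 4, 4, 4 and 6 units (sex bivalent : autosome bivalent = 1.5).

Pole-ratio classes of the random-segregation null are unordered
(5:3 ≡ 3:5). The analytic mode enumerates all `2^n` assignments in closed
form via binomial coefficients and is capped at `n = 30`
(2^30 ≈ 10^9 outcome weightings are still exact through the binomial form;
the cap guards against meaningless astronomically small class
probabilities); beyond the cap only Monte-Carlo is offered.

## Synthetic movies

The generator emulates single-nucleus two-channel acquisitions:
46 focal planes at 0.5 µm and 45 s intervals for meiosis-I movies,
29 planes at 0.8 µm for territory-formation movies (presets
`acquisition_m1`, `acquisition_territory`). Lateral pixel size defaults to
0.25 µm (60x objective on a 16-µm-pixel EMCCD). A rendered dot is an
anisotropic Gaussian with σ = (0.6, 0.2, 0.2) µm (z, y, x): the lateral
FWHM of ≈ 0.47 µm represents the ~0.5 µm apparent size of a centromeric
dot (object extent convolved with the PSF), with the axial extent three
times wider. The voxel sum of a rendered dot equals
`intensity_units × photons_per_unit × bleach_factor`, conserved to < 1%
(4σ rendering box), so integrated-intensity estimators can be validated
absolutely. Bleaching is exponential per frame; noise is Poisson (on
signal + baseline) plus Gaussian read noise, applied after rendering.
`configure_snr` rescales the photon budget so the dimmest dot class
reaches a requested peak-SNR, where SNR is peak signal over the total
noise SD at the peak (read noise plus shot noise of baseline + signal).

Motion is anchored confined diffusion: a discrete Ornstein–Uhlenbeck
update with reversion 0.1 per frame toward the anchor, isotropic Gaussian
steps calibrated so the mean per-interval displacement equals
`mean_speed × frame_interval` (E|N(0, σ²I₃)| = σ·2√(2/π)), and a hard
confinement radius (default 0.5 µm). An optional two-state switch produces
transient faster phases; its parameters are free choices, not measured
values. Cluster anchors repel each other below 1.4 µm, emulating the
separation of chromosome territories — this is what keeps distinct
clusters in distinct subnuclear regions, and it is also what makes
frame-to-frame identity preservation achievable at realistic sampling.
Whole-scene drift is linear at a configurable µm/frame vector and is
applied to the nucleus and all dots alike.

The de-clustering event grammar is a fixed split order taking the dot
count 1 → 8. Cluster intensities follow the karyotype (all = 18, Aa = Ab =
4, XY4 = 10 units, …). The two observed variants move the first release
from the XY4 cluster earlier: before the Ab split (`variant_four_dot`) or
before the Aa split (`variant_three_dot`). The two ~4-unit products
released from the XY4 cluster (the Y sister pair and the chr4 bivalent)
are not distinguishable by intensity; the schedule seed decides which
label carries the terminal chr4 split. Split products spawn 1 µm apart
with anchors 2 µm apart: splitting dots visibly jump apart within a frame
or two, which matches how split events become countable in real movies.

Condensin II mutant mode suppresses splits: each split of a dot that
exists becomes a stretch episode — the dot is rendered as two half-
intensity sub-dots separating along a fixed random axis with a triangular
elongation profile (default maximum 2 µm, configurable up to 4.8 µm) —
with an optional rare definitive split. Overexpression mode renders four
resolved satellite dots from frame 0. Anaphase mode moves one univalent
per chromosome toward one of two poles: intact bivalents (or all bivalents
when the random-null flag is off) send their two univalents to opposite
poles; with the random flag each univalent of a disrupted bivalent flips
an independent fair coin.

All randomness flows from a single seed through three spawned substreams
(schedule, motion, noise); identical seeds give bit-identical movies.

## Detection and segmentation choices

The LoG scale follows the standard blob relation σ = d/(2√2); the axial
diameter defaults to twice the lateral one. The quality threshold is
auto-calibrated per frame as median + k·(1.4826·MAD) of the response with
k = 5.5, fixed by a calibration run on noise-only and SNR-5 frames
(k = 5 admitted ≈ 0.3 false maxima per frame; 5.5 keeps single-spot recall
at 0.99 with 0.07 false positives per frame). A relative floor of 10% of
the peak response suppresses rendering ripples on noise-free frames where
the MAD vanishes. Subpixel positions use a response-weighted centroid over
a ±2σ window, which is markedly more stable than per-axis quadratic
interpolation along the coarsely sampled z axis; quadratic interpolation
remains the fallback at image borders. Intensities are integrated over an
anisotropic sphere (lateral radius = the estimated diameter, axial radius
= the axial diameter) with the median of a surrounding shell subtracted
per voxel, making measured intensities proportional to true dot units.

Nuclear segmentation thresholds the smoothed diffuse channel by Otsu and
then refines the threshold to the half-maximum between the eroded-core
median and the background median; for a soft-edged nucleus this places the
surface at the half-intensity radius, where plain Otsu systematically
bleeds outward (the refinement brings the equivalent-diameter error from
≈ +7% to ≈ 1%). The boundary stage value d = 9.0 µm is assigned to the
S3/S4 bin. Radial position is exposed both as the raw distance to the
periphery and as the normalized fraction (0 centre, 1 periphery), since
published "radial positions" do not fix a normalization.

## Tracking and event calling

Per frame, active tracks predict `last + memory × last displacement`
(memory default 0.8) and candidates are assigned by optimal bipartite
matching on Euclidean costs gated at `max_step`; ties resolve by the
deterministic within-frame detection order (sorted by position), making
linking invariant to input order. Tracks bridge up to `max_gap` missing
frames. Drift correction subtracts the nucleus-centroid displacement
relative to frame 0, interpolating missing centroids with a warning.

A split is associated by finding, near a newly opened track, an existing
track whose intensity drops by a commensurate amount; intensities are
averaged over a three-frame window on each side because a splitting dot
sheds its product gradually while the pair is still unresolved, and the
partition fraction uses the same windows. Unassociated new tracks are kept
and used by the program classifier as orphan events. Fusions are the time
reverse. Events with several near-equal parents are flagged ambiguous
rather than silently assigned.

The de-clustering program call deliberately does not trust the lineage
tree topology (an occasional wrong parent association would corrupt it).
Instead every called split and every orphan track start is typed by the
intensity of the product in karyotype units (units estimated from the
root cluster = 18): a 1.2–3 unit product is a sister-split candidate, a
3–8 unit product appearing while at least three dots exist is an
XY4-release candidate. Candidates within 3 frames collapse to one event
(the two products of one split can resolve on different frames), and
sister candidates on a release frame are dropped (a release reshuffles the
linking). The first two sister splits are the Aa and Ab splits in every
program, so the label follows from where the first release falls: after
the Ab split (or never observed) = canonical, between the Aa and Ab splits
= variant_four_dot, before the Aa split = variant_three_dot; anything
incomplete is `other` with a note. Identity maps (Aa/Ab/XY4/…) are still
assigned by the lineage walk where the tree is consistent, with the
"released-Y-or-4" label for XY4 products, matching the fact that ambiguous
identities should not be guessed.

Pole inference for segregation calls projects final-frame positions on
their principal axis and runs deterministic 2-means initialized at the
projection extremes; explicit anchors override. Units equidistant from
both poles within the localization SD are excluded with a warning. The
goodness-of-fit report combines the chi-square statistic with a seeded
Monte-Carlo exact multinomial p value (fraction of null cohorts with a
statistic at least as large, with add-one smoothing).

## Metrics conventions

Stage intervals are maximal constant-count runs; a run touching the window
edge is censored and its duration is a minimal duration. Count dips
shorter than 2 frames flanked by equal higher counts are bridged before
run-length encoding (transient fusions reduce counts only transiently);
the debounce is configurable and recorded in output metadata. A run of n
frames has duration n × interval. Pair separations encode 0 on frames
where only one of the two signals was detected — zero is reserved for this
encoding; frames with neither signal are missing values and are never
imputed. Stretch episodes are maximal runs with separation ≥ 1 µm (the
two-spot detectability scale at the 1 µm satellite-dot diameter) lasting
≥ 3 frames; the outcome is `definitive_split` if the separation never
returns to 0 before the end of observation. Group comparisons default to
the classical pooled-variance Student t test (two-tailed, stars at
0.05/0.01/0.001); Welch is available by flag.

## Problem sizes and what the tests show

The test suite and the bundled pipeline demo run on movies of 12–65 frames
at 16–29 z-planes × 48–96² voxels with nucleus radius 3.5 µm — the full
acquisition geometry at a reduced field of view, chosen so the suite
completes quickly on one CPU. Identity preservation and program
classification are exercised at 5 s sampling (the regime in which dot
tracking is meaningful: at 10-minute sampling a 0.03 µm/s dot fully
re-randomizes inside its confinement between frames); stage-duration
recovery is exercised at 10-minute sampling where only counts matter.
Program-classification accuracy is measured over 3 noise-free and 12
SNR-5 seeded simulations.

The simulator reproduces the countable structure of the real data (cluster
intensities, event order, confinement-scale motion, drift, noise and
bleaching) but not nuclear growth, chromosome-arm structure, Y-loops,
nucleoli, multi-nucleus cysts, or optical sectioning physics beyond a
Gaussian PSF. Passing recovery tests therefore demonstrates estimator
correctness under the modelled imaging physics, not performance on every
real-data pathology (e.g. overlapping nuclei or strong uneven background).

## Known limitations

* Split calling depends on an intensity-commensurability gate; in crowded
  late stages (7–8 dots in a 3.5 µm nucleus) associations are occasionally
  missed or mis-assigned, which the program classifier tolerates but the
  identity map reports as unassociated branches.
* Censored stage durations are flagged, not modelled; no survival analysis
  is attempted.
* The detector's quality score is the band-pass response at the maximum
  and is not claimed to match any commercial tool's proprietary score.
* Manual track editing is supported only as a deterministic batch edits
  file (add/delete spot, cut/join), not interactively.
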
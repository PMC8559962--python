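"""Nuclear segmentation, diameter staging and distance-to-periphery geometry.

The diffuse nuclear channel (His2Av-mRFP or nucleoplasmic TALE-light signal)
is smoothed and thresholded (Otsu) to produce a per-frame nuclear mask; the
equivalent-sphere diameter serves as the developmental-stage proxy.  An
exact anisotropic Euclidean distance transform supplies the shortest
distance from any interior point to the nuclear periphery, from which
normalized radial positions (0 = centre, 1 = periphery) are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import SegmentationError

__all__ = [
    "NucleusModel",
    "StageLabel",
    "segment_nucleus",
    "distance_to_periphery",
    "stage_from_diameter",
    "radial_position",
]

# staging bins (um): d < 9 -> S1_2; 9 <= d <= 12 -> S3_4; d > 12 -> later.
# 9.0 um exactly is assigned to the upper bin.
STAGE_BOUNDS = {"S1_2": (0.0, 9.0), "S3_4": (9.0, 12.0), "later": (12.0, np.inf)}


@dataclass
class StageLabel:
    label: str
    bounds_um: tuple

    def __str__(self):
        return self.label


@dataclass
class NucleusModel:
    """Segmented nucleus of one frame."""

    mask: np.ndarray           # boolean (z, y, x)
    spacing: np.ndarray        # (dz, dy, dx) um
    centroid_um: np.ndarray    # (z, y, x) um
    equivalent_diameter_um: float
    _dist: np.ndarray | None = field(default=None, repr=False)
    _dist_out: np.ndarray | None = field(default=None, repr=False)

    @property
    def radius_um(self) -> float:
        return self.equivalent_diameter_um / 2.0

    def distance_field(self) -> np.ndarray:
        """Exact anisotropic EDT of the mask (um to the nearest boundary)."""
        if self._dist is None:
            self._dist = ndimage.distance_transform_edt(
                self.mask, sampling=self.spacing)
        return self._dist

    def _outside_field(self) -> np.ndarray:
        if self._dist_out is None:
            self._dist_out = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.spacing)
        return self._dist_out


def segment_nucleus(frame, spacing, smoothing_sigma_um: float = 0.5) -> NucleusModel:
    """Segment the nucleus from one 3D diffuse-channel frame.

    Gaussian smoothing (sigma in um, converted per axis), Otsu threshold,
    largest connected component, hole filling.  Raises
    :class:`SegmentationError` on constant frames or empty foreground.
    """
    img = np.asarray(frame, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if img.max() == img.min():
        raise SegmentationError("constant frame: nothing to segment")
    sig = smoothing_sigma_um / spacing
    smooth = ndimage.gaussian_filter(img, sigma=sig)
    thr = threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any():
        raise SegmentationError("no foreground voxels after thresholding")
    # refine to the half-maximum surface: estimate the interior plateau from
    # the eroded core (the soft edge slopes well into the foreground, so the
    # plain foreground median - and Otsu - bleed into the background) and
    # re-threshold midway between plateau and background
    erosion_um = 0.8
    for _ in range(2):
        iters = max(1, int(round(erosion_um / float(spacing.min()))))
        core = ndimage.binary_erosion(fg, iterations=iters)
        if not core.any():
            break
        plateau = np.median(smooth[core])
        bg_med = np.median(smooth[~fg])
        new_thr = bg_med + 0.5 * (plateau - bg_med)
        new_fg = smooth > new_thr
        if not new_fg.any():
            break
        fg = new_fg
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    voxel_volume = float(np.prod(spacing))
    volume = fg.sum() * voxel_volume
    diameter = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    centroid_vox = np.asarray(ndimage.center_of_mass(fg))
    return NucleusModel(
        mask=fg, spacing=spacing,
        centroid_um=centroid_vox * spacing,
        equivalent_diameter_um=float(diameter),
    )


def distance_to_periphery(point_um, nucleus: NucleusModel) -> float:
    """Shortest distance (um) from a point to the nuclear boundary.

    Positive inside the mask, negative outside (signed distance).  The
    interior EDT is sampled by trilinear interpolation at the physical
    coordinates of the point.
    """
    pt_vox = np.asarray(point_um, dtype=float) / nucleus.spacing
    inside = ndimage.map_coordinates(
        nucleus.mask.astype(np.uint8), pt_vox[:, None], order=0,
        mode="constant")[0] > 0
    if inside:
        val = ndimage.map_coordinates(
            nucleus.distance_field(), pt_vox[:, None], order=1,
            mode="nearest")[0]
        return float(val)
    val = ndimage.map_coordinates(
        nucleus._outside_field(), pt_vox[:, None], order=1, mode="nearest")[0]
    return -float(val)


def stage_from_diameter(d_um: float) -> StageLabel:
    """Developmental stage from the nuclear diameter proxy."""
    if d_um <= 0:
        raise ValueError("diameter must be positive")
    if d_um < 9.0:
        label = "S1_2"
    elif d_um <= 12.0:
        label = "S3_4"
    else:
        label = "later"
    return StageLabel(label, STAGE_BOUNDS[label])


def radial_position(distance_to_periphery_um: float, radius_um: float) -> float:
    """Normalized radial position: 0 at the centre, 1 at the periphery."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    frac = (radius_um - distance_to_periphery_um) / radius_um
    if distance_to_periphery_um < 0 or distance_to_periphery_um > radius_um:
        warnings.warn(
            f"distance {distance_to_periphery_um} outside [0, radius]; "
            "radial position clamped")
        frac = float(np.clip(frac, 0.0, 1.0))
    return float(frac)
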
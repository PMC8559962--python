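"""Ground-truth comparison utilities.

Helpers to score estimator output against simulator truth: detection
recall/precision by position matching, tracking identity preservation, and
conversions from :class:`~chromotrace.simulate.GroundTruth` to the track and
lineage structures the classifiers consume.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .classify import LineageNode, lineage_from_events
from .tracking import Track

__all__ = ["match_detections", "detection_scores", "tracks_from_truth",
           "lineage_from_truth", "lineage_from_tracks",
           "identity_preservation"]


def match_detections(truth_positions, detected_positions, tolerance_um):
    """One-to-one matching of detections to true positions within a tolerance.

    Returns (pairs, unmatched_truth, unmatched_detections); pairs are
    (truth_index, detection_index).
    """
    t = np.asarray(truth_positions, dtype=float).reshape(-1, 3)
    d = np.asarray(detected_positions, dtype=float).reshape(-1, 3)
    if len(t) == 0 or len(d) == 0:
        return [], list(range(len(t))), list(range(len(d)))
    cost = np.linalg.norm(t[:, None, :] - d[None, :, :], axis=2)
    BIG = 1e6
    gated = np.where(cost <= tolerance_um, cost, BIG)
    rows, cols = linear_sum_assignment(gated)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if gated[i, j] < BIG]
    mt = sorted(set(range(len(t))) - {i for i, _ in pairs})
    md = sorted(set(range(len(d))) - {j for _, j in pairs})
    return pairs, mt, md


def detection_scores(truth_positions, detected_positions, tolerance_um):
    """Recall and precision of a detection set against truth."""
    pairs, mt, md = match_detections(truth_positions, detected_positions,
                                     tolerance_um)
    n_t = len(pairs) + len(mt)
    n_d = len(pairs) + len(md)
    recall = len(pairs) / n_t if n_t else 1.0
    precision = len(pairs) / n_d if n_d else 1.0
    return recall, precision


def tracks_from_truth(gt) -> list[Track]:
    """One Track per true dot id, in the nucleus frame (already drift-free)."""
    tracks = []
    for i, (dot_id, grp) in enumerate(sorted(gt.dots.groupby("dot_id"))):
        grp = grp.sort_values("frame")
        tr = Track(track_id=i)
        tr.label = dot_id  # truth label kept for scoring
        tr.frames = [int(f) for f in grp["frame"]]
        tr.positions_um = [np.array(p) for p in
                           grp[["z_um", "y_um", "x_um"]].to_numpy()]
        tr.corrected_um = [p.copy() for p in tr.positions_um]
        tr.intensities = [float(v) for v in grp["intensity_units"]]
        tr.qualities = [np.nan] * len(tr.frames)
        tracks.append(tr)
    return tracks


def lineage_from_truth(gt) -> dict[str, LineageNode]:
    """Lineage tree of the true dots, for classifier oracle checks."""
    node_info = {}
    for dot_id, grp in gt.dots.groupby("dot_id"):
        node_info[dot_id] = (int(grp["frame"].min()), int(grp["frame"].max()),
                             float(grp["intensity_units"].mean()))
    events = []
    for _, row in gt.events.iterrows():
        if row["kind"] == "split":
            events.append((int(row["frame"]), row["parent"],
                           row["child1"], row["child2"]))
    return lineage_from_events(node_info, events)


def lineage_from_tracks(tracks, split_events, min_track_length: int = 3,
                        early_window: int = 6) -> dict[str, LineageNode]:
    """Build a lineage tree from tracker output and called split events.

    A parent track continues through its own splits, so each track is cut
    into segments at the frames where it splits; every segment becomes one
    lineage node.  A node's intensity is the mean over the first
    ``early_window`` frames of its segment: right after the event it still
    reflects the product's own brightness, whereas a whole-segment mean is
    contaminated when a later split of that dot went uncalled.  Tracks not
    involved in any event and shorter than ``min_track_length`` frames
    (typically noise detections) are dropped.
    """
    splits_by_parent: dict[int, list] = {}
    involved = set()
    for ev in sorted(split_events, key=lambda e: (e.frame, e.child1_id)):
        splits_by_parent.setdefault(ev.parent_id, []).append(ev)
        involved.update((ev.parent_id, ev.child1_id, ev.child2_id))
    tracks = [tr for tr in tracks
              if tr.track_id in involved or len(tr) >= min_track_length]

    by_id = {tr.track_id: tr for tr in tracks}

    def segments(tr):
        cut_frames = [ev.frame for ev in splits_by_parent.get(tr.track_id, [])]
        segs, start = [], 0
        for cf in cut_frames:
            i = next((k for k, f in enumerate(tr.frames) if f >= cf),
                     len(tr.frames))
            if i > start:
                segs.append((start, i))
            start = i
        if start < len(tr.frames):
            segs.append((start, len(tr.frames)))
        return segs

    node_info, seg_index = {}, {}
    for tr in tracks:
        for k, (i, j) in enumerate(segments(tr)):
            nid = f"t{tr.track_id}.{k}"
            inten = float(np.mean(tr.intensities[i:min(j, i + early_window)]))
            node_info[nid] = (tr.frames[i], tr.frames[j - 1], inten)
            seg_index.setdefault(tr.track_id, []).append((tr.frames[i], nid))

    def node_at(track_id, frame):
        segs = seg_index.get(track_id, [])
        best = None
        for start, nid in segs:
            if start <= frame:
                best = nid
        return best if best is not None else (segs[0][1] if segs else None)

    events = []
    for ev in sorted(split_events, key=lambda e: (e.frame, e.child1_id)):
        parent_node = node_at(ev.parent_id, ev.frame - 1)
        c_new = node_at(ev.child1_id, ev.frame)
        c_cont = node_at(ev.parent_id, ev.frame)
        if parent_node and c_new and c_cont and parent_node != c_cont:
            events.append((ev.frame, parent_node, c_new, c_cont))
    return lineage_from_events(node_info, events)


def identity_preservation(tracks, gt, tolerance_um=0.5) -> float:
    """Fraction of within-track identity transitions consistent with lineage.

    Each tracked point is matched to the nearest true dot of its frame
    (within the tolerance; frames where the second-nearest true dot also
    lies within the tolerance are ambiguous and skipped).  A transition
    between consecutive matched labels is legitimate when the labels are
    identical or related by ancestry in the true lineage (a track correctly
    follows a cluster through its splits); any other transition is an
    identity switch.  Returns 1 - switches / transitions, pooled over tracks.
    """
    truth_by_frame = {
        int(f): (grp["dot_id"].to_list(),
                 grp[["z_um", "y_um", "x_um"]].to_numpy())
        for f, grp in gt.dots.groupby("frame")}
    parent_of = {}
    for _, row in gt.events.iterrows():
        if row["kind"] == "split":
            parent_of[row["child1"]] = row["parent"]
            parent_of[row["child2"]] = row["parent"]

    def ancestors(lab):
        out = {lab}
        while lab in parent_of:
            lab = parent_of[lab]
            out.add(lab)
        return out

    def related(a, b):
        return a in ancestors(b) or b in ancestors(a)

    transitions = switches = 0
    for tr in tracks:
        labels = []
        for f, p in zip(tr.frames, tr.positions(corrected=True)):
            if f not in truth_by_frame:
                continue
            ids, pos = truth_by_frame[f]
            d = np.linalg.norm(pos - np.asarray(p), axis=1)
            order = np.argsort(d)
            if d[order[0]] > tolerance_um:
                continue
            if len(order) > 1 and d[order[1]] <= tolerance_um:
                continue  # ambiguous frame: two truths within tolerance
            labels.append(ids[order[0]])
        for a, b in zip(labels, labels[1:]):
            transitions += 1
            if a != b and not related(a, b):
                switches += 1
    return 1.0 - switches / transitions if transitions else 0.0
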
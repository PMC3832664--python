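"""Pipeline-vs-ground-truth validation metrics for simulated movies.

These helpers compare the segmentation/tracking/classification output with
the simulator's exported truth (label movie + TruthCell records): per-nucleus
IoU, track purity, division recovery and cell-type agreement.
"""

from __future__ import annotations

import numpy as np

from .movie import LabelMovie4D
from .params import CellType
from .quantify import biological_cells
from .simulate import BYSTANDER_ID_START, TruthCell
from .track import LineageTree, Track

__all__ = [
    "truth_id_of_observation",
    "track_truth_id",
    "track_purity",
    "segmentation_iou",
    "division_recovery",
    "classification_agreement",
]


def truth_id_of_observation(obs, truth: LabelMovie4D) -> int:
    """Ground-truth cell id under an observation's centroid (majority over a
    3×3×3 neighbourhood when the centre voxel is background)."""
    cal = truth.calibration
    x, y, z = obs.centroid
    zi = int(z / cal.voxel_z)
    yi = int(y / cal.voxel_xy)
    xi = int(x / cal.voxel_xy)
    lab = truth.data[obs.frame]
    nz, ny, nx = lab.shape
    zi, yi, xi = min(max(zi, 0), nz - 1), min(max(yi, 0), ny - 1), min(max(xi, 0), nx - 1)
    v = int(lab[zi, yi, xi])
    if v:
        return v
    nb = lab[max(0, zi - 1): zi + 2, max(0, yi - 1): yi + 2, max(0, xi - 1): xi + 2]
    vals, counts = np.unique(nb[nb > 0], return_counts=True)
    return int(vals[counts.argmax()]) if len(vals) else 0


def track_truth_id(track: Track, truth: LabelMovie4D) -> int:
    ids = [truth_id_of_observation(o, truth) for o in track.observations]
    ids = [i for i in ids if i > 0]
    if not ids:
        return 0
    vals, counts = np.unique(ids, return_counts=True)
    return int(vals[counts.argmax()])


def track_purity(tracks: list[Track], truth: LabelMovie4D) -> float:
    """Fraction of observations whose ground-truth id matches their track's
    majority ground-truth id."""
    good = total = 0
    for tr in tracks:
        ids = [truth_id_of_observation(o, truth) for o in tr.observations]
        known = [i for i in ids if i > 0]
        if not known:
            continue
        vals, counts = np.unique(known, return_counts=True)
        majority = int(vals[counts.argmax()])
        good += sum(1 for i in known if i == majority)
        total += len(known)
    return good / total if total else float("nan")


def segmentation_iou(seg: LabelMovie4D, truth: LabelMovie4D, frame: int) -> dict[int, float]:
    """Per-truth-object IoU with its best-overlapping segmented object."""
    s = seg.data[frame]
    t = truth.data[frame]
    out: dict[int, float] = {}
    for tid in np.unique(t[t > 0]):
        tmask = t == tid
        overlap_labels, counts = np.unique(s[tmask], return_counts=True)
        fg = overlap_labels > 0
        if not fg.any():
            out[int(tid)] = 0.0
            continue
        best = overlap_labels[fg][counts[fg].argmax()]
        inter = int(((s == best) & tmask).sum())
        union = int(((s == best) | tmask).sum())
        out[int(tid)] = inter / union
    return out


def division_recovery(
    tree: LineageTree,
    truth_cells: list[TruthCell],
    truth_labels: LabelMovie4D,
    n_frames: int,
    frame_tolerance: int = 2,
    margin_frames: int = 5,
) -> float:
    """Fraction of true division events recovered with the correct parent.

    A true event (cell P disperses at time t, daughters appear before the
    movie ends) is recovered when some detected division has a NEBD frame
    within ``frame_tolerance`` of t and its parent track maps to P (majority
    ground-truth id). Events within ``margin_frames`` of the movie end are
    unobservable and excluded.
    """
    interval = truth_labels.calibration.frame_interval
    truth_events = []
    for c in truth_cells:
        if c.cell_id >= BYSTANDER_ID_START:
            continue
        for t in c.nebd_times:
            f = int(np.ceil(t / interval))
            if f <= n_frames - margin_frames:
                truth_events.append((c.cell_id, f))
    detected = []
    for tid, tr in tree.tracks.items():
        if tr.nebd_frame is not None and tr.daughter_ids is not None:
            detected.append((track_truth_id(tr, truth_labels), tr.nebd_frame))
    hit = 0
    for pid, f in truth_events:
        if any(dp == pid and abs(df - f) <= frame_tolerance for dp, df in detected):
            hit += 1
    return hit / len(truth_events) if truth_events else float("nan")


def classification_agreement(
    tree: LineageTree,
    truth_cells: list[TruthCell],
    truth_labels: LabelMovie4D,
) -> float:
    """Fraction of lineage biological cells whose assigned type matches the
    ground-truth type of their majority ground-truth cell."""
    truth_type = {c.cell_id: c.cell_type for c in truth_cells}
    good = total = 0
    for cell in biological_cells(tree):
        first_track = tree.tracks[cell.track_ids[0]]
        tid = track_truth_id(first_track, truth_labels)
        if tid == 0 or tid >= BYSTANDER_ID_START or tid not in truth_type:
            continue
        total += 1
        if cell.cell_type is CellType(truth_type[tid]):
            good += 1
    return good / total if total else float("nan")
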
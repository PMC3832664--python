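"""Lineage statistics: cycle lengths, windowed representative volumes, growth
folds and speeds, lineage census, and the nuclear-vs-cell diameter check.

Definitions (all converted to minutes / µm³ via the frame interval and voxel
calibration):

* cycle length — time between two consecutive NEBDs of a renewing cell; a
  newborn cell's first cycle runs from the parental NEBD that created it to
  its own first NEBD.
* representative volume — NB: mean over the 9 min (3 frames) preceding its
  NEBD; INP: mean over minutes 39–45 (frames +13..+15) after first
  detection; GMC: minutes 9–15 (frames +3..+5) after first detection;
  neuron: mean over its final 3 observed frames.
* growth fold — (pre-division 9-min window mean) / (post-birth 9-min window
  mean), so growing cells give folds > 1.
* growth speed — window-mean difference divided by the time between the two
  window centres, µm³/min.

Frames beyond the analysis horizon (default 200) are excluded from every
statistic.

Because tracking assigns a fresh track id to a renewed NB/INP after each
division, statistics operate on *biological cells*: chains of tracks linked
through the larger, type-preserving daughter at each division.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .movie import LabelMovie4D, Movie4D
from .params import CellType, QuantConfig
from .track import LineageTree, _order_by_size

__all__ = [
    "BioCell",
    "biological_cells",
    "cycle_records",
    "growth_records",
    "rep_volume_records",
    "metrics_table",
    "summarize",
    "census",
    "census_table",
    "diameter_ratio_check",
    "equivalent_diameter",
]


def equivalent_diameter(volume: float) -> float:
    """Diameter (µm) of the sphere with the given volume (µm³)."""
    return 2.0 * (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class BioCell:
    """A biological cell: one or more tracks chained through renewals."""

    cell_id: int                      # id of the first track of the chain
    cell_type: CellType
    track_ids: list[int]
    first_frame: int
    parent_nebd_frame: int | None     # NEBD of the mitosis that created it
    cycles: list[tuple[int, int | None]]  # (first observed frame, NEBD frame) per track
    volume_series: dict[int, float]
    terminal_daughter_start: int | None = None  # first frame of daughters after a terminal division
    flags: list[str] = field(default_factory=list)

    @property
    def nebd_frames(self) -> list[int]:
        return [n for _, n in self.cycles if n is not None]


def biological_cells(tree: LineageTree) -> list[BioCell]:
    """Chain tracks into biological cells using the renewal rule: at each
    division the larger daughter continues the parent when it has the same
    proliferative type (NB or INP)."""
    cont: dict[int, int] = {}
    for tid in tree.nodes():
        tr = tree.tracks[tid]
        if tr.daughter_ids is None:
            continue
        t = tree.cell_type(tid)
        if t not in (CellType.NB, CellType.INP):
            continue
        big, _small = _order_by_size(tree, *tr.daughter_ids)
        if tree.cell_type(big) == t:
            cont[tid] = big
    continued = set(cont.values())

    cells: list[BioCell] = []
    for tid in tree.nodes():
        if tid in continued:
            continue
        chain = [tid]
        while chain[-1] in cont:
            chain.append(cont[chain[-1]])
        first = tree.tracks[tid]
        parent_nebd = None
        if first.parent_id is not None:
            parent_nebd = tree.tracks[first.parent_id].nebd_frame
        vol: dict[int, float] = {}
        cycles: list[tuple[int, int | None]] = []
        for t_id in chain:
            tr = tree.tracks[t_id]
            vol.update(tr.volume_series())
            cycles.append((tr.first_frame, tr.nebd_frame))
        last = tree.tracks[chain[-1]]
        term_start = None
        if last.daughter_ids is not None:  # terminal division (e.g. GMC -> neurons)
            term_start = min(tree.tracks[d].first_frame for d in last.daughter_ids)
        cells.append(
            BioCell(
                cell_id=tid,
                cell_type=tree.cell_type(tid),
                track_ids=chain,
                first_frame=first.first_frame,
                parent_nebd_frame=parent_nebd,
                cycles=cycles,
                volume_series=vol,
                terminal_daughter_start=term_start,
            )
        )
    return cells


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------


def _window_mean(series: dict[int, float], frames: range) -> float | None:
    vals = [series[f] for f in frames if f in series]
    if not vals:
        return None
    return float(np.mean(vals))


def _pre_nebd_window(cell: BioCell, nebd: int, config: QuantConfig) -> float | None:
    w = config.window_frames(config.nb_premitosis_window)
    return _window_mean(cell.volume_series, range(nebd - w, nebd))


def _post_birth_window(cell: BioCell, start: int, config: QuantConfig) -> float | None:
    w = config.window_frames(config.postmitosis_window)
    return _window_mean(cell.volume_series, range(start, start + w))


def _detection_window(cell: BioCell, window: tuple[float, float], config: QuantConfig) -> float | None:
    f0 = cell.first_frame
    a = int(round(window[0] / config.frame_interval))
    b = int(round(window[1] / config.frame_interval))
    return _window_mean(cell.volume_series, range(f0 + a, f0 + b + 1))


# --------------------------------------------------------------------------
# per-cycle / per-cell records
# --------------------------------------------------------------------------


def cycle_records(tree: LineageTree, config: QuantConfig) -> pd.DataFrame:
    """One row per measured cell cycle: (cell_id, cell_type, kind, cycle_min)
    with kind 'first' (parent NEBD → own first NEBD) or 'renewal'
    (consecutive own NEBDs)."""
    horizon = config.analysis_horizon_frames
    rows = []
    for cell in biological_cells(tree):
        events: list[tuple[int, str]] = []
        if cell.parent_nebd_frame is not None:
            events.append((cell.parent_nebd_frame, "birth"))
        for n in cell.nebd_frames:
            events.append((n, "nebd"))
        events.sort()
        for (f0, k0), (f1, k1) in zip(events, events[1:]):
            if k1 != "nebd" or f1 > horizon:
                continue
            kind = "first" if k0 == "birth" else "renewal"
            rows.append(
                (cell.cell_id, cell.cell_type.value, kind, (f1 - f0) * config.frame_interval)
            )
    return pd.DataFrame(rows, columns=["cell_id", "cell_type", "kind", "cycle_min"])


def growth_records(tree: LineageTree, config: QuantConfig) -> pd.DataFrame:
    """One row per cycle with both 9-min windows available: growth fold and
    growth speed. Cycles whose birth mitosis was not observed (the root's
    first cycle) contribute nothing."""
    horizon = config.analysis_horizon_frames
    wpre = config.window_frames(config.nb_premitosis_window)
    wpost = config.window_frames(config.postmitosis_window)
    rows = []
    for cell in biological_cells(tree):
        birth_known = cell.parent_nebd_frame is not None
        for i, (start, nebd) in enumerate(cell.cycles):
            if nebd is None or nebd > horizon:
                continue
            if i == 0 and not birth_known:
                continue
            if nebd - start < wpre + wpost:  # windows would overlap
                continue
            pre = _pre_nebd_window(cell, nebd, config)
            post = _post_birth_window(cell, start, config)
            if pre is None or post is None or post <= 0:
                continue
            # time between window centres
            dt = ((nebd - 1) - (wpre - 1) / 2.0 - (start + (wpost - 1) / 2.0)) * config.frame_interval
            speed = (pre - post) / dt if dt > 0 else np.nan
            rows.append((cell.cell_id, cell.cell_type.value, i, pre / post, speed, pre, post))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "cell_type", "cycle_index", "growth_fold",
                 "growth_speed_um3_min", "pre_mean_um3", "post_mean_um3"],
    )


def rep_volume_records(tree: LineageTree, config: QuantConfig) -> pd.DataFrame:
    """One row per cell: the type-specific representative volume.

    NB (and any renewing cell measured at mitosis): mean of the per-NEBD
    pre-mitosis windows; INP/GMC: the post-detection window; neuron: final 3
    observed frames."""
    horizon = config.analysis_horizon_frames
    rows = []
    for cell in biological_cells(tree):
        t = cell.cell_type
        vol: float | None = None
        flagged = False
        if t is CellType.NB:
            vols = [
                v for n in cell.nebd_frames if n <= horizon
                for v in [_pre_nebd_window(cell, n, config)] if v is not None
            ]
            vol = float(np.mean(vols)) if vols else None
        elif t is CellType.INP:
            vol = _detection_window(cell, config.inp_window, config)
        elif t is CellType.GMC:
            vol = _detection_window(cell, config.gmc_window, config)
        elif t is CellType.NEURON:
            frames = sorted(f for f in cell.volume_series if f <= horizon)
            if frames:
                vol = float(np.mean([cell.volume_series[f] for f in frames[-3:]]))
        if vol is None:
            flagged = True
        rows.append((cell.cell_id, t.value, vol, flagged))
    return pd.DataFrame(
        rows, columns=["cell_id", "cell_type", "rep_volume_um3", "window_clipped"]
    )


def metrics_table(tree: LineageTree, config: QuantConfig) -> pd.DataFrame:
    """Per-cell summary combining cycles, representative volume and growth."""
    cyc = cycle_records(tree, config)
    grw = growth_records(tree, config)
    rep = rep_volume_records(tree, config)
    cyc_mean = cyc.groupby("cell_id")["cycle_min"].mean()
    fold_mean = grw.groupby("cell_id")["growth_fold"].mean()
    speed_mean = grw.groupby("cell_id")["growth_speed_um3_min"].mean()
    out = rep[["cell_id", "cell_type", "rep_volume_um3"]].copy()
    out["cycle_min"] = out["cell_id"].map(cyc_mean)
    out["growth_fold"] = out["cell_id"].map(fold_mean)
    out["growth_speed_um3_min"] = out["cell_id"].map(speed_mean)
    return out[
        ["cell_id", "cell_type", "cycle_min", "rep_volume_um3",
         "growth_fold", "growth_speed_um3_min"]
    ]


def summarize(metrics: pd.DataFrame, grouping: list[str] | None = None) -> pd.DataFrame:
    """Long-format mean/sd/n per group for every numeric metric column."""
    grouping = grouping or ["cell_type"]
    value_cols = [
        c for c in metrics.columns
        if c not in grouping + ["cell_id"] and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    rows = []
    for keys, grp in metrics.groupby(grouping, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        name = "/".join(str(k) for k in keys)
        for col in value_cols:
            vals = grp[col].dropna()
            rows.append(
                (name, col,
                 float(vals.mean()) if len(vals) else np.nan,
                 float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                 int(len(vals)))
            )
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "sd", "n"])


# --------------------------------------------------------------------------
# census
# --------------------------------------------------------------------------


def census(tree: LineageTree, at_frame: int, n_frames: int) -> int:
    """Cells of the main lineage alive at ``at_frame``: born and not yet
    divided-with-daughters; a cell in its NEBD dispersal gap still counts."""
    if not (0 <= at_frame < n_frames):
        raise ValueError(f"frame {at_frame} outside movie of {n_frames} frames")
    main = set(tree.main_tree_nodes())
    count = 0
    for cell in biological_cells(tree):
        if cell.cell_id not in main:
            continue
        if cell.first_frame > at_frame:
            continue
        if cell.terminal_daughter_start is not None and at_frame >= cell.terminal_daughter_start:
            continue
        count += 1
    return count


def census_table(tree: LineageTree, n_frames: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"frame": range(n_frames),
         "cells_alive": [census(tree, f, n_frames) for f in range(n_frames)]}
    )


# --------------------------------------------------------------------------
# nuclear vs cell diameter (dispersed-signal) check
# --------------------------------------------------------------------------


def _measure_dispersed(
    movie: Movie4D,
    labels: LabelMovie4D,
    frame: int,
    center_um: np.ndarray,
    roi_half_um: float = 8.0,
) -> float | None:
    """Volume (µm³) of the dispersed-GFP cell object at a permissive (Otsu)
    threshold inside a ROI around the vanished nucleus, with segmented
    interphase nuclei masked out. Returns None when undetectable."""
    if not (0 <= frame < movie.n_frames):
        return None
    cal = movie.calibration
    img = movie.data[frame]
    lab = labels.data[frame]
    nz, ny, nx = img.shape
    cx, cy, cz = center_um
    zc = int(cz / cal.voxel_z)
    yc = int(cy / cal.voxel_xy)
    xc = int(cx / cal.voxel_xy)
    hz = max(2, int(round(roi_half_um / cal.voxel_z)))
    hxy = max(2, int(round(roi_half_um / cal.voxel_xy)))
    sl = (
        slice(max(0, zc - hz), min(nz, zc + hz + 1)),
        slice(max(0, yc - hxy), min(ny, yc + hxy + 1)),
        slice(max(0, xc - hxy), min(nx, xc + hxy + 1)),
    )
    # light smoothing suppresses shot-noise specks before the permissive
    # threshold; segmented nuclei are masked out with a margin covering
    # their PSF halo
    roi_img = ndimage.gaussian_filter(
        img[sl].astype(np.float32),
        (0.5 / cal.voxel_z, 0.5 / cal.voxel_xy, 0.5 / cal.voxel_xy),
    )
    occupied = ndimage.binary_dilation(lab[sl] > 0, iterations=3)
    free = ~occupied
    vals = roi_img[free]
    if vals.size < 32 or np.ptp(vals) == 0:
        return None
    thr = threshold_otsu(vals)
    mask = free & (roi_img > thr)
    cc, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return None
    # component nearest the ROI centre
    zc_l, yc_l, xc_l = zc - sl[0].start, yc - sl[1].start, xc - sl[2].start
    best, best_d = None, np.inf
    for i in range(1, n + 1):
        zz, yy, xx = np.nonzero(cc == i)
        d = float(np.hypot(np.hypot((zz.mean() - zc_l) * cal.voxel_z,
                                    (yy.mean() - yc_l) * cal.voxel_xy),
                           (xx.mean() - xc_l) * cal.voxel_xy))
        if d < best_d:
            best, best_d = i, d
    count = int((cc == best).sum())
    vol = count * cal.voxel_volume
    return vol if vol > 0 else None


def diameter_ratio_check(
    tree: LineageTree,
    movie: Movie4D,
    labels: LabelMovie4D,
    config: QuantConfig,
) -> pd.DataFrame:
    """Per NB division, compare the NB/daughter size ratio computed from
    nuclear equivalent diameters with the one computed from whole-cell
    diameters measured on the dispersed signal right after NEBD.

    A pair requires both the NB's and the daughter's dispersal objects to be
    measurable (the daughter must itself divide within the movie); pairs
    where either is undetectable are skipped."""
    cells = {c.cell_id: c for c in biological_cells(tree)}
    rep = rep_volume_records(tree, config).set_index("cell_id")["rep_volume_um3"]
    rows = []
    for cell in cells.values():
        if cell.cell_type is not CellType.NB:
            continue
        for start, nebd in cell.cycles:
            if nebd is None or nebd > config.analysis_horizon_frames:
                continue
            track_id = next(
                (tid for tid in cell.track_ids
                 if tree.tracks[tid].nebd_frame == nebd), None)
            if track_id is None or tree.tracks[track_id].daughter_ids is None:
                continue
            big, small = _order_by_size(tree, *tree.tracks[track_id].daughter_ids)
            daughter = next((c for c in cells.values() if c.cell_id == small), None)
            if daughter is None or not daughter.nebd_frames:
                continue
            nb_pre = _pre_nebd_window(cell, nebd, config)
            d_rep = rep.get(small)
            if nb_pre is None or d_rep is None or not np.isfinite(d_rep):
                continue
            nb_cell_vol = _measure_dispersed(
                movie, labels, nebd, tree.tracks[track_id].last_centroid
            )
            d_nebd = daughter.nebd_frames[0]
            d_track = next(
                tree.tracks[tid] for tid in daughter.track_ids
                if tree.tracks[tid].nebd_frame == d_nebd
            )
            d_cell_vol = _measure_dispersed(
                movie, labels, d_nebd, d_track.last_centroid
            )
            if nb_cell_vol is None or d_cell_vol is None:
                continue
            nuclear_ratio = equivalent_diameter(nb_pre) / equivalent_diameter(d_rep)
            cell_ratio = equivalent_diameter(nb_cell_vol) / equivalent_diameter(d_cell_vol)
            rows.append((cell.cell_id, small, nebd, nuclear_ratio, cell_ratio))
    return pd.DataFrame(
        rows, columns=["nb_id", "daughter_id", "nebd_frame", "nuclear_ratio", "cell_ratio"]
    )
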
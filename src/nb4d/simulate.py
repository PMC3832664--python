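"""Ground-truth neuroblast lineage simulation and 4D movie rendering.

The generator has two stages. :func:`simulate_lineage` runs an event-driven
simulation of a single neuroblast lineage (type I or type II) and returns
:class:`TruthCell` records with exact birth times, nuclear-envelope-breakdown
(NEBD) times and piecewise-linear nuclear volume trajectories.
:func:`render_movie` voxelizes those cells into a calibrated intensity movie —
spheroidal nuclei, NEBD intervals rendered as dim cell-sized dispersed signal,
anisotropic Gaussian PSF, Poisson photon noise and Gaussian read noise — plus a
noise-free ground-truth label movie for testing the downstream pipeline.

Randomness uses one root seed split into independent substreams for lineage
timing, cell motion and camera noise, so imaging noise can be switched off
without changing the lineage.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .movie import Calibration, LabelMovie4D, Movie4D
from .params import CellType, ImagingParams, LineageMode, LineageParams, ParamError

__all__ = [
    "TruthCell",
    "simulate_lineage",
    "make_bystanders",
    "render_movie",
    "write_truth_tables",
    "read_truth_tables",
    "sphere_radius",
]

BYSTANDER_ID_START = 9001
_PLACEMENT_GAP = 0.6   # µm clearance demanded between nuclear surfaces
_WALL_MARGIN = 0.5     # µm kept between a nucleus and the field boundary


class RenderError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


def sphere_radius(volume: float) -> float:
    """Radius (µm) of a sphere of the given volume (µm³)."""
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class TruthCell:
    """One simulated cell: lineage bookkeeping plus its volume trajectory.

    A self-renewing cell (NB, INP) is a single TruthCell with one NEBD time
    per division; its volume trajectory is one linear segment per cycle.
    ``volume_segments`` are half-open intervals ``(t0, t1, v0, v1)``; between
    a NEBD and NEBD + ``dispersal_min`` there is no segment — the nucleus does
    not exist and the signal is dispersed through the cell.
    """

    cell_id: int
    parent_id: int | None
    cell_type: CellType
    birth_time: float                       # min
    nebd_times: list[float] = field(default_factory=list)
    dispersal_min: float = 6.0
    volume_segments: list[tuple[float, float, float, float]] = field(default_factory=list)
    death_time: float | None = None         # end of terminal dispersal (GMC) or None
    positions: dict[int, np.ndarray] = field(default_factory=dict)  # frame -> (x, y, z) µm
    mobile: bool = True

    def volume_at(self, t: float) -> float | None:
        """Interphase nuclear volume at time t (µm³), or None if the cell is
        not alive or its signal is dispersed (mitosis)."""
        if t < self.birth_time or (self.death_time is not None and t >= self.death_time):
            return None
        for t0, t1, v0, v1 in self.volume_segments:
            if t0 <= t < t1:
                if t1 == t0:
                    return v1
                return v0 + (v1 - v0) * (t - t0) / (t1 - t0)
        return None

    def is_interphase_at(self, t: float) -> bool:
        return self.volume_at(t) is not None

    def in_dispersal_at(self, t: float) -> bool:
        return self.dispersal_volume_at(t) is not None

    def dispersal_volume_at(self, t: float) -> float | None:
        """Pre-NEBD nuclear volume if t falls in a dispersal interval, else None."""
        for nt in self.nebd_times:
            if nt <= t < nt + self.dispersal_min:
                for t0, t1, v0, v1 in self.volume_segments:
                    if abs(t1 - nt) < 1e-9:
                        return v1
                return None
        return None

    def alive_at(self, t: float) -> bool:
        """Alive = born and not past terminal dispersal; includes mitosis."""
        if t < self.birth_time:
            return False
        if self.death_time is not None and t >= self.death_time:
            return False
        return True

    def nuclear_radius_at(self, t: float) -> float | None:
        v = self.volume_at(t)
        if v is None:
            v = self.dispersal_volume_at(t)
        return None if v is None else sphere_radius(v)


def _draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Cycle-length draw: mean × (1 + cv·N(0,1)), floored at 20% of the mean."""
    return mean * max(0.2, 1.0 + cv * rng.standard_normal())


def simulate_lineage(
    params: LineageParams, duration: float, seed: int | None = None
) -> list[TruthCell]:
    """Event-driven simulation of one lineage over ``duration`` minutes.

    The root NB divides repeatedly; each NB NEBD yields a renewed NB (the same
    TruthCell, starting a fresh growth segment) and one daughter — a GMC in
    type I, an INP in type II. Type I GMCs divide once, symmetrically, into
    two neurons after ``gmc_division_delay_mean``. INPs divide first after
    ``inp_first_cycle_mean`` (maturation included) and then every
    ``inp_mature_cycle_mean``, each division producing a renewed INP and a
    GMC. Daughters are born ``mitosis_duration`` minutes after the parent's
    NEBD. Volumes grow linearly from birth to pre-division volume within each
    cycle, so the realized growth fold equals the configured fold exactly.
    """
    if duration <= 0:
        raise ParamError("duration must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mode = params.lineage_mode
    mit = params.mitosis_duration

    cells: dict[int, TruthCell] = {}
    next_id = [1]
    heap: list[tuple[float, int, int]] = []
    seq = [0]

    def new_cell(parent: int | None, ctype: CellType, birth: float) -> TruthCell:
        cid = next_id[0]
        next_id[0] += 1
        cell = TruthCell(
            cell_id=cid, parent_id=parent, cell_type=ctype,
            birth_time=birth, dispersal_min=mit,
        )
        cells[cid] = cell
        return cell

    def schedule_nebd(cell: TruthCell, t: float) -> None:
        if t <= duration:
            seq[0] += 1
            heapq.heappush(heap, (t, seq[0], cell.cell_id))

    def start_cycle(cell: TruthCell, t0: float, t1: float, v0: float, v1: float) -> None:
        cell.volume_segments.append((t0, t1, v0, v1))
        schedule_nebd(cell, t1)

    p_nb, b_nb = params.nb_predivision_volume, params.nb_birth_volume

    root = new_cell(None, CellType.NB, 0.0)
    first_total = _draw(rng, params.nb_cycle_mean, params.nb_cycle_cv)
    phase = params.initial_phase
    v_start = b_nb + (p_nb - b_nb) * phase
    start_cycle(root, 0.0, first_total * (1.0 - phase), v_start, p_nb)

    def spawn_daughter(parent: TruthCell, birth: float) -> None:
        if birth >= duration:
            return
        if parent.cell_type is CellType.NB:
            if mode is LineageMode.TYPE_I:
                gmc = new_cell(parent.cell_id, CellType.GMC, birth)
                nebd = birth + _draw(rng, params.gmc_division_delay_mean, params.daughter_cycle_cv)
                start_cycle(gmc, birth, nebd, params.gmc_volume, params.gmc_volume)
            else:
                inp = new_cell(parent.cell_id, CellType.INP, birth)
                nebd = birth + _draw(rng, params.inp_first_cycle_mean, params.daughter_cycle_cv)
                start_cycle(inp, birth, nebd, params.inp_birth_volume, params.inp_predivision_volume)
        elif parent.cell_type is CellType.INP:
            gmc = new_cell(parent.cell_id, CellType.GMC, birth)
            nebd = birth + _draw(rng, params.gmc_division_delay_mean, params.daughter_cycle_cv)
            start_cycle(gmc, birth, nebd, params.gmc_volume, params.gmc_volume)

    while heap:
        t, _, cid = heapq.heappop(heap)
        cell = cells[cid]
        cell.nebd_times.append(t)
        rebirth = t + mit
        if cell.cell_type is CellType.NB:
            spawn_daughter(cell, rebirth)
            if rebirth < duration:
                # inter-NEBD interval equals the cycle draw (mitosis included)
                nxt = t + max(_draw(rng, params.nb_cycle_mean, params.nb_cycle_cv), mit * 1.5)
                start_cycle(cell, rebirth, nxt, b_nb, p_nb)
        elif cell.cell_type is CellType.INP:
            spawn_daughter(cell, rebirth)
            if rebirth < duration:
                nxt = t + max(_draw(rng, params.inp_mature_cycle_mean, params.daughter_cycle_cv), mit * 1.5)
                start_cycle(cell, rebirth, nxt, params.inp_birth_volume, params.inp_predivision_volume)
        elif cell.cell_type is CellType.GMC:
            cell.death_time = rebirth
            if rebirth < duration:
                for _ in range(2):
                    neuron = new_cell(cell.cell_id, CellType.NEURON, rebirth)
                    neuron.volume_segments.append(
                        (rebirth, duration + mit, params.neuron_volume, params.neuron_volume)
                    )

    return [cells[cid] for cid in sorted(cells)]


def make_bystanders(
    imaging: ImagingParams, duration: float, n: int | None = None, seed: int | None = None,
    volume: float = 20.0,
) -> list[TruthCell]:
    """Static differentiated nuclei emulating the other cells of a dense
    primary culture; placed near the field periphery, they never divide."""
    n = imaging.n_bystanders if n is None else n
    rng = np.random.default_rng((imaging.seed if seed is None else seed) + 7919)
    out: list[TruthCell] = []
    lx = imaging.field_xy
    lz = imaging.stack_depth
    r = sphere_radius(volume)
    for k in range(n):
        cell = TruthCell(
            cell_id=BYSTANDER_ID_START + k,
            parent_id=None,
            cell_type=CellType.NEURON,
            birth_time=0.0,
            dispersal_min=0.0,
            mobile=False,
        )
        cell.volume_segments.append((0.0, duration + 1.0, volume, volume))
        # ring positions offset toward the field corners, random depth
        ang = 2.0 * math.pi * (k + rng.uniform(0.1, 0.9)) / max(n, 1)
        rad = 0.5 * lx - r - 2.0
        cell.positions[-1] = np.array(
            [
                0.5 * lx + rad * math.cos(ang) * 0.8,
                0.5 * lx + rad * math.sin(ang) * 0.8,
                rng.uniform(r + 2.0, lz - r - 2.0),
            ]
        )
        out.append(cell)
    return out


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _ball_slices(
    center: np.ndarray, r: float, shape: tuple[int, int, int], vxy: float, vz: float
) -> tuple[tuple[slice, slice, slice], np.ndarray] | None:
    """Bounding-box slices and boolean mask of a sphere (physical radius r µm)
    on the anisotropic voxel grid. Voxel centres at (i + 0.5)·voxel."""
    nz, ny, nx = shape
    cx, cy, cz = center
    z0 = max(0, int(math.floor((cz - r) / vz - 0.5)))
    z1 = min(nz, int(math.ceil((cz + r) / vz - 0.5)) + 1)
    y0 = max(0, int(math.floor((cy - r) / vxy - 0.5)))
    y1 = min(ny, int(math.ceil((cy + r) / vxy - 0.5)) + 1)
    x0 = max(0, int(math.floor((cx - r) / vxy - 0.5)))
    x1 = min(nx, int(math.ceil((cx + r) / vxy - 0.5)) + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return None
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    dz = ((zz + 0.5) * vz - cz) / r
    dy = ((yy + 0.5) * vxy - cy) / r
    dx = ((xx + 0.5) * vxy - cx) / r
    mask = dz * dz + dy * dy + dx * dx <= 1.0
    if not mask.any():
        return None
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), mask


def _relax_positions(
    pos: dict[int, np.ndarray], radii: dict[int, float], mobile: dict[int, bool],
    lx: float, lz: float, rng: np.random.Generator,
) -> None:
    """Pairwise hard-core repulsion plus wall clamping, in place."""
    ids = sorted(pos)
    for _ in range(60):
        moved = False
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                d = pos[b] - pos[a]
                dist = float(np.linalg.norm(d))
                target = radii[a] + radii[b] + _PLACEMENT_GAP
                if dist >= target:
                    continue
                if dist < 1e-6:
                    d = rng.normal(size=3)
                    dist = float(np.linalg.norm(d))
                push = 0.5 * (target - dist) * d / dist
                if mobile[a]:
                    pos[a] -= push
                if mobile[b]:
                    pos[b] += push
                if not (mobile[a] or mobile[b]):
                    continue
                moved = True
        for c in ids:
            r = radii[c] + _WALL_MARGIN
            pos[c][0] = np.clip(pos[c][0], r, lx - r)
            pos[c][1] = np.clip(pos[c][1], r, lx - r)
            pos[c][2] = np.clip(pos[c][2], r, lz - r)
        if not moved:
            return
    # final check: nuclear surfaces must not interpenetrate
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if np.linalg.norm(pos[b] - pos[a]) < 0.9 * (radii[a] + radii[b]):
                raise RenderError(f"cannot place cells {a} and {b} without overlap")


def _simulate_positions(
    cells: list[TruthCell], imaging: ImagingParams, n_frames: int,
    rng: np.random.Generator,
) -> None:
    """Fill ``cell.positions`` for every frame the cell is alive."""
    lx, lz = imaging.field_xy, imaging.stack_depth
    by_id = {c.cell_id: c for c in cells}
    root = min((c for c in cells if c.parent_id is None and c.cell_id < BYSTANDER_ID_START),
               key=lambda c: c.cell_id, default=None)
    current: dict[int, np.ndarray] = {}
    for c in cells:
        if -1 in c.positions:  # pre-seeded (bystanders)
            current[c.cell_id] = c.positions[-1].astype(float).copy()

    for t in range(n_frames):
        time = t * imaging.frame_interval
        alive = [c for c in cells if c.alive_at(time)]

        def radii_of(cid: int, time: float = time) -> float:
            return by_id[cid].nuclear_radius_at(time) or 1.0

        # retire dead cells
        for cid in list(current):
            if not by_id[cid].alive_at(time):
                del current[cid]
        # place newborns next to their parent
        for c in sorted(alive, key=lambda c: c.cell_id):
            if c.cell_id in current:
                continue
            r = c.nuclear_radius_at(time) or sphere_radius(20.0)
            if c.parent_id is not None and c.parent_id in current:
                anchor = current[c.parent_id]
                pr = by_id[c.parent_id].nuclear_radius_at(time) or r
            elif c.parent_id is not None and by_id[c.parent_id].positions:
                # parent already gone (terminal division): anchor at its last
                # known position
                parent = by_id[c.parent_id]
                last = max(parent.positions)
                anchor = parent.positions[last]
                pr = parent.nuclear_radius_at(last * imaging.frame_interval) or r
            elif root is not None and c.cell_id == root.cell_id:
                current[c.cell_id] = np.array([0.5 * lx, 0.5 * lx, 0.5 * lz])
                continue
            else:
                anchor, pr = np.array([0.5 * lx, 0.5 * lx, 0.5 * lz]), 3.0
            best = None
            for fac in (1.0, 1.2, 1.45):
                ring_best = None
                sep = (pr + r) * fac + _PLACEMENT_GAP
                for _ in range(48):
                    u = rng.normal(size=3)
                    u /= max(np.linalg.norm(u), 1e-9)
                    cand = anchor + u * sep
                    m = r + _WALL_MARGIN
                    cand = np.clip(cand, [m, m, m], [lx - m, lx - m, lz - m])
                    clearance = min(
                        (np.linalg.norm(cand - p) - radii_of(other, time) - r
                         for other, p in current.items()),
                        default=np.inf,
                    )
                    if ring_best is None or clearance > ring_best[0]:
                        ring_best = (clearance, cand)
                if best is None or ring_best[0] > best[0]:
                    best = ring_best
                # daughters stay adjacent to the parent: accept the closest
                # ring that fits without pushing neighbours
                if ring_best[0] >= 0.25:
                    best = ring_best
                    break
            current[c.cell_id] = best[1]

        # random walk
        for cid in current:
            if by_id[cid].mobile:
                current[cid] = current[cid] + rng.normal(0.0, imaging.motion_sigma, 3)
        radii = {cid: radii_of(cid) for cid in current}
        mobile = {cid: by_id[cid].mobile for cid in current}
        _relax_positions(current, radii, mobile, lx, lz, rng)
        for cid, p in current.items():
            by_id[cid].positions[t] = p.copy()


def render_movie(
    cells: list[TruthCell],
    imaging: ImagingParams,
    duration: float,
    *,
    noise: bool = True,
    blur: bool = True,
) -> tuple[Movie4D, LabelMovie4D]:
    """Render TruthCells into an intensity movie and its ground-truth labels.

    Interphase nuclei are spheres of the trajectory volume at uniform
    ``nuclear_intensity``; within [NEBD, NEBD + mitosis) the signal is spread
    over a cell-sized sphere (``cell_volume_factor`` × nuclear volume) at
    ``nebd_dispersal_factor`` contrast and the label movie is empty for that
    cell. The label movie always contains the noise-free, PSF-free interphase
    masks.
    """
    if duration <= 0:
        raise ParamError("duration must be positive")
    n_frames = int(round(duration / imaging.frame_interval))
    shape = imaging.shape_zyx
    vxy, vz = imaging.voxel_xy, imaging.voxel_z
    ss = np.random.SeedSequence(imaging.seed)
    motion_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    _simulate_positions(cells, imaging, n_frames, motion_rng)

    cal = Calibration(voxel_xy=vxy, voxel_z=vz,
                      frame_interval=imaging.frame_interval, bit_depth=imaging.bit_depth)
    dtype = np.uint8 if imaging.bit_depth == 8 else np.uint16
    data = np.zeros((n_frames, *shape), dtype=dtype)
    labels = np.zeros((n_frames, *shape), dtype=np.int32)
    bg = imaging.background_level
    fg = imaging.nuclear_intensity
    psf_sigma = (imaging.psf_sigma_z / vz, imaging.psf_sigma_xy / vxy,
                 imaging.psf_sigma_xy / vxy)

    for t in range(n_frames):
        time = t * imaging.frame_interval
        clean = np.full(shape, bg, dtype=np.float32)
        lab = labels[t]
        for c in sorted(cells, key=lambda c: c.cell_id):
            pos = c.positions.get(t)
            if pos is None:
                continue
            v = c.volume_at(time)
            if v is not None:
                hit = _ball_slices(pos, sphere_radius(v), shape, vxy, vz)
                if hit is not None:
                    sl, m = hit
                    sub = clean[sl]
                    sub[m] = np.maximum(sub[m], fg)
                    lsub = lab[sl]
                    lsub[m & (lsub == 0)] = c.cell_id
            else:
                dv = c.dispersal_volume_at(time)
                if dv is not None:
                    r_cell = sphere_radius(dv * imaging.cell_volume_factor)
                    hit = _ball_slices(pos, r_cell, shape, vxy, vz)
                    if hit is not None:
                        sl, m = hit
                        level = bg + imaging.nebd_dispersal_factor * (fg - bg)
                        sub = clean[sl]
                        sub[m] = np.maximum(sub[m], level)
        if blur and (imaging.psf_sigma_xy > 0 or imaging.psf_sigma_z > 0):
            clean = gaussian_filter(clean, psf_sigma)
        if noise:
            scale = max(imaging.photon_scale, 1e-6)
            img = noise_rng.poisson(clean / scale).astype(np.float32) * scale
            if imaging.read_noise_sd > 0:
                img += noise_rng.normal(0.0, imaging.read_noise_sd, size=shape).astype(np.float32)
        else:
            img = clean
        data[t] = np.clip(np.rint(img), 0, imaging.max_count).astype(dtype)

    return Movie4D(data=data, calibration=cal), LabelMovie4D(data=labels, calibration=cal)


# --------------------------------------------------------------------------
# truth tables
# --------------------------------------------------------------------------


def write_truth_tables(cells: list[TruthCell], out_dir: str | Path,
                       frame_interval: float = 3.0) -> tuple[Path, Path]:
    """Write cells.csv and frames.csv; returns their paths.

    frames.csv has one row per (frame, cell) in which the cell's nucleus is
    present (interphase); positions require the cells to have been rendered.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells_df = cells_table(cells)
    frames_df = frames_table(cells, frame_interval)
    cells_path = out_dir / "cells.csv"
    frames_path = out_dir / "frames.csv"
    cells_df.to_csv(cells_path, index=False)
    frames_df.to_csv(frames_path, index=False)
    return cells_path, frames_path


def cells_table(cells: list[TruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "parent_id": [c.parent_id if c.parent_id is not None else -1 for c in cells],
            "cell_type": [c.cell_type.value for c in cells],
            "birth_time_min": [c.birth_time for c in cells],
            "nebd_times_min": [";".join(repr(t) for t in c.nebd_times) for c in cells],
        }
    )


def frames_table(cells: list[TruthCell], frame_interval: float) -> pd.DataFrame:
    rows = []
    for c in cells:
        for t in sorted(c.positions):
            if t < 0:
                continue
            time = t * frame_interval
            v = c.volume_at(time)
            if v is None:
                continue
            x, y, z = c.positions[t]
            rows.append((t, c.cell_id, x, y, z, v))
    return pd.DataFrame(
        rows, columns=["frame", "cell_id", "x_um", "y_um", "z_um", "true_volume_um3"]
    )


def read_truth_tables(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out_dir = Path(out_dir)
    cells_df = pd.read_csv(out_dir / "cells.csv",
                           dtype={"nebd_times_min": str}, keep_default_na=False)
    frames_df = pd.read_csv(out_dir / "frames.csv")
    return cells_df, frames_df


def parse_nebd_times(s: str) -> list[float]:
    return [float(x) for x in s.split(";")] if s else []
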
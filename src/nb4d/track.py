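"""Frame-to-frame linking, NEBD/division detection, lineage trees and
cell-type classification.

The observable for mitosis is a detection gap: at nuclear envelope breakdown
the nuclear reporter disperses through the cell and segmentation loses the
object. A division is therefore recognized when a track ends and two new
tracks appear nearby shortly after; the parent's NEBD frame is the first
frame its nucleus is absent. The larger daughter continues the parent's
proliferative identity (a renewed NB stays NB, a renewed INP stays INP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .params import CellType, LineageMode, TrackingConfig
from .segment import NucleusObject

__all__ = [
    "Track",
    "DivisionEvent",
    "LineageTree",
    "link_nuclei",
    "detect_divisions",
    "build_lineage_tree",
    "classify_cells",
    "tracks_table",
    "lineage_table",
    "to_newick",
]


@dataclass
class Track:
    """One nucleus followed over consecutive frames (short gaps allowed)."""

    cell_id: int
    observations: list[NucleusObject] = field(default_factory=list)
    nebd_frame: int | None = None
    parent_id: int | None = None
    daughter_ids: tuple[int, int] | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame

    @property
    def last_centroid(self) -> np.ndarray:
        return np.asarray(self.observations[-1].centroid)

    @property
    def first_centroid(self) -> np.ndarray:
        return np.asarray(self.observations[0].centroid)

    def early_volume(self, n: int = 3) -> float:
        """Mean volume over the first n observations (birth-size proxy)."""
        vols = [o.volume for o in self.observations[:n]]
        return float(np.mean(vols))

    def mean_volume(self) -> float:
        return float(np.mean([o.volume for o in self.observations]))

    def volume_series(self) -> dict[int, float]:
        return {o.frame: o.volume for o in self.observations}


def link_nuclei(
    per_frame: list[list[NucleusObject]], config: TrackingConfig
) -> list[Track]:
    """Greedy nearest-neighbour linking.

    Candidate (track, object) pairs within ``max_step × gap`` µm are assigned
    smallest-distance first, ties broken by volume similarity, then by label.
    Tracks persist unmatched for up to ``max_gap_frames`` frames, then close;
    unmatched objects open new tracks.
    """
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 1
    for f, objs in enumerate(per_frame):
        candidates = []
        for tr in active:
            gap = f - tr.last_frame
            gate = config.max_step * gap
            c = tr.last_centroid
            lv = tr.observations[-1].volume
            for o in objs:
                d = float(np.linalg.norm(np.asarray(o.centroid) - c))
                jump = max(o.volume, lv) / max(min(o.volume, lv), 1e-9)
                if d <= gate and jump <= config.volume_jump_max:
                    candidates.append((d, abs(o.volume - lv), o.label, tr.cell_id, tr, o))
        candidates.sort(key=lambda c: c[:4])
        used_tracks: set[int] = set()
        used_objs: set[int] = set()
        for d, dv, lab, tid, tr, o in candidates:
            if tid in used_tracks or lab in used_objs:
                continue
            tr.observations.append(o)
            used_tracks.add(tid)
            used_objs.add(lab)
        for o in objs:
            if o.label not in used_objs:
                tr = Track(cell_id=next_id, observations=[o])
                next_id += 1
                tracks.append(tr)
                active.append(tr)
        active = [tr for tr in active if f - tr.last_frame <= config.max_gap_frames]
    return tracks


_LAG_PENALTY = 25.0  # µm-equivalent cost per frame of atypical appearance lag
_INADMISSIBLE = 1e9


def _optimal_daughter_assignment(pairs) -> dict[int, list[Track]]:
    """Globally optimal parent↔daughter matching (each parent two slots),
    minimizing appearance-lag penalty plus centroid distance. Keeps
    co-occurring divisions from claiming each other's daughters."""
    from scipy.optimize import linear_sum_assignment

    if not pairs:
        return {}
    parents = sorted({pid for _, _, pid, _, _, _ in pairs})
    cand_ids = sorted({sid for _, _, _, sid, _, _ in pairs})
    cands = {sid: s for _, _, _, sid, _, s in pairs}
    cost = np.full((2 * len(parents), len(cand_ids)), _INADMISSIBLE)
    p_index = {pid: i for i, pid in enumerate(parents)}
    c_index = {sid: j for j, sid in enumerate(cand_ids)}
    for lag, d, pid, sid, _, _ in pairs:
        val = lag * _LAG_PENALTY + d
        for slot in (0, 1):
            cost[2 * p_index[pid] + slot, c_index[sid]] = val
    rows, cols = linear_sum_assignment(cost)
    assigned: dict[int, list[Track]] = {}
    for r, c in zip(rows, cols):
        if cost[r, c] >= _INADMISSIBLE:
            continue
        assigned.setdefault(parents[r // 2], []).append(cands[cand_ids[c]])
    return assigned


@dataclass
class DivisionEvent:
    parent_id: int
    daughter_ids: tuple[int, int]
    nebd_frame: int
    ambiguous: bool = False


def detect_divisions(
    tracks: list[Track], config: TrackingConfig, n_frames: int | None = None
) -> list[DivisionEvent]:
    """Assign parents/daughters from track ends and nearby track starts.

    A track ending at frame f (before the movie's final frame) whose last
    centroid has ≥ 2 unparented tracks starting within
    ``division_search_frames`` frames and ``division_radius`` µm divides into
    the two nearest; its NEBD frame is f + 1, the first frame its nucleus is
    absent. Track ends with no daughters found are flagged terminal; > 2
    candidates flag the event ambiguous.
    """
    if n_frames is None:
        n_frames = max((tr.last_frame for tr in tracks), default=0) + 1
    ended = [tr for tr in tracks if tr.last_frame < n_frames - 1]
    # all admissible (parent, daughter-candidate) pairs, assigned globally so
    # co-occurring divisions do not steal each other's daughters; candidates
    # whose appearance delay matches the expected dispersal gap come first
    expected = config.division_gap_frames + 1
    pairs: list[tuple[int, float, int, int, Track, Track]] = []
    n_cands: dict[int, int] = {}
    for tr in ended:
        f = tr.last_frame
        for s in tracks:
            if s.cell_id == tr.cell_id or s.parent_id is not None:
                continue
            if not (f < s.first_frame <= f + config.division_search_frames):
                continue
            d = float(np.linalg.norm(s.first_centroid - tr.last_centroid))
            if d <= config.division_radius:
                lag = abs((s.first_frame - f) - expected)
                pairs.append((lag, d, tr.cell_id, s.cell_id, tr, s))
                n_cands[tr.cell_id] = n_cands.get(tr.cell_id, 0) + 1
    assigned = _optimal_daughter_assignment(pairs)
    events: list[DivisionEvent] = []
    for tr in sorted(ended, key=lambda t: (t.last_frame, t.cell_id)):
        got = assigned.get(tr.cell_id, [])
        if len(got) == 2:
            a, b = sorted(got, key=lambda t: t.cell_id)
            a.parent_id = b.parent_id = tr.cell_id
            tr.daughter_ids = (a.cell_id, b.cell_id)
            tr.nebd_frame = tr.last_frame + 1
            ev = DivisionEvent(tr.cell_id, (a.cell_id, b.cell_id), tr.nebd_frame,
                               ambiguous=n_cands.get(tr.cell_id, 0) > 2)
            if ev.ambiguous:
                tr.flags.append("ambiguous_division")
            events.append(ev)
        else:
            # a lone candidate stays unparented: a division needs two daughters
            tr.flags.append("terminal_no_daughters")
    return events


@dataclass
class LineageTree:
    """Cells (tracks) as nodes with parent→daughter edges.

    ``root`` is the main lineage root: the frame-0 track with the largest
    mean volume. Other parentless tracks are independent roots (bystander
    cells, orphaned tracks) in ``roots``.
    """

    graph: nx.DiGraph
    tracks: dict[int, Track]
    root: int | None
    roots: list[int]

    def cell_type(self, cell_id: int) -> CellType:
        return self.graph.nodes[cell_id].get("cell_type", CellType.UNKNOWN)

    def daughters(self, cell_id: int) -> tuple[int, int] | None:
        out = sorted(self.graph.successors(cell_id))
        return (out[0], out[1]) if len(out) == 2 else None

    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def main_tree_nodes(self) -> list[int]:
        if self.root is None:
            return []
        return sorted({self.root} | nx.descendants(self.graph, self.root))


def build_lineage_tree(
    tracks: list[Track], divisions: list[DivisionEvent] | None = None
) -> LineageTree:
    """Rooted forest from tracks with parent/daughter assignments.

    ``divisions`` is accepted for interface symmetry; the parent links set by
    :func:`detect_divisions` on the tracks are authoritative.
    """
    g = nx.DiGraph()
    by_id = {tr.cell_id: tr for tr in tracks}
    for tr in tracks:
        g.add_node(tr.cell_id)
    for tr in tracks:
        if tr.parent_id is not None:
            g.add_edge(tr.parent_id, tr.cell_id)
    roots = sorted(tid for tid, tr in by_id.items() if tr.parent_id is None)
    frame0 = [tid for tid in roots if by_id[tid].first_frame == 0]
    root = max(frame0, key=lambda tid: by_id[tid].mean_volume(), default=None)
    return LineageTree(graph=g, tracks=by_id, root=root, roots=roots)


def infer_lineage_mode(tree: LineageTree, config: TrackingConfig) -> LineageMode:
    """Auto mode: TYPE_II iff any smaller first-generation daughter divides
    asymmetrically (INP behaviour); otherwise TYPE_I."""
    for rid in tree.roots:
        tr = tree.tracks[rid]
        if tr.first_frame != 0:
            continue
        node = rid
        while tree.tracks[node].daughter_ids is not None:
            a, b = tree.tracks[node].daughter_ids
            big, small = _order_by_size(tree, a, b)
            str_tr = tree.tracks[small]
            if str_tr.daughter_ids is not None:
                da, db = str_tr.daughter_ids
                x, y = _order_by_size(tree, da, db)
                ratio = tree.tracks[x].early_volume() / max(tree.tracks[y].early_volume(), 1e-9)
                if ratio > config.symmetric_ratio_max:
                    return LineageMode.TYPE_II
            node = big
    return LineageMode.TYPE_I


def _order_by_size(tree: LineageTree, a: int, b: int) -> tuple[int, int]:
    va, vb = tree.tracks[a].early_volume(), tree.tracks[b].early_volume()
    if va == vb:  # deterministic tie-break
        return (min(a, b), max(a, b))
    return (a, b) if va > vb else (b, a)


def classify_cells(
    tree: LineageTree,
    lineage_mode: LineageMode | str,
    config: TrackingConfig,
) -> LineageTree:
    """Rule-based typing of every track in the forest.

    Frame-0 roots whose subtree contains at least one division are
    neuroblasts; at each division the larger daughter inherits the parent's
    proliferative type, the smaller daughter of an NB becomes a GMC (type I)
    or an INP (type II), INP divisions yield INP (larger) + GMC (smaller),
    and a symmetric GMC division (volume ratio ≤ ``symmetric_ratio_max``)
    yields two neurons. Cells with no classification evidence stay UNKNOWN.
    """
    if lineage_mode == "auto":
        lineage_mode = infer_lineage_mode(tree, config)
    mode = LineageMode(lineage_mode)
    g = tree.graph
    for n in g.nodes:
        g.nodes[n]["cell_type"] = CellType.UNKNOWN
    queue: list[int] = []
    for rid in tree.roots:
        tr = tree.tracks[rid]
        if tr.first_frame == 0 and tr.daughter_ids is not None:
            g.nodes[rid]["cell_type"] = CellType.NB
        queue.append(rid)
    while queue:
        node = queue.pop(0)
        t = g.nodes[node]["cell_type"]
        d = tree.tracks[node].daughter_ids
        if d is None:
            continue
        big, small = _order_by_size(tree, *d)
        ratio = tree.tracks[big].early_volume() / max(tree.tracks[small].early_volume(), 1e-9)
        if t is CellType.NB:
            g.nodes[big]["cell_type"] = CellType.NB
            g.nodes[small]["cell_type"] = (
                CellType.GMC if mode is LineageMode.TYPE_I else CellType.INP
            )
        elif t is CellType.INP:
            g.nodes[big]["cell_type"] = CellType.INP
            g.nodes[small]["cell_type"] = CellType.GMC
        elif t is CellType.GMC:
            if ratio <= config.symmetric_ratio_max:
                g.nodes[big]["cell_type"] = CellType.NEURON
                g.nodes[small]["cell_type"] = CellType.NEURON
        queue.extend(d)
    return tree


# --------------------------------------------------------------------------
# tables / export
# --------------------------------------------------------------------------


def tracks_table(tracks: list[Track]) -> pd.DataFrame:
    rows = [
        (tr.cell_id, o.frame, o.label, *o.centroid, o.volume)
        for tr in tracks
        for o in tr.observations
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "frame", "label", "x_um", "y_um", "z_um", "volume_um3"]
    )


def lineage_table(tree: LineageTree) -> pd.DataFrame:
    rows = []
    for tid in tree.nodes():
        tr = tree.tracks[tid]
        rows.append(
            (
                tid,
                tr.parent_id if tr.parent_id is not None else -1,
                tree.cell_type(tid).value,
                tr.first_frame,
                tr.nebd_frame if tr.nebd_frame is not None else -1,
            )
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "parent_id", "cell_type", "birth_frame", "nebd_frame"]
    )


def per_frame_objects(nuclei: pd.DataFrame) -> list[list[NucleusObject]]:
    """Rebuild per-frame object lists from a nuclei table (as written by the
    segmentation stage); fields not stored in the table get placeholders."""
    n_frames = int(nuclei["frame"].max()) + 1 if len(nuclei) else 0
    out: list[list[NucleusObject]] = [[] for _ in range(n_frames)]
    for row in nuclei.itertuples(index=False):
        vol = float(row.volume_um3)
        out[int(row.frame)].append(
            NucleusObject(
                frame=int(row.frame),
                label=int(row.label),
                voxel_count=int(row.voxel_count),
                volume=vol,
                centroid=(float(row.x_um), float(row.y_um), float(row.z_um)),
                bbox=((0, 0, 0), (0, 0, 0)),
                mean_intensity=float(row.mean_intensity),
                sphericity=float(row.sphericity),
                equivalent_diameter=2.0 * (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0),
            )
        )
    return out


def tree_from_tables(lineage: pd.DataFrame, tracks_df: pd.DataFrame) -> LineageTree:
    """Reconstruct a typed LineageTree from lineage.csv + tracks.csv."""
    tracks: dict[int, Track] = {}
    for cid, grp in tracks_df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        obs = [
            NucleusObject(
                frame=int(r.frame), label=int(r.label), voxel_count=0,
                volume=float(r.volume_um3),
                centroid=(float(r.x_um), float(r.y_um), float(r.z_um)),
                bbox=((0, 0, 0), (0, 0, 0)), mean_intensity=np.nan,
                sphericity=np.nan,
                equivalent_diameter=2.0 * (3.0 * float(r.volume_um3) / (4.0 * np.pi)) ** (1.0 / 3.0),
            )
            for r in grp.itertuples(index=False)
        ]
        tracks[int(cid)] = Track(cell_id=int(cid), observations=obs)
    g = nx.DiGraph()
    for row in lineage.itertuples(index=False):
        cid = int(row.cell_id)
        tr = tracks.get(cid)
        if tr is None:
            continue
        g.add_node(cid, cell_type=CellType(row.cell_type))
        if int(row.parent_id) >= 0:
            tr.parent_id = int(row.parent_id)
        if int(row.nebd_frame) >= 0:
            tr.nebd_frame = int(row.nebd_frame)
    for tr in tracks.values():
        if tr.parent_id is not None and tr.parent_id in tracks:
            g.add_edge(tr.parent_id, tr.cell_id)
    for pid in list(tracks):
        kids = sorted(g.successors(pid)) if pid in g else []
        if len(kids) == 2:
            tracks[pid].daughter_ids = (kids[0], kids[1])
    roots = sorted(t for t, tr in tracks.items() if tr.parent_id is None)
    frame0 = [t for t in roots if tracks[t].first_frame == 0]
    root = max(frame0, key=lambda t: tracks[t].mean_volume(), default=None)
    return LineageTree(graph=g, tracks=tracks, root=root, roots=roots)


def to_newick(tree: LineageTree, frame_interval: float) -> str:
    """Main lineage tree as a Newick string; branch lengths in minutes from a
    cell's first observation to its NEBD (or last observation)."""
    if tree.root is None:
        return ";"

    def branch_len(tid: int) -> float:
        tr = tree.tracks[tid]
        end = tr.nebd_frame if tr.nebd_frame is not None else tr.last_frame
        return (end - tr.first_frame) * frame_interval

    def render(tid: int) -> str:
        kids = sorted(tree.graph.successors(tid))
        label = f"{tid}:{branch_len(tid):g}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(tree.root) + ";"
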
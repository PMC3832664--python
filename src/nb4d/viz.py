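"""Visualization: maximum-intensity projections with optional label overlays
and type-coloured lineage-tree plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .movie import LabelMovie4D, Movie4D
from .params import CellType
from .track import LineageTree

__all__ = ["render_mip", "mip_overlay", "plot_lineage_tree"]

_TYPE_COLORS = {
    CellType.NB: "#d62728",
    CellType.INP: "#9467bd",
    CellType.GMC: "#1f77b4",
    CellType.NEURON: "#2ca02c",
    CellType.UNKNOWN: "#7f7f7f",
}


def render_mip(movie: Movie4D | LabelMovie4D) -> np.ndarray:
    """Per-frame maximum-intensity projection along z: (T, Y, X)."""
    return movie.data.max(axis=1)


def mip_overlay(movie: Movie4D, labels: LabelMovie4D | None = None) -> np.ndarray:
    """(T, Y, X, 3) float RGB: grayscale MIP with labels tinted by id."""
    mip = render_mip(movie).astype(np.float32)
    mx = mip.max() or 1.0
    rgb = np.repeat((mip / mx)[..., None], 3, axis=-1)
    if labels is not None:
        lmip = render_mip(labels)
        rng = np.random.default_rng(0)
        ids = np.unique(lmip[lmip > 0])
        for i in ids:
            color = rng.uniform(0.3, 1.0, size=3)
            m = lmip == i
            rgb[m] = 0.5 * rgb[m] + 0.5 * color
    return np.clip(rgb, 0, 1)


def plot_lineage_tree(
    tree: LineageTree, frame_interval: float, out: str | Path | None = None
):
    """Time-vertical lineage tree; nodes coloured by cell type."""
    fig, ax = plt.subplots(figsize=(6, 5))
    if tree.root is None:
        ax.set_axis_off()
        if out:
            fig.savefig(out, dpi=120)
        return fig

    xpos: dict[int, float] = {}
    next_x = [0.0]

    def layout(tid: int) -> float:
        kids = sorted(tree.graph.successors(tid))
        if not kids:
            xpos[tid] = next_x[0]
            next_x[0] += 1.0
        else:
            xpos[tid] = float(np.mean([layout(k) for k in kids]))
        return xpos[tid]

    layout(tree.root)
    for tid in tree.main_tree_nodes():
        tr = tree.tracks[tid]
        t0 = tr.first_frame * frame_interval
        t1 = (tr.nebd_frame if tr.nebd_frame is not None else tr.last_frame) * frame_interval
        color = _TYPE_COLORS[tree.cell_type(tid)]
        ax.plot([xpos[tid], xpos[tid]], [t0, t1], color=color, lw=2.5)
        for k in sorted(tree.graph.successors(tid)):
            ax.plot([xpos[tid], xpos[k]],
                    [t1, tree.tracks[k].first_frame * frame_interval],
                    color="#bbbbbb", lw=1.0)
    ax.invert_yaxis()
    ax.set_ylabel("time (min)")
    ax.set_xticks([])
    handles = [plt.Line2D([], [], color=c, lw=3, label=t.value)
               for t, c in _TYPE_COLORS.items()]
    ax.legend(handles=handles, fontsize=8, loc="upper right")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
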
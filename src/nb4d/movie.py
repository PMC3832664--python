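"""Calibrated 4D movie containers and TIFF + JSON-sidecar I/O.

Movies are stored as multi-page TIFF in TZYX page order; the calibration
(voxel sizes in µm, frame interval in minutes, bit depth) travels in a JSON
sidecar next to the TIFF. Calibration is mandatory: readers refuse to guess
voxel sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Calibration", "Movie4D", "LabelMovie4D", "write_movie", "read_movie"]

AXES = "TZYX"


class MovieIOError(ValueError):
    pass


@dataclass(frozen=True)
class Calibration:
    voxel_xy: float      # µm / pixel
    voxel_z: float       # µm / plane
    frame_interval: float  # min
    bit_depth: int = 8

    @property
    def voxel_volume(self) -> float:
        """µm³ per voxel."""
        return self.voxel_xy ** 2 * self.voxel_z


@dataclass
class Movie4D:
    """T×Z×Y×X intensity movie with physical calibration.

    The origin convention is voxel-centred: the physical position of voxel
    (z, y, x) is ((x+0.5)·voxel_xy, (y+0.5)·voxel_xy, (z+0.5)·voxel_z) µm.
    """

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise MovieIOError(f"expected TZYX data, got {self.data.ndim} dims")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def frame_time(self, t: int) -> float:
        """Start time of frame t in minutes."""
        return t * self.calibration.frame_interval


@dataclass
class LabelMovie4D:
    """T×Z×Y×X integer labels; 0 is background, otherwise the cell id."""

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise MovieIOError(f"expected TZYX data, got {self.data.ndim} dims")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise MovieIOError("label movie must be integer typed")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".tif" else path.with_suffix(".json")


def write_movie(movie: Movie4D | LabelMovie4D, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF (TZYX pages) plus a JSON sidecar;
    returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = movie.data
    t, z, y, x = data.shape
    tifffile.imwrite(path, data.reshape(t * z, y, x))
    cal = movie.calibration
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "axes": AXES,
                "n_frames": t,
                "n_planes": z,
                "voxel_xy": cal.voxel_xy,
                "voxel_z": cal.voxel_z,
                "frame_interval": cal.frame_interval,
                "bit_depth": cal.bit_depth,
                "dtype": str(data.dtype),
                "kind": "labels" if isinstance(movie, LabelMovie4D) else "intensity",
            },
            indent=1,
        )
    )
    return sidecar


def read_movie(path: str | Path, sidecar: str | Path | None = None) -> Movie4D:
    """Read a TZYX TIFF movie; calibration comes from the JSON sidecar.

    Raises :class:`MovieIOError` if the sidecar or any calibration key is
    missing, or if the page count is inconsistent with the sidecar.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise MovieIOError(f"missing calibration sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("voxel_xy", "voxel_z", "frame_interval", "n_frames", "n_planes"):
        if key not in meta:
            raise MovieIOError(f"calibration sidecar lacks required key {key!r}")
    if meta.get("axes", AXES) != AXES:
        raise MovieIOError(f"unsupported axes order {meta.get('axes')!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    t, z = int(meta["n_frames"]), int(meta["n_planes"])
    if pages.shape[0] != t * z:
        raise MovieIOError(
            f"page count {pages.shape[0]} does not match sidecar T*Z = {t * z}"
        )
    data = pages.reshape(t, z, pages.shape[1], pages.shape[2])
    cal = Calibration(
        voxel_xy=float(meta["voxel_xy"]),
        voxel_z=float(meta["voxel_z"]),
        frame_interval=float(meta["frame_interval"]),
        bit_depth=int(meta.get("bit_depth", 8)),
    )
    if np.issubdtype(data.dtype, np.integer) and meta.get("kind") == "labels":
        return LabelMovie4D(data=data, calibration=cal)  # type: ignore[return-value]
    return Movie4D(data=data, calibration=cal)
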
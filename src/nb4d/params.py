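"""Parameter containers for simulation, segmentation, tracking and quantification.

All spatial quantities are in micrometres (µm), times in minutes, volumes in µm³,
intensities in camera counts. Every dataclass validates its invariants in
``__post_init__`` and can be round-tripped through plain dicts (and hence YAML/JSON)
via :func:`config_to_dict` / :func:`config_from_dict`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Any

__all__ = [
    "LineageMode",
    "CellType",
    "LineageParams",
    "ImagingParams",
    "SegmentationConfig",
    "TrackingConfig",
    "QuantConfig",
    "PipelineConfig",
    "type_i_preset",
    "type_ii_preset",
    "default_imaging",
    "config_to_dict",
    "config_from_dict",
]

# Window centres of the representative-volume windows, minutes after first
# detection of the cell (midpoints of the 39-45 and 9-15 min windows).
INP_REP_WINDOW_CENTER_MIN = 42.0
GMC_REP_WINDOW_CENTER_MIN = 12.0


class LineageMode(str, Enum):
    """Neuroblast lineage architecture.

    TYPE_I neuroblasts bud off ganglion mother cells (GMCs) that divide once,
    symmetrically, into two neurons. TYPE_II neuroblasts bud off intermediate
    neural progenitors (INPs) that mature, then divide asymmetrically into a
    renewed INP and a GMC.
    """

    TYPE_I = "typeI"
    TYPE_II = "typeII"


class CellType(str, Enum):
    NB = "NB"
    INP = "INP"
    GMC = "GMC"
    NEURON = "NEURON"
    UNKNOWN = "UNKNOWN"


class ParamError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class LineageParams:
    """Ground-truth lineage generator parameters.

    Volumes are anchored by ``nb_predivision_volume`` (the neuroblast's nuclear
    volume just before nuclear envelope breakdown); every other characteristic
    volume is derived from the fold parameters, see the derived properties.
    """

    lineage_mode: LineageMode = LineageMode.TYPE_I
    nb_cycle_mean: float = 78.0          # min between consecutive NB NEBDs
    nb_cycle_cv: float = 0.1
    gmc_division_delay_mean: float = 252.0   # min, GMC birth -> NEBD
    inp_first_cycle_mean: float = 396.0      # min, INP birth -> first NEBD (incl. maturation)
    inp_mature_cycle_mean: float = 150.0     # min, mature INP inter-NEBD interval
    daughter_cycle_cv: float = 0.1
    nb_predivision_volume: float = 250.0 / 1.5  # µm³ (type I default)
    nb_growth_fold: float = 1.2          # pre-division / post-birth NB volume
    daughter_volume_fold: float = 3.6    # NB pre-division / daughter representative volume
    inp_growth_fold: float = 1.7
    inp_gmc_volume_fold: float = 1.5     # INP / type II GMC representative volume
    neuron_volume: float = 20.0          # µm³
    mitosis_duration: float = 6.0        # min of NEBD signal dispersal
    initial_phase: float = 0.0           # fraction of first NB cycle elapsed at t=0
    seed: int = 0

    def __post_init__(self) -> None:
        self.lineage_mode = LineageMode(self.lineage_mode)
        cycles = [
            self.nb_cycle_mean,
            self.gmc_division_delay_mean,
            self.inp_first_cycle_mean,
            self.inp_mature_cycle_mean,
        ]
        if any(c <= 0 for c in cycles):
            raise ParamError("all cycle means must be > 0")
        folds = [
            self.nb_growth_fold,
            self.daughter_volume_fold,
            self.inp_growth_fold,
            self.inp_gmc_volume_fold,
        ]
        if any(f < 1 for f in folds):
            raise ParamError("all folds must be >= 1")
        if not (0 <= self.initial_phase < 1):
            raise ParamError("initial_phase must lie in [0, 1)")
        if any(self.mitosis_duration >= c for c in cycles):
            raise ParamError("mitosis_duration must be shorter than every cycle mean")
        if self.nb_predivision_volume <= 0 or self.neuron_volume <= 0:
            raise ParamError("volumes must be positive")
        if self.nb_cycle_cv < 0 or self.daughter_cycle_cv < 0:
            raise ParamError("cycle CVs must be >= 0")

    # ---- derived characteristic volumes (µm³) ------------------------------
    @property
    def nb_birth_volume(self) -> float:
        return self.nb_predivision_volume / self.nb_growth_fold

    @property
    def daughter_rep_volume(self) -> float:
        """Representative volume of the NB's small daughter (GMC or INP)."""
        return self.nb_predivision_volume / self.daughter_volume_fold

    @property
    def inp_birth_volume(self) -> float:
        # Solve B so that the linearly growing INP hits the representative
        # volume at the centre of its 39-45 min measurement window while
        # spanning exactly inp_growth_fold over its first cycle.
        f = self.inp_growth_fold
        w = INP_REP_WINDOW_CENTER_MIN / self.inp_first_cycle_mean
        return self.daughter_rep_volume / (1.0 + (f - 1.0) * w)

    @property
    def inp_predivision_volume(self) -> float:
        return self.inp_growth_fold * self.inp_birth_volume

    @property
    def gmc_volume(self) -> float:
        """GMC nuclear volume (GMCs do not grow)."""
        if self.lineage_mode is LineageMode.TYPE_I:
            return self.daughter_rep_volume
        return self.daughter_rep_volume / self.inp_gmc_volume_fold


def type_i_preset(seed: int = 0, **overrides: Any) -> LineageParams:
    """Type I lineage defaults: 78-min NB cycles, 4.2-h GMC delay, volume
    system anchored so the type-II/type-I pre-division ratio is 1.5."""
    kw: dict[str, Any] = dict(
        lineage_mode=LineageMode.TYPE_I,
        nb_cycle_mean=78.0,
        nb_predivision_volume=250.0 / 1.5,
        nb_growth_fold=1.2,
        daughter_volume_fold=3.6,
        seed=seed,
    )
    kw.update(overrides)
    return LineageParams(**kw)


def type_ii_preset(seed: int = 0, **overrides: Any) -> LineageParams:
    """Type II lineage defaults: 96-min NB cycles, 6.6-h INP first cycle,
    2.5-h mature INP cycles, 250 µm³ NB pre-division anchor."""
    kw: dict[str, Any] = dict(
        lineage_mode=LineageMode.TYPE_II,
        nb_cycle_mean=96.0,
        nb_predivision_volume=250.0,
        nb_growth_fold=1.4,
        daughter_volume_fold=4.2,
        inp_growth_fold=1.7,
        inp_gmc_volume_fold=1.5,
        seed=seed,
    )
    kw.update(overrides)
    return LineageParams(**kw)


@dataclass
class ImagingParams:
    """Virtual microscope: geometry, optics and noise of the rendered movie.

    Defaults follow the acquisition the simulator emulates: 1-µm z steps,
    3-min frame interval, 40-µm stacks, 8-bit camera.
    """

    voxel_xy: float = 0.33          # µm / pixel
    voxel_z: float = 1.0            # µm / plane
    frame_interval: float = 3.0     # min
    stack_depth: float = 40.0       # µm
    field_xy: float = 64 * 0.33     # µm (64-pixel field)
    bit_depth: int = 8
    psf_sigma_xy: float = 0.25      # µm
    psf_sigma_z: float = 0.6        # µm
    background_level: float = 10.0  # counts
    nuclear_intensity: float = 140.0  # counts
    nebd_dispersal_factor: float = 0.15  # dispersed-signal contrast vs interphase nucleus
    read_noise_sd: float = 2.0      # counts
    photon_scale: float = 1.0       # counts per photon
    cell_volume_factor: float = 2.0  # cell volume / nuclear volume
    motion_sigma: float = 0.3       # µm/frame random-walk step of cultured cells
    n_bystanders: int = 3           # static non-lineage nuclei in the field
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.voxel_z >= self.voxel_xy > 0):
            raise ParamError("requires voxel_z >= voxel_xy > 0")
        if self.frame_interval <= 0:
            raise ParamError("frame_interval must be > 0")
        if not (0 <= self.nebd_dispersal_factor < 1):
            raise ParamError("nebd_dispersal_factor must lie in [0, 1)")
        if self.bit_depth not in (8, 16):
            raise ParamError("bit_depth must be 8 or 16")
        if self.cell_volume_factor < 1:
            raise ParamError("cell_volume_factor must be >= 1")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        nz = int(round(self.stack_depth / self.voxel_z))
        nxy = int(round(self.field_xy / self.voxel_xy))
        return nz, nxy, nxy

    @property
    def voxel_volume(self) -> float:
        return self.voxel_xy ** 2 * self.voxel_z

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


def default_imaging(seed: int = 0, **overrides: Any) -> ImagingParams:
    kw: dict[str, Any] = dict(seed=seed)
    kw.update(overrides)
    return ImagingParams(**kw)


@dataclass
class SegmentationConfig:
    gauss_sigma: float = 1.0             # µm, isotropic in physical units
    threshold_method: str = "otsu"
    min_nucleus_volume: float = 10.0     # µm³
    max_nucleus_volume: float = 1000.0   # µm³
    min_sphericity: float = 0.6
    seed_min_distance: float = 3.0       # µm
    refine_iterations: int = 3
    refine_intensity_quantile: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_nucleus_volume < self.max_nucleus_volume:
            raise ParamError("min_nucleus_volume must be < max_nucleus_volume")
        if not (0 < self.min_sphericity <= 1):
            raise ParamError("min_sphericity must lie in (0, 1]")
        if self.threshold_method != "otsu":
            raise ParamError("only the 'otsu' threshold method is supported")
        if not (0 <= self.refine_intensity_quantile < 1):
            raise ParamError("refine_intensity_quantile must lie in [0, 1)")


@dataclass
class TrackingConfig:
    max_step: float = 5.0            # µm / frame
    max_gap_frames: int = 1
    division_search_frames: int = 4
    division_gap_frames: int = 2     # typical NEBD detection gap (frames)
    division_radius: float = 12.0    # µm
    symmetric_ratio_max: float = 1.25  # daughter volume ratio at/below which a division is symmetric
    volume_jump_max: float = 2.0     # max volume fold change tolerated across one link

    def __post_init__(self) -> None:
        if min(self.max_step, self.division_search_frames, self.division_radius) <= 0:
            raise ParamError("tracking parameters must be positive")
        if self.max_gap_frames < 0:
            raise ParamError("max_gap_frames must be >= 0")
        if self.symmetric_ratio_max < 1:
            raise ParamError("symmetric_ratio_max must be >= 1")


@dataclass
class QuantConfig:
    frame_interval: float = 3.0          # min
    nb_premitosis_window: float = 9.0    # min
    postmitosis_window: float = 9.0      # min
    inp_window: tuple[float, float] = (39.0, 45.0)   # min after first detection
    gmc_window: tuple[float, float] = (9.0, 15.0)    # min after first detection
    analysis_horizon_frames: int = 200

    def __post_init__(self) -> None:
        self.inp_window = tuple(self.inp_window)  # type: ignore[assignment]
        self.gmc_window = tuple(self.gmc_window)  # type: ignore[assignment]
        if self.frame_interval <= 0:
            raise ParamError("frame_interval must be > 0")
        for w in (self.nb_premitosis_window, self.postmitosis_window):
            if w <= 0:
                raise ParamError("windows must be positive")
        for a, b in (self.inp_window, self.gmc_window):
            if not 0 <= a < b:
                raise ParamError("window bounds must satisfy 0 <= start < end")
        if self.analysis_horizon_frames <= 0:
            raise ParamError("analysis_horizon_frames must be positive")

    def window_frames(self, minutes: float) -> int:
        """Number of frames spanned by a window of the given length."""
        return max(1, int(round(minutes / self.frame_interval)))


_SECTION_TYPES = {
    "lineage": LineageParams,
    "imaging": ImagingParams,
    "segmentation": SegmentationConfig,
    "tracking": TrackingConfig,
    "quantify": QuantConfig,
}


@dataclass
class PipelineConfig:
    """Nested configuration for a full run; unknown keys are rejected on load
    and all defaults are materialized so the emitted config reproduces the run."""

    schema_version: int = 1
    lineage: LineageParams = field(default_factory=LineageParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    quantify: QuantConfig = field(default_factory=QuantConfig)


def config_to_dict(cfg: Any) -> dict[str, Any]:
    """Dataclass -> plain dict (enums to their string values, tuples to lists)."""

    def convert(v: Any) -> Any:
        if isinstance(v, Enum):
            return v.value
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: convert(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, (list, tuple)):
            return [convert(x) for x in v]
        return v

    return convert(cfg)


def _from_dict(cls: type, data: dict[str, Any]) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ParamError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    data = dict(data)
    version = data.pop("schema_version", 1)
    if version != 1:
        raise ParamError(f"unsupported config schema_version {version}")
    sections: dict[str, Any] = {}
    for key, payload in data.items():
        if key not in _SECTION_TYPES:
            raise ParamError(f"unknown config section {key!r}")
        sections[key] = _from_dict(_SECTION_TYPES[key], payload)
    return PipelineConfig(schema_version=version, **sections)
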
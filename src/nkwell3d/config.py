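"""Configuration objects for every stage of the pipeline.

Each stage (simulation, volume rendering, segmentation, linking, track
filtering, rolling-window analysis, contact analysis) owns a small frozen-ish
dataclass validated on construction.  All physical quantities are in
micrometres and minutes; voxel units appear only in the segmentation and
linking configs, mirroring how the tracking software is parameterized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml

MODE_TMAP = "TMAP"
MODE_RANDOM = "random"
MODE_DIRECTED = "directed"
ALL_MODES: Tuple[str, str, str] = (MODE_TMAP, MODE_RANDOM, MODE_DIRECTED)

NK = "NK"
TARGET = "target"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite_nonneg(value: float, name: str) -> None:
    import math

    _require(math.isfinite(value) and value >= 0, f"{name} must be finite and >= 0, got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the mode-switching trajectory simulator.

    NK cells alternate between confined (``TMAP``), Brownian (``random``)
    and persistent (``directed``) motion with exponentially distributed mode
    dwell times (mean ``dwell_mean``, default 106 min, the population mean
    residence time in a migration mode).  Targets are near-immotile Brownian
    particles.  Cells are impenetrable: a step that would bring two cell
    centres within ``min_separation`` (default 8 um, one cell diameter) is
    rejected and the cell stalls for that frame.  The default well is the
    450 x 450 x 300 um microwell.
    """

    n_nk: int = 20
    n_target: int = 5
    well_size: Tuple[float, float, float] = (450.0, 450.0, 300.0)
    dt: float = 2.0
    duration: float = 540.0
    mode_set: Tuple[str, ...] = ALL_MODES
    M_tmap: float = 1.0
    M_random: float = 15.0
    v_directed: float = 6.0
    dwell_mean: float = 106.0
    target_M: float = 0.3
    contact_radius: float = 20.0
    p_kill_per_contact: float = 0.57
    kill_delay_mean: float = 20.0
    min_separation: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_nk >= 0 and self.n_target >= 0, "cell counts must be >= 0")
        _require(len(self.well_size) == 3 and all(s > 0 for s in self.well_size),
                 "well_size must be three strictly positive extents")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.duration >= self.dt, "duration must be >= dt")
        _require(len(self.mode_set) >= 1 and all(m in ALL_MODES for m in self.mode_set),
                 f"mode_set entries must be among {ALL_MODES}")
        for name in ("M_tmap", "M_random", "v_directed", "target_M",
                     "dwell_mean", "contact_radius", "kill_delay_mean",
                     "min_separation"):
            _finite_nonneg(getattr(self, name), name)
        _require(0.0 <= self.p_kill_per_contact <= 1.0, "p_kill_per_contact must be in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt)) + 1


@dataclass
class ImageRenderConfig:
    """How simulated cells are painted into two-channel 8-bit voxel stacks.

    Geometry defaults follow the assay: 36-39 optical sections of 512 x 512
    pixels at ~1.1 x 1.1 x 8 um voxels.  Each live cell becomes an
    anisotropic Gaussian blob (``psf_sigma``, um per axis, folding cell size
    and the confocal PSF together); a killed target keeps a residual blob at
    ``post_kill_intensity_fraction`` of its amplitude, emulating calcein
    leakage on death.  Noise: Poisson at ``poisson_gain`` counts/intensity
    unit (``None`` disables), then Gaussian read noise.
    """

    frame_shape: Tuple[int, int, int] = (38, 512, 512)  # (z, y, x) voxels
    voxel_size: Tuple[float, float, float] = (1.1, 1.1, 8.0)  # (x, y, z) um
    psf_sigma: Tuple[float, float, float] = (2.5, 2.5, 4.0)  # (x, y, z) um
    amplitude: float = 200.0
    background_level: float = 8.0
    poisson_gain: Optional[float] = 1.0
    read_noise_sigma: float = 2.0
    post_kill_intensity_fraction: float = 0.1

    def __post_init__(self) -> None:
        _require(len(self.frame_shape) == 3 and all(int(s) >= 1 for s in self.frame_shape),
                 "frame_shape must be three positive voxel counts")
        _require(len(self.voxel_size) == 3 and all(v > 0 for v in self.voxel_size),
                 "voxel_size must be three positive extents")
        _require(all(s > 0 for s in self.psf_sigma), "psf_sigma must be positive")
        _finite_nonneg(self.amplitude, "amplitude")
        _finite_nonneg(self.background_level, "background_level")
        _finite_nonneg(self.read_noise_sigma, "read_noise_sigma")
        if self.poisson_gain is not None:
            _require(self.poisson_gain > 0, "poisson_gain must be > 0 or None")
        _require(0.0 <= self.post_kill_intensity_fraction <= 1.0,
                 "post_kill_intensity_fraction must be in [0, 1]")

    @property
    def physical_extent(self) -> Tuple[float, float, float]:
        """(x, y, z) extent of the rendered volume in um."""
        nz, ny, nx = self.frame_shape
        vx, vy, vz = self.voxel_size
        return ((nx - 1) * vx, (ny - 1) * vy, (nz - 1) * vz)


@dataclass
class SegmentationConfig:
    """Difference-of-Gaussians band-pass + threshold + h-minima watershed.

    Sigmas are in xy pixels; in z both kernels are divided by
    ``z_sigma_divisor`` to account for the coarse axial sampling.  The
    threshold applies to the band-passed image of an intensity-normalized
    ([0, 1]) stack.  Regions smaller than ``min_voxels`` are discarded.
    """

    sigma_pos: float = 1.0
    sigma_neg: float = 3.0
    z_sigma_divisor: float = 8.0
    threshold: float = 0.02
    h_min: float = 0.15
    min_voxels: int = 5

    def __post_init__(self) -> None:
        _require(0 < self.sigma_pos < self.sigma_neg,
                 "need sigma_neg > sigma_pos > 0")
        _require(self.z_sigma_divisor > 0, "z_sigma_divisor must be > 0")
        _require(0.0 < self.threshold < 1.0, "threshold must be in (0, 1)")
        _require(self.h_min >= 0, "h_min must be >= 0")
        _require(self.min_voxels >= 1, "min_voxels must be >= 1")


@dataclass
class LinkingConfig:
    """Frame-to-frame probabilistic assignment parameters.

    The motion model is an anisotropic Gaussian centred on the previous
    position with standard deviations in voxels; appearance/disappearance
    probabilities penalize starting/ending tracks.  ``p_count`` are the
    prior probabilities that a segmented object holds 0, 1 or 2+ cells.
    """

    sigma_xy: float = 6.0
    sigma_z: float = 0.5
    p_count: Tuple[float, float, float] = (0.2, 0.7, 0.1)
    p_appear: float = 0.001
    p_disappear: float = 0.001
    p_death: float = 0.0
    p_division: float = 0.0
    max_link_sigmas: float = 5.0  # gating distance, in units of sigma
    # detections larger than this multiple of the median object volume are
    # treated as 2+-cell clusters and are not linked (0 disables)
    multi_cell_voxel_factor: float = 1.6

    def __post_init__(self) -> None:
        _require(self.sigma_xy > 0 and self.sigma_z > 0, "link sigmas must be > 0")
        _require(len(self.p_count) == 3 and all(0 <= p <= 1 for p in self.p_count),
                 "p_count must be three probabilities")
        _require(abs(sum(self.p_count) - 1.0) < 1e-9, "p_count must sum to 1")
        for name in ("p_appear", "p_disappear", "p_death", "p_division"):
            p = getattr(self, name)
            _require(0.0 <= p <= 1.0, f"{name} must be in [0, 1]")
        _require(self.max_link_sigmas > 0, "max_link_sigmas must be > 0")
        _require(self.multi_cell_voxel_factor >= 0,
                 "multi_cell_voxel_factor must be >= 0")


@dataclass
class TrackFilterConfig:
    """Track QC: minimum duration and maximum consecutive-frame z jump."""

    min_duration: float = 60.0  # min
    max_z_jump: float = 40.0  # um

    def __post_init__(self) -> None:
        _require(self.min_duration > 0, "min_duration must be > 0")
        _require(self.max_z_jump > 0, "max_z_jump must be > 0")


@dataclass
class WindowConfig:
    """Rolling-window MSD analysis parameters.

    ``window`` points are centred on each time point; the motility
    coefficient M comes from a linear fit to the first ``fit_points`` MSD
    lags (MSD = 6 M t), the anomalous exponent alpha from the log-log fit
    over the same lags.  Profiles are smoothed by a centred rolling average
    before thresholding: M below ``M_threshold`` marks migration arrest,
    alpha above ``alpha_threshold`` for at least ``directed_min_run``
    consecutive points marks directed migration.
    """

    window: int = 25
    fit_points: int = 6
    smooth_window: int = 5
    M_threshold: float = 4.9  # um^2/min
    alpha_threshold: float = 1.5
    directed_min_run: int = 10

    def __post_init__(self) -> None:
        _require(self.window > self.fit_points >= 3,
                 "need window > fit_points >= 3")
        _require(self.smooth_window >= 1, "smooth_window must be >= 1")
        _require(self.M_threshold > 0 and self.alpha_threshold > 0,
                 "thresholds must be > 0")
        _require(self.directed_min_run >= 1, "directed_min_run must be >= 1")

    @property
    def half_window(self) -> int:
        return self.window // 2


@dataclass
class ContactConfig:
    """NK-target contact and death-call parameters (um / frames / min)."""

    contact_radius: float = 20.0
    gap_tolerance: int = 0
    death_attribution_window: float = 30.0
    death_intensity_fraction: float = 0.5
    death_min_frames: int = 3

    def __post_init__(self) -> None:
        _require(self.contact_radius > 0, "contact_radius must be > 0")
        _require(self.gap_tolerance >= 0, "gap_tolerance must be >= 0")
        _require(self.death_attribution_window >= 0,
                 "death_attribution_window must be >= 0")
        _require(0.0 < self.death_intensity_fraction < 1.0,
                 "death_intensity_fraction must be in (0, 1)")
        _require(self.death_min_frames >= 1, "death_min_frames must be >= 1")


@dataclass
class RunConfig:
    """Whole-pipeline configuration: one global seed plus per-stage configs.

    ``imaging=False`` bypasses rendering/segmentation/linking and feeds the
    simulated tracks straight into the migration and interaction analyses.
    """

    seed: int = 0
    imaging: bool = False
    background_subtract: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    render: ImageRenderConfig = field(default_factory=ImageRenderConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    track_filter: TrackFilterConfig = field(default_factory=TrackFilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)

    def __post_init__(self) -> None:
        _require(0 <= int(self.seed) < 2**31, "seed must be a non-negative 31-bit integer")


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "render": ImageRenderConfig,
    "segmentation": SegmentationConfig,
    "linking": LinkingConfig,
    "track_filter": TrackFilterConfig,
    "window": WindowConfig,
    "contact": ContactConfig,
}


def _coerce(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _coerce(cls, data.pop(name) or {})
    for key in ("seed", "imaging", "background_subtract"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ValueError(f"unknown run-config keys: {sorted(data)}")
    if "seed" not in kwargs:
        raise ValueError("run config must set an explicit seed")
    cfg = RunConfig(**kwargs)
    # a single seed governs every stochastic stage
    cfg.simulation = dataclasses.replace(cfg.simulation, seed=int(cfg.seed))
    return cfg


def load_run_config(path) -> RunConfig:
    """Read a pipeline :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return run_config_from_dict(data)


def dump_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_to_dict(cfg) -> dict:
    """Dataclass config -> plain dict (tuples become lists), YAML/JSON ready."""
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v

    return clean(d)
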
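"""Configuration objects for acquisition, simulation, tracking and classification.

All physical quantities are stored in SI units (seconds, Hz); lifetimes that
users touch directly are in nanoseconds, mirroring how they are reported in
FLIM practice.  Every config round-trips losslessly through ``to_dict`` /
``from_dict`` and hence through YAML/JSON run files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

NS = 1e-9


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pulsed-excitation TCSPC acquisition settings.

    Parameters
    ----------
    rep_rate_hz:
        Laser repetition rate ``f`` (Hz).  The phasor angular frequency is
        ``omega = 2 pi f``.
    dwell_time_s:
        Per-pixel dwell time.  The number of excitation pulses each pixel
        sees per frame is ``dwell_time_s * rep_rate_hz``.
    dead_time_s:
        Detector/electronics dead time after each *recorded* photon.
        ~50 ns for classic TCSPC timing electronics, ~2 ns for rapid
        hybrid-detector systems.
    sync_rearm:
        If True the detector re-arms only at the first excitation pulse after
        the dead interval expires (start-stop electronics: at most one
        conversion per sync period).  If False it re-arms the instant the
        dead time elapses (multi-stop electronics).
    emission_model:
        ``"binomial"`` - at most one photon per pulse, emitted with
        probability equal to the emission rate (single-emitter pixel);
        ``"poisson"`` - Poisson photon number per pulse with the emission
        rate as its mean (ensemble pixel).  Pileup skew requires the
        multi-photon model.
    n_microtime_bins:
        TCSPC histogram bins spanning one pulse period.
    irf_sigma_s / irf_center_s:
        Gaussian instrument-response jitter and the arrival time of the
        excitation pulse within the micro-time window.  ``irf_center_s > 0``
        keeps jittered arrivals from wrapping below zero.
    """

    rep_rate_hz: float = 40e6
    dwell_time_s: float = 10e-6
    dead_time_s: float = 2e-9
    sync_rearm: bool = False
    emission_model: str = "binomial"
    n_microtime_bins: int = 250
    frame_shape: tuple[int, int] = (64, 64)
    frame_interval_s: float = 1.0
    irf_sigma_s: float = 0.2e-9
    irf_center_s: float = 1.0e-9
    min_photons: int = 20

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0:
            raise ValueError("rep_rate_hz must be positive")
        if self.dead_time_s < 0:
            raise ValueError("dead_time_s must be >= 0")
        if self.n_microtime_bins < 2:
            raise ValueError("n_microtime_bins must be >= 2")
        if self.emission_model not in ("binomial", "poisson"):
            raise ValueError(f"unknown emission_model {self.emission_model!r}")
        if len(self.frame_shape) != 2 or min(self.frame_shape) <= 0:
            raise ValueError("frame_shape must be a positive (rows, cols) pair")

    @property
    def pulse_period_s(self) -> float:
        return 1.0 / self.rep_rate_hz

    @property
    def pulse_period_ns(self) -> float:
        return 1.0 / self.rep_rate_hz / NS

    @property
    def angular_freq(self) -> float:
        """omega = 2 pi f (rad/s)."""
        return 2.0 * np.pi * self.rep_rate_hz

    @property
    def pulses_per_pixel(self) -> int:
        return int(round(self.dwell_time_s * self.rep_rate_hz))

    @property
    def bin_width_ns(self) -> float:
        return self.pulse_period_ns / self.n_microtime_bins

    @property
    def frame_acquisition_time_s(self) -> float:
        """Time to raster one frame at the configured dwell time."""
        rows, cols = self.frame_shape
        return rows * cols * self.dwell_time_s

    @property
    def irf_center_ns(self) -> float:
        return self.irf_center_s / NS


def classic_flim(**overrides: Any) -> AcquisitionConfig:
    """Classic TCSPC electronics: 50 ns dead time, start-stop re-arming."""
    kw: dict[str, Any] = dict(dead_time_s=50e-9, sync_rearm=True)
    kw.update(overrides)
    return AcquisitionConfig(**kw)


def rapid_flim(**overrides: Any) -> AcquisitionConfig:
    """Rapid hybrid-detector electronics: ~2 ns dead time, multi-stop."""
    kw: dict[str, Any] = dict(dead_time_s=2e-9, sync_rearm=False)
    kw.update(overrides)
    return AcquisitionConfig(**kw)


#: Default compartment lifetime table (ns).  The nuclear value sits one
#: membrane step (+0.8 ns) above cytoplasm so that boundary crossings exceed
#: a typical control-derived threshold; all values are overridable.
DEFAULT_LIFETIMES_NS: dict[str, float] = {
    "extracellular": 2.0,
    "cytoplasm": 3.0,
    "nucleus": 3.8,
}


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth scene: geometry, motion and emission brightness.

    ``photons_per_particle_frame`` is the expected number of photons a spot
    *emits* toward the detector per frame.  In the cell preset spots are
    endosomal clusters of several nanoparticles and are correspondingly
    brighter than the single particles of the agarose control preset.
    """

    n_particles: int = 20
    n_frames: int = 25
    motion_model: str = "confined"  # "free" | "confined"
    diffusion_px2_per_frame: float = 0.55
    photons_per_particle_frame: float = 4000.0
    background_rate_per_pulse: float = 0.004
    psf_sigma_px: float = 1.0
    cell_radius_px: tuple[float, float] = (32.0, 28.0)
    nucleus_radius_px: tuple[float, float] = (11.0, 10.0)
    boundary_width_px: float = 2.0
    fraction_near_nucleus: float = 0.5
    lifetimes_ns: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIFETIMES_NS)
    )
    transition_frames: int = 0

    def __post_init__(self) -> None:
        if self.motion_model not in ("free", "confined"):
            raise ValueError(f"unknown motion_model {self.motion_model!r}")
        if self.diffusion_px2_per_frame < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")


@dataclass(frozen=True)
class TrackerConfig:
    """Detection and linking parameters (commercial-tracker semantics).

    ``brightness_max`` is recorded for provenance but not applied as an
    upper cut: the conventional 750-1500 brightness window is read as a
    dim-particle removal floor.
    """

    band_low_px: float = 0.75
    band_high_px: float = 1.0
    size_window_px: tuple[float, float] = (0.85, 1.5)
    brightness_min: float = 750.0
    brightness_max: float | None = 1500.0
    peak_snr: float = 5.0
    max_jump_px: float = 5.0
    min_track_length: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.band_low_px < self.band_high_px:
            raise ValueError("need 0 < band_low_px < band_high_px")
        if self.max_jump_px <= 0:
            raise ValueError("max_jump_px must be positive")


@dataclass(frozen=True)
class ClassifierConfig:
    """Trajectory lifetime-range classifier parameters.

    ``threshold_ns`` defaults to the published control-derived value
    (0.39 ns); pipelines on synthetic data recompute it from their own
    controls via ``delta_stats``.
    """

    threshold_ns: float = 0.39
    smoothing_window: int = 3
    sampling_radius_px: float = 3.0
    min_track_length: int = 10

    def __post_init__(self) -> None:
        if self.threshold_ns <= 0:
            raise ValueError("threshold_ns must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.sampling_radius_px < 0:
            raise ValueError("sampling_radius_px must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline run: every stage parameter plus the master seed."""

    acquisition: AcquisitionConfig = field(default_factory=rapid_flim)
    scene: SceneConfig = field(default_factory=SceneConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    name: str = "run"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return _as_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            acquisition=_from_mapping(AcquisitionConfig, d.get("acquisition", {})),
            scene=_from_mapping(SceneConfig, d.get("scene", {})),
            tracker=_from_mapping(TrackerConfig, d.get("tracker", {})),
            classifier=_from_mapping(ClassifierConfig, d.get("classifier", {})),
            seed=int(d.get("seed", 0)),
            name=str(d.get("name", "run")),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _as_plain(obj: Any) -> Any:
    """Recursively convert tuples/numpy scalars to YAML-safe plain types."""
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


_TUPLE_FIELDS = {"frame_shape", "size_window_px", "cell_radius_px", "nucleus_radius_px"}


def _from_mapping(cls, d: dict[str, Any]):
    kwargs = {}
    names = {f.name for f in dataclasses.fields(cls)}
    for k, v in d.items():
        if k not in names:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        kwargs[k] = tuple(v) if k in _TUPLE_FIELDS and v is not None else v
    return cls(**kwargs)
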
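"""Render ground-truth scenes into photon-level TCSPC movies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .detector import PixelDecay, simulate_frame_photons
from .scene import CODE_LABELS, CompartmentMap, GroundTruth

__all__ = ["DecayMovie", "render_movie"]


@dataclass
class DecayMovie:
    """Stack of per-pixel micro-time histograms: (frames, rows, cols, bins)."""

    counts: np.ndarray
    config: AcquisitionConfig
    ground_truth: GroundTruth | None = None
    frame_times_s: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.ndim != 4:
            raise ValueError("counts must be (frames, rows, cols, bins)")
        if self.counts.shape[-1] != self.config.n_microtime_bins:
            raise ValueError("last axis must match n_microtime_bins")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.n_frames) * self.config.frame_interval_s

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1], self.counts.shape[2]

    def pixel_decay(self, frame: int, row: int, col: int) -> PixelDecay:
        return PixelDecay(self.counts[frame, row, col], pixel=(row, col), frame=frame)

    def total_photons(self) -> int:
        return int(self.counts.sum(dtype=np.int64))


def _psf_weights(x: float, y: float, sigma: float, shape, trunc: float = 4.0):
    """Gaussian PSF sampled at pixel centers in a truncated window.

    Returns (rows, cols, weights); weights sum to the in-frame fraction of a
    unit-integral PSF, so off-frame emission is genuinely lost.
    """
    r = int(np.ceil(trunc * sigma))
    r0 = max(0, int(np.floor(y)) - r)
    r1 = min(shape[0] - 1, int(np.ceil(y)) + r)
    c0 = max(0, int(np.floor(x)) - r)
    c1 = min(shape[1] - 1, int(np.ceil(x)) + r)
    if r1 < r0 or c1 < c0:
        return None
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    w = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))
    w /= 2.0 * np.pi * sigma**2
    return slice(r0, r1 + 1), slice(c0, c1 + 1), w


def render_movie(
    ground_truth: GroundTruth,
    compartment_map: CompartmentMap,
    config: AcquisitionConfig,
    *,
    psf_sigma_px: float = 1.0,
    photons_per_particle_frame: float = 2500.0,
    background_rate_per_pulse: float = 0.004,
    background_lifetimes_ns: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> DecayMovie:
    """Simulate the TCSPC movie a camera-free scanning system would record.

    Each in-bounds particle contributes a Gaussian-PSF-weighted emission rate
    at its own true lifetime; the background emits at the compartment's
    lifetime.  Each pixel's single effective lifetime is the emission-rate
    weighted mean of its contributions, and photons are then drawn through
    the dead-time detector model (Poisson emission: a pixel integrates many
    emitters).  An empty ground truth yields a background-only movie.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = compartment_map.shape
    n_frames = ground_truth.n_frames if len(ground_truth.table) else 1
    n_pulses = config.pulses_per_pixel

    if background_lifetimes_ns is None:
        from .config import DEFAULT_LIFETIMES_NS

        background_lifetimes_ns = DEFAULT_LIFETIMES_NS
    bg_tau = np.empty(shape)
    for code in np.unique(compartment_map.labels):
        bg_tau[compartment_map.labels == code] = background_lifetimes_ns[CODE_LABELS[int(code)]]

    has_tau = "tau_ns" in ground_truth.table.columns
    if len(ground_truth.table) and not has_tau:
        raise ValueError("ground truth has no lifetimes; run assign_lifetimes first")

    frames = np.zeros((n_frames, *shape, config.n_microtime_bins), dtype=np.uint16)
    per_pulse_particle = photons_per_particle_frame / n_pulses
    table = ground_truth.table
    for f in range(n_frames):
        rate = np.full(shape, background_rate_per_pulse, dtype=float)
        tau_weighted = background_rate_per_pulse * bg_tau.copy()
        if len(table):
            sub = table[(table["frame"] == f) & table["in_bounds"]]
            for _, row in sub.iterrows():
                psf = _psf_weights(row["x"], row["y"], psf_sigma_px, shape)
                if psf is None:
                    continue
                rs, cs, w = psf
                contrib = per_pulse_particle * w
                rate[rs, cs] += contrib
                tau_weighted[rs, cs] += contrib * row["tau_ns"]
        tau_map = np.where(rate > 0, tau_weighted / np.maximum(rate, 1e-300), 1.0)
        counts = simulate_frame_photons(rate, tau_map, config, rng)
        frames[f] = counts.astype(np.uint16)
    return DecayMovie(counts=frames, config=config, ground_truth=ground_truth)
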
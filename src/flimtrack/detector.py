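"""Pulse-by-pulse TCSPC photon emission and dead-time detection.

The simulator works in nanoseconds internally.  Each excitation pulse excites
the pixel's fluorophores; photons are emitted at ``irf_center + Exp(tau) +
N(0, irf_sigma)`` after the pulse and wrapped into one pulse period (the
micro-time).  A non-paralyzable detector then records a photon only if it is
not within ``dead_time`` of the previous *recorded* photon; with
``sync_rearm`` the detector additionally waits for the next excitation pulse
before re-arming, which models start-stop timing electronics that perform at
most one conversion per sync period.

Two emission models are available.  ``"binomial"`` emits at most one photon
per pulse with probability equal to the emission rate - a single emitter
cannot yield two photons from one excitation.  ``"poisson"`` draws a Poisson
photon number per pulse - the ensemble regime in which several photons can
compete within one dead-time window, the mechanism behind pileup skew.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NS, AcquisitionConfig

__all__ = [
    "PixelDecay",
    "emit_photons",
    "apply_dead_time",
    "simulate_pixel_photons",
    "simulate_frame_photons",
    "detected_count_rate",
    "expected_mean_arrival",
    "wrapped_decay_cdf",
]


@dataclass
class PixelDecay:
    """Micro-time photon histogram for one pixel: the measured decay I(t)."""

    counts: np.ndarray
    pixel: tuple[int, int] = (0, 0)
    frame: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def emit_photons(
    rate: float,
    tau_ns: float,
    n_pulses: int,
    config: AcquisitionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw emitted photon times for ``n_pulses`` excitation pulses.

    Returns ``(abs_times_ns, micro_times_ns)`` sorted by absolute time.
    ``rate`` is photons per pulse: a probability for the binomial model
    (must be <= 1) or a Poisson mean.
    """
    if rate < 0:
        raise ValueError("emission rate must be >= 0")
    if tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    period = config.pulse_period_ns
    if config.emission_model == "binomial":
        if rate > 1.0:
            raise ValueError("binomial emission rate is a probability; got > 1")
        pulse_idx = np.nonzero(rng.random(n_pulses) < rate)[0]
    else:
        k = rng.poisson(rate, n_pulses)
        pulse_idx = np.repeat(np.arange(n_pulses), k)
    n = pulse_idx.size
    t = rng.exponential(tau_ns, n) + config.irf_center_s / NS
    if config.irf_sigma_s > 0:
        t += rng.normal(0.0, config.irf_sigma_s / NS, n)
    micro = np.mod(t, period)
    abs_t = pulse_idx * period + micro
    order = np.argsort(abs_t, kind="stable")
    return abs_t[order], micro[order]


def apply_dead_time(
    abs_times_ns: np.ndarray,
    config: AcquisitionConfig,
    *,
    reset_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of photons that survive the non-paralyzable dead time.

    ``reset_idx`` marks positions where an independent photon stream begins
    (used to batch many pixels into one call); the detector state is reset
    there.
    """
    dead = config.dead_time_s / NS
    period = config.pulse_period_ns
    n = abs_times_ns.size
    keep = np.zeros(n, dtype=bool)
    if n == 0:
        return keep
    if dead == 0:
        keep[:] = True
        return keep
    resets = np.zeros(n, dtype=bool)
    if reset_idx is not None:
        resets[reset_idx] = True
    sync = config.sync_rearm
    armed_at = -np.inf
    t = abs_times_ns
    for i in range(n):
        if resets[i]:
            armed_at = -np.inf
        if t[i] >= armed_at:
            keep[i] = True
            end = t[i] + dead
            armed_at = np.ceil(end / period) * period if sync else end
    return keep


def simulate_pixel_photons(
    emission_rate_per_pulse: float,
    tau_true_ns: float,
    config: AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    *,
    n_pulses: int | None = None,
    pixel: tuple[int, int] = (0, 0),
    frame: int = 0,
) -> PixelDecay:
    """Simulate one pixel's TCSPC acquisition and histogram the micro-times.

    ``n_pulses`` defaults to the per-pixel dwell (``dwell_time * rep_rate``).
    Saturating rates are allowed; the recorded count rate then reflects the
    detector's dead-time ceiling rather than the emission rate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_pulses is None:
        n_pulses = config.pulses_per_pixel
    abs_t, micro = emit_photons(emission_rate_per_pulse, tau_true_ns, n_pulses, config, rng)
    keep = apply_dead_time(abs_t, config)
    counts = _histogram_micro(micro[keep], config)
    return PixelDecay(counts=counts, pixel=pixel, frame=frame)


def _histogram_micro(micro_ns: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    period = config.pulse_period_ns
    nbins = config.n_microtime_bins
    idx = np.minimum((micro_ns / period * nbins).astype(np.intp), nbins - 1)
    return np.bincount(idx, minlength=nbins)


def simulate_frame_photons(
    rate_map: np.ndarray,
    tau_map_ns: np.ndarray,
    config: AcquisitionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate every pixel of one frame in a single batched pass.

    ``rate_map`` holds emitted photons/pulse per pixel (Poisson emission:
    each pixel integrates many emitters plus background) and ``tau_map_ns``
    the pixel's lifetime.  Returns a ``(rows, cols, n_microtime_bins)``
    uint32 count array.  Statistically identical to calling
    ``simulate_pixel_photons`` per pixel with the Poisson model; pixels are
    independent detector streams.
    """
    rows, cols = rate_map.shape
    npix = rows * cols
    n_pulses = config.pulses_per_pixel
    period = config.pulse_period_ns
    rate_flat = rate_map.reshape(npix)
    tau_flat = tau_map_ns.reshape(npix)

    # photon count per (pixel, pulse), flattened pixel-major so that the
    # dead-time pass sees each pixel's photons contiguously and time-ordered
    k_per_pulse = rng.poisson(np.repeat(rate_flat, n_pulses))
    pix_of_photon = np.repeat(np.arange(npix), k_per_pulse.reshape(npix, n_pulses).sum(axis=1))
    pulse_of_photon = np.repeat(
        np.tile(np.arange(n_pulses), npix), k_per_pulse
    )
    n = pix_of_photon.size
    if n == 0:
        return np.zeros((rows, cols, config.n_microtime_bins), dtype=np.uint32)
    t = rng.exponential(1.0, n) * tau_flat[pix_of_photon] + config.irf_center_s / NS
    if config.irf_sigma_s > 0:
        t += rng.normal(0.0, config.irf_sigma_s / NS, n)
    micro = np.mod(t, period)
    abs_t = pulse_of_photon * period + micro
    # sort within each pixel by absolute time
    order = np.lexsort((abs_t, pix_of_photon))
    pix_of_photon = pix_of_photon[order]
    abs_t = abs_t[order]
    micro = micro[order]
    reset_idx = np.nonzero(np.diff(pix_of_photon, prepend=-1) != 0)[0]
    keep = apply_dead_time(abs_t, config, reset_idx=reset_idx)

    nbins = config.n_microtime_bins
    bin_idx = np.minimum((micro[keep] / period * nbins).astype(np.intp), nbins - 1)
    flat = np.zeros(npix * nbins, dtype=np.uint32)
    np.add.at(flat, pix_of_photon[keep] * nbins + bin_idx, 1)
    return flat.reshape(rows, cols, nbins)


def detected_count_rate(
    emission_rate_per_pulse: float,
    tau_ns: float,
    config: AcquisitionConfig,
    n_pulses: int,
    seed: int | np.random.Generator = 0,
) -> float:
    """Sustained detected count rate (counts/s) over ``n_pulses`` pulses."""
    decay = simulate_pixel_photons(
        emission_rate_per_pulse, tau_ns, config, seed, n_pulses=n_pulses
    )
    elapsed_s = n_pulses * config.pulse_period_s
    return decay.total / elapsed_s


def calibrate_emission_rate(
    target_cps: float,
    tau_ns: float,
    config: AcquisitionConfig,
    seed: int | np.random.Generator = 0,
    *,
    n_pulses: int = 200_000,
    tol: float = 0.01,
) -> float:
    """Emission rate per pulse that sustains ``target_cps`` detected counts/s.

    Emulates an operator attenuating excitation while watching the count-rate
    meter: bisection on the emission rate against simulated detected rates,
    to a relative tolerance ``tol``.  Useful to set up the classic-FLIM
    "detected rate below 10% of the repetition rate" operating point.
    """
    if target_cps <= 0 or target_cps >= config.rep_rate_hz:
        raise ValueError("target rate must lie in (0, rep_rate)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = 0.0, 1.0
    # expand upper bound if the model allows super-unit rates (poisson)
    while (
        detected_count_rate(hi, tau_ns, config, n_pulses, rng) < target_cps
        and config.emission_model == "poisson"
        and hi < 64
    ):
        hi *= 2
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        rate = detected_count_rate(mid, tau_ns, config, n_pulses, rng)
        if abs(rate - target_cps) <= tol * target_cps:
            return mid
        if rate < target_cps:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def expected_mean_arrival(tau_ns: float, period_ns: float, irf_center_ns: float = 0.0) -> float:
    """Exact mean micro-time of a wrapped monoexponential decay.

    For a decay starting at micro-time ``t0`` within a period ``T``::

        E[t] = t0 + tau - T * exp(t0/tau) / (exp(T/tau) - 1)

    which reduces to the classic truncated-exponential mean
    ``tau - T/(exp(T/tau) - 1)`` at ``t0 = 0``.
    """
    if tau_ns <= 0:
        raise ValueError("tau_ns must be positive")
    r = period_ns / tau_ns
    if r > 700.0:  # tail term underflows: effectively untruncated decay
        return irf_center_ns + tau_ns
    # expm1 keeps the tail term accurate for moderate tau << T
    return irf_center_ns + tau_ns - period_ns * np.exp(irf_center_ns / tau_ns) / np.expm1(r)


def wrapped_decay_cdf(
    t_ns: np.ndarray,
    tau_ns: float,
    period_ns: float,
    irf_center_ns: float = 0.0,
    irf_sigma_ns: float = 0.0,
    n_grid: int = 20001,
) -> np.ndarray:
    """CDF of the wrapped (IRF-convolved) monoexponential micro-time density.

    Computed on a fine grid by summing the exponential tail over wrap periods
    and, if ``irf_sigma_ns > 0``, convolving with the Gaussian IRF.  Serves
    as the analytic reference distribution for goodness-of-fit checks of the
    photon simulator at zero dead time.
    """
    grid = np.linspace(0.0, period_ns, n_grid)
    dens = np.zeros_like(grid)
    # sum enough wraps to cover the decay tail
    n_wraps = max(3, int(np.ceil(10 * tau_ns / period_ns)) + 2)
    if irf_sigma_ns == 0:
        for k in range(n_wraps):
            arg = grid - irf_center_ns + k * period_ns
            dens += np.where(arg >= 0, np.exp(-np.clip(arg, 0, None) / tau_ns), 0.0) / tau_ns
    else:
        from scipy.stats import exponnorm

        # exponentially modified Gaussian: Exp(tau) + N(0, sigma), shifted
        K = tau_ns / irf_sigma_ns
        for k in range(-2, n_wraps):
            arg = grid - irf_center_ns + k * period_ns
            dens += exponnorm.pdf(arg, K, loc=0.0, scale=irf_sigma_ns)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(np.asarray(t_ns, dtype=float), grid, cdf)
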
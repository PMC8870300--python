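"""First-harmonic phasor analysis of per-pixel decays.

Each decay I(t) maps to the point

    G = integral I(t) cos(wt) dt / integral I(t) dt
    S = integral I(t) sin(wt) dt / integral I(t) dt

with w = 2 pi f the angular repetition frequency.  Discrete sums are taken
at micro-time bin centers.  Monoexponential decays fall on the universal
semicircle (G - 1/2)^2 + S^2 = 1/4, at the closed-form point
G = 1/(1+(w tau)^2), S = w tau G; mixtures lie on the chord between their
components because the transform is linear in the (additive) decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NS, AcquisitionConfig
from .detector import PixelDecay
from .movie import DecayMovie

__all__ = [
    "PhasorPoint",
    "PhasorGate",
    "phasor_transform",
    "phasor_coordinates",
    "phasor_cloud",
    "gate_fractions",
]


@dataclass(frozen=True)
class PhasorPoint:
    G: float
    S: float
    pixel: tuple[int, int] = (0, 0)
    frame: int = 0
    counts: int = 0


@dataclass(frozen=True)
class PhasorGate:
    """Circular gate in phasor space (the published gates are colored blobs
    of unstated geometry; circles with configurable center/radius stand in)."""

    name: str
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("gate radius must be positive")

    def contains(self, G, S):
        return (np.asarray(G) - self.center[0]) ** 2 + (
            np.asarray(S) - self.center[1]
        ) ** 2 <= self.radius**2

    def overlaps(self, other: "PhasorGate") -> bool:
        d = np.hypot(
            self.center[0] - other.center[0], self.center[1] - other.center[1]
        )
        return d < self.radius + other.radius


def phasor_coordinates(tau_ns: float, config: AcquisitionConfig) -> tuple[float, float]:
    """Closed-form semicircle point for a monoexponential lifetime."""
    wt = config.angular_freq * tau_ns * NS
    g = 1.0 / (1.0 + wt**2)
    return g, wt * g


def phasor_transform(
    decay: PixelDecay | np.ndarray,
    config: AcquisitionConfig,
    *,
    pixel: tuple[int, int] = (0, 0),
    frame: int = 0,
) -> PhasorPoint:
    """Phasor point of one decay histogram; raises on zero total counts."""
    counts = decay.counts if isinstance(decay, PixelDecay) else np.asarray(decay)
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("cannot phasor-transform a decay with zero counts")
    period = config.pulse_period_ns
    centers = (np.arange(counts.size) + 0.5) * (period / counts.size)
    phase = config.angular_freq * centers * NS
    g = float(counts @ np.cos(phase)) / total
    s = float(counts @ np.sin(phase)) / total
    return PhasorPoint(G=g, S=s, pixel=pixel, frame=frame, counts=int(total))


def phasor_cloud(
    movie: DecayMovie,
    min_photons: int | None = None,
) -> pd.DataFrame:
    """One phasor point per qualifying pixel per frame.

    Returns a DataFrame (frame, row, col, G, S, counts); empty, with a
    warning, if no pixel reaches ``min_photons``.
    """
    config = movie.config
    if min_photons is None:
        min_photons = config.min_photons
    nbins = config.n_microtime_bins
    period = config.pulse_period_ns
    centers = (np.arange(nbins) + 0.5) * (period / nbins)
    phase = config.angular_freq * centers * NS
    cosb, sinb = np.cos(phase), np.sin(phase)

    rows = []
    for f in range(movie.n_frames):
        frame = movie.counts[f].astype(float)
        total = frame.sum(axis=-1)
        mask = total >= max(min_photons, 1)
        if not mask.any():
            continue
        rr, cc = np.nonzero(mask)
        sel = frame[mask]
        g = (sel @ cosb) / total[mask]
        s = (sel @ sinb) / total[mask]
        rows.append(
            pd.DataFrame(
                {"frame": f, "row": rr, "col": cc, "G": g, "S": s, "counts": total[mask]}
            )
        )
    if not rows:
        import warnings

        warnings.warn("phasor cloud is empty: no pixel reached min_photons")
        return pd.DataFrame(columns=["frame", "row", "col", "G", "S", "counts"])
    return pd.concat(rows, ignore_index=True)


def gate_fractions(
    cloud: pd.DataFrame,
    gates: list[PhasorGate],
    frames: list[int] | None = None,
) -> pd.DataFrame:
    """Per-frame fraction of phasor points falling in each (disjoint) gate.

    Fractions over {gates..., unassigned} sum to 1 per frame.  Raises if any
    two gates overlap.
    """
    for i, a in enumerate(gates):
        for b in gates[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"gates {a.name!r} and {b.name!r} overlap")
    if frames is None:
        frames = sorted(cloud["frame"].unique())
    out = []
    for f in frames:
        sub = cloud[cloud["frame"] == f]
        n = len(sub)
        row: dict[str, float] = {"frame": f, "n_points": n}
        assigned = np.zeros(n, dtype=bool)
        for gate in gates:
            inside = gate.contains(sub["G"].to_numpy(), sub["S"].to_numpy())
            row[gate.name] = inside.sum() / n if n else np.nan
            assigned |= inside
        row["unassigned"] = (~assigned).sum() / n if n else np.nan
        out.append(row)
    return pd.DataFrame(out)
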
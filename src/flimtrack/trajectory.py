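"""Per-trajectory lifetime series and the lifetime-range classifier.

The pipeline's core statistic: each track samples a lifetime per frame from
the two-channel images (intensity-weighted over a small neighborhood), the
series is smoothed with a centered moving median, and the track is called
*above threshold* when the smoothed lifetime range (max - min) strictly
exceeds the mean frame-to-frame |delta lifetime| measured on control tracks
(particles embedded in a homogeneous gel, where any variation is
measurement noise).  Above-threshold tracks flag a changing molecular
environment along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassifierConfig
from .flim import LifetimeImage
from .scene import CompartmentMap, GroundTruth, LABEL_CODES, _edge_band
from .tracking import Track

__all__ = [
    "DeltaLifetimeStats",
    "sample_track_lifetimes",
    "smooth",
    "delta_stats",
    "classify",
    "classify_tracks",
    "boundary_report",
    "match_tracks_to_truth",
    "expected_labels_from_truth",
]


@dataclass
class DeltaLifetimeStats:
    """Pooled frame-to-frame |delta tau| from control tracks.

    ``mean_delta_ns`` is the classification threshold; ``n`` counts the
    pooled deltas (sum of track_length-1 over fully defined tracks).
    """

    deltas_ns: np.ndarray
    mean_delta_ns: float
    n: int

    @classmethod
    def from_deltas(cls, deltas: np.ndarray) -> "DeltaLifetimeStats":
        deltas = np.asarray(deltas, dtype=float)
        return cls(deltas_ns=deltas, mean_delta_ns=float(deltas.mean()), n=deltas.size)


def sample_track_lifetimes(
    track: Track,
    lifetime_images: dict[int, LifetimeImage] | list[LifetimeImage],
    sampling_radius_px: float = 3.0,
) -> np.ndarray:
    """Per-frame lifetime along a track (ns); NaN where no defined pixel lies
    within ``sampling_radius_px`` of the sub-pixel position.

    The sample is the intensity-weighted mean of defined-lifetime pixels in
    the disk, so bright particle pixels dominate dim surroundings.  Raises if
    no track frame exists in the image stack.
    """
    if isinstance(lifetime_images, list):
        images = {img.frame_index: img for img in lifetime_images}
    else:
        images = lifetime_images
    have = [d.frame in images for d in track.detections]
    if not any(have):
        raise ValueError("track lies entirely outside the image stack")
    out = np.full(len(track), np.nan)
    r_int = int(np.floor(sampling_radius_px))
    for i, det in enumerate(track.detections):
        img = images.get(det.frame)
        if img is None:
            continue
        rows, cols = img.shape
        r0 = max(0, int(round(det.y)) - r_int - 1)
        r1 = min(rows - 1, int(round(det.y)) + r_int + 1)
        c0 = max(0, int(round(det.x)) - r_int - 1)
        c1 = min(cols - 1, int(round(det.x)) + r_int + 1)
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        disk = (xx - det.x) ** 2 + (yy - det.y) ** 2 <= sampling_radius_px**2
        tau = img.lifetime_ns[r0 : r1 + 1, c0 : c1 + 1]
        inten = img.intensity[r0 : r1 + 1, c0 : c1 + 1]
        ok = disk & ~np.isnan(tau)
        if not ok.any():
            continue
        w = inten[ok]
        out[i] = float((tau[ok] * w).sum() / w.sum())
    return out


def smooth(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving median; endpoints with incomplete windows pass through.

    Undefined (NaN) entries are excluded from each window's median and stay
    NaN in the output (skipped, never interpolated).  An all-NaN series is
    returned unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    n = x.size
    half = window // 2
    if window == 1 or n <= 2 * half:
        return x.copy()
    y = x.copy()
    for i in range(half, n - half):
        if np.isnan(x[i]):
            continue
        win = x[i - half : i + half + 1]
        vals = win[~np.isnan(win)]
        if vals.size:
            y[i] = float(np.median(vals))
    return y


def delta_stats(series_list: list[np.ndarray]) -> DeltaLifetimeStats:
    """Pool |tau_{i+1} - tau_i| over consecutive defined pairs of control tracks.

    The mean of the pooled absolute deltas is the classification threshold.
    Raises if no valid consecutive pair exists.
    """
    deltas = []
    for s in series_list:
        s = np.asarray(s, dtype=float)
        ok = ~np.isnan(s)
        pair = ok[:-1] & ok[1:]
        if pair.any():
            deltas.append(np.abs(np.diff(s))[pair])
    if not deltas:
        raise ValueError("no consecutive defined lifetime pairs in control tracks")
    return DeltaLifetimeStats.from_deltas(np.concatenate(deltas))


def classify(track: Track, config: ClassifierConfig) -> str:
    """Label a track by its smoothed lifetime range vs the threshold.

    Requires ``lifetimes_ns`` to be present; fills ``smoothed_ns``,
    ``lifetime_range_ns`` and ``label``.  Tracks shorter than
    ``min_track_length`` or with fewer than two defined smoothed entries are
    ``unclassified``.  The comparison is strict: a range exactly equal to
    the threshold stays below.
    """
    if track.lifetimes_ns is None:
        raise ValueError("track has no sampled lifetimes")
    track.smoothed_ns = smooth(track.lifetimes_ns, config.smoothing_window)
    defined = track.smoothed_ns[~np.isnan(track.smoothed_ns)]
    if len(track) < config.min_track_length or defined.size < 2:
        track.label = "unclassified"
        track.lifetime_range_ns = np.nan
        return track.label
    track.lifetime_range_ns = float(defined.max() - defined.min())
    track.label = (
        "above_threshold"
        if track.lifetime_range_ns > config.threshold_ns
        else "below_threshold"
    )
    return track.label


def classify_tracks(
    tracks: list[Track],
    lifetime_images: list[LifetimeImage],
    config: ClassifierConfig,
    threshold_ns: float | None = None,
) -> list[Track]:
    """Sample, smooth and classify every track in place.

    ``threshold_ns`` overrides the config value (e.g. a threshold recomputed
    from this experiment's own controls).
    """
    cfg = config
    if threshold_ns is not None:
        import dataclasses

        cfg = dataclasses.replace(config, threshold_ns=threshold_ns)
    images = {img.frame_index: img for img in lifetime_images}
    for t in tracks:
        t.lifetimes_ns = sample_track_lifetimes(t, images, cfg.sampling_radius_px)
        classify(t, cfg)
    return tracks


def boundary_report(
    tracks: list[Track],
    compartment_map: CompartmentMap,
    band_px: float = 3.0,
) -> dict:
    """Localization of classified tracks relative to compartment boundaries.

    Each track is assigned the zone (boundary band vs interior) of its median
    position, where the band collects pixels within ``band_px/2`` of the
    membrane or nuclear interface.  Reports per-class zone counts and
    fractions plus the odds ratio of above-threshold tracks lying in the
    band; complete separation is flagged with an infinite odds ratio.
    """
    if band_px <= 0:
        raise ValueError("band_px must be positive")
    labels = compartment_map.labels
    cell = labels != LABEL_CODES["extracellular"]
    nucleus = labels == LABEL_CODES["nucleus"]
    band = _edge_band(cell, band_px)
    if nucleus.any():
        band |= _edge_band(nucleus, band_px)

    counts = {
        "above_threshold": {"boundary": 0, "interior": 0},
        "below_threshold": {"boundary": 0, "interior": 0},
    }
    zones: dict[int, str] = {}
    for t in tracks:
        if t.label not in counts:
            continue
        x, y = t.median_position()
        r = int(np.clip(round(y), 0, labels.shape[0] - 1))
        c = int(np.clip(round(x), 0, labels.shape[1] - 1))
        zone = "boundary" if band[r, c] else "interior"
        zones[t.id] = zone
        counts[t.label][zone] += 1

    a = counts["above_threshold"]["boundary"]
    b = counts["above_threshold"]["interior"]
    c_ = counts["below_threshold"]["boundary"]
    d = counts["below_threshold"]["interior"]
    if b == 0 or c_ == 0:
        odds = np.inf if (a > 0 and d > 0) else np.nan
        separation = a > 0 and d > 0
    else:
        odds = (a / b) / (c_ / d)
        separation = False
    fractions = {
        lab: {
            z: (counts[lab][z] / max(1, sum(counts[lab].values())))
            for z in ("boundary", "interior")
        }
        for lab in counts
    }
    return {
        "counts": counts,
        "fractions": fractions,
        "odds_ratio": float(odds) if np.isfinite(odds) else odds,
        "complete_separation": bool(separation),
        "zones": zones,
        "band_px": band_px,
    }


def match_tracks_to_truth(
    tracks: list[Track], ground_truth: GroundTruth, tol_px: float = 2.0
) -> dict[int, int | None]:
    """Map each track to the ground-truth particle it follows (majority vote
    of nearest true positions within ``tol_px``), or None if unmatched."""
    gt = ground_truth.table
    by_frame = {f: g for f, g in gt.groupby("frame")}
    out: dict[int, int | None] = {}
    for t in tracks:
        votes: dict[int, int] = {}
        for det in t.detections:
            g = by_frame.get(det.frame)
            if g is None or not len(g):
                continue
            d2 = (g["x"].to_numpy() - det.x) ** 2 + (g["y"].to_numpy() - det.y) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= tol_px**2:
                pid = int(g["particle"].to_numpy()[j])
                votes[pid] = votes.get(pid, 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: kv[1])
            out[t.id] = best[0] if best[1] >= max(1, len(t) // 2) else None
        else:
            out[t.id] = None
    return out


def expected_labels_from_truth(
    ground_truth: GroundTruth,
    config: ClassifierConfig,
    threshold_ns: float,
) -> dict[int, str]:
    """Noise-free reference label per particle: smooth the *true* lifetime
    series with the classifier's own rule and compare its range to the
    threshold.  This is the label a perfect measurement would produce."""
    if "tau_ns" not in ground_truth.table.columns:
        raise ValueError("ground truth has no lifetimes; run assign_lifetimes first")
    out = {}
    for pid, g in ground_truth.table.groupby("particle"):
        tau = g.sort_values("frame")["tau_ns"].to_numpy(float)
        sm = smooth(tau, config.smoothing_window)
        rng = float(np.nanmax(sm) - np.nanmin(sm))
        out[int(pid)] = "above_threshold" if rng > threshold_ns else "below_threshold"
    return out
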
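"""Sub-pixel particle detection and frame-to-frame linking.

The stage mirrors the semantics of commercial trackers configured with a
spatial band-pass (here 0.75-1 px by default), a spot-size acceptance window
for the fitted Gaussian width, a minimum spot brightness, and a hard maximum
jump between consecutive frames.  Linking is a per-frame-pair globally
optimal one-to-one assignment minimizing summed squared displacement among
candidate pairs within the jump limit; there is no gap closing, merging or
splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares, linear_sum_assignment
from skimage.feature import peak_local_max

from .config import TrackerConfig

__all__ = ["Detection", "Track", "preprocess", "detect", "link", "tracks_to_table", "table_to_tracks"]


@dataclass(frozen=True)
class Detection:
    """One sub-pixel spot: position, frame, integrated brightness, fitted width."""

    x: float
    y: float
    frame: int
    brightness: float
    sigma_px: float


@dataclass
class Track:
    """Linked detections on consecutive frames, plus per-frame lifetime data.

    ``lifetimes_ns``/``smoothed_ns`` are filled by the trajectory-lifetime
    stage; undefined entries are NaN.  ``label`` is one of
    ``below_threshold`` / ``above_threshold`` / ``unclassified``.
    """

    id: int
    detections: list[Detection]
    lifetimes_ns: np.ndarray | None = None
    smoothed_ns: np.ndarray | None = None
    lifetime_range_ns: float = np.nan
    label: str = "unclassified"

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([(d.x, d.y) for d in self.detections])

    def median_position(self) -> tuple[float, float]:
        p = self.positions
        return float(np.median(p[:, 0])), float(np.median(p[:, 1]))


def preprocess(
    frame: np.ndarray,
    band_low_px: float = 0.75,
    band_high_px: float = 1.0,
    *,
    background_sigma_factor: float = 4.0,
) -> np.ndarray:
    """Background-subtracted band-pass of one intensity frame.

    Difference of Gaussians: smooth at ``band_low_px`` (suppresses
    sub-spot-scale noise) minus smooth at ``background_sigma_factor *
    band_high_px`` (the large-scale background estimate).  Constant offsets
    and smooth gradients vanish; spots in the band survive.
    """
    if not 0 < band_low_px < band_high_px:
        raise ValueError("need 0 < band_low_px < band_high_px")
    img = np.asarray(frame, dtype=float)
    lo = gaussian_filter(img, band_low_px, mode="nearest")
    bg = gaussian_filter(img, background_sigma_factor * band_high_px, mode="nearest")
    return lo - bg


def _fit_gaussian_spot(img: np.ndarray, r0: int, c0: int, win: int = 3):
    """2-D Gaussian least-squares refinement in a (2*win+1)^2 window.

    Returns (x, y, brightness, sigma) or None if the fit leaves the window.
    Brightness is the integrated Gaussian volume 2*pi*A*sigma^2.
    """
    rows, cols = img.shape
    rlo, rhi = max(0, r0 - win), min(rows, r0 + win + 1)
    clo, chi = max(0, c0 - win), min(cols, c0 + win + 1)
    patch = img[rlo:rhi, clo:chi].astype(float)
    yy, xx = np.mgrid[rlo:rhi, clo:chi]
    base = float(patch.min())
    amp0 = float(patch.max() - base)
    if amp0 <= 0:
        return None

    def resid(p):
        a, x, y, s, off = p
        model = off + a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * s**2))
        return (model - patch).ravel()

    p0 = np.array([amp0, c0, r0, 1.0, base])
    lower = [0.0, clo - 1, rlo - 1, 0.2, -np.inf]
    upper = [np.inf, chi, rhi, 2 * win, np.inf]
    try:
        sol = least_squares(resid, p0, bounds=(lower, upper), max_nfev=200)
    except ValueError:
        return None
    a, x, y, s, _ = sol.x
    if not (clo - 0.5 <= x <= chi - 0.5 and rlo - 0.5 <= y <= rhi - 0.5):
        return None
    brightness = 2.0 * np.pi * a * s**2
    return float(x), float(y), float(brightness), float(s)


def detect(
    filtered: np.ndarray,
    config: TrackerConfig,
    *,
    frame: int = 0,
    raw: np.ndarray | None = None,
) -> list[Detection]:
    """Detect sub-pixel spots in a preprocessed frame.

    Local maxima above a robust noise floor (``peak_snr`` median absolute
    deviations) are refined by 2-D Gaussian fits on the raw (or filtered)
    frame; detections are kept iff the fitted width lies in
    ``size_window_px`` and brightness >= ``brightness_min``.
    """
    lo, hi = config.size_window_px
    if not 0 < lo < hi:
        raise ValueError("invalid size window")
    img = np.asarray(filtered, dtype=float)
    fit_img = np.asarray(raw, dtype=float) if raw is not None else img
    noise = 1.4826 * np.median(np.abs(img - np.median(img)))
    thr = config.peak_snr * max(noise, 1e-12)
    peaks = peak_local_max(img, min_distance=2, threshold_abs=thr, exclude_border=False)
    out = []
    for r0, c0 in peaks:
        fit = _fit_gaussian_spot(fit_img, int(r0), int(c0))
        if fit is None:
            continue
        x, y, brightness, sigma = fit
        if not lo <= sigma <= hi:
            continue
        if brightness < config.brightness_min:
            continue
        if not (0 <= x <= img.shape[1] - 1 and 0 <= y <= img.shape[0] - 1):
            continue
        out.append(Detection(x=x, y=y, frame=frame, brightness=brightness, sigma_px=sigma))
    # canonical order: linking is then invariant to the caller's ordering
    out.sort(key=lambda d: (d.y, d.x))
    return out


def link(
    detections: list[Detection],
    max_jump_px: float,
    min_track_length: int = 10,
) -> list[Track]:
    """Link detections into tracks; discard tracks shorter than the minimum.

    For every consecutive frame pair the globally optimal one-to-one
    assignment (Hungarian algorithm on squared displacement) is computed over
    candidate pairs within ``max_jump_px``; unmatched detections end/start
    tracks.  Every emitted link is asserted to respect the jump limit.
    """
    if max_jump_px <= 0:
        raise ValueError("max_jump_px must be positive")
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for f in by_frame:
        by_frame[f] = sorted(by_frame[f], key=lambda d: (d.y, d.x))
    frames = sorted(by_frame)
    if not frames:
        return []

    BIG = 4.0 * max_jump_px**2 + 1e6
    open_tracks: dict[int, list[Detection]] = {}
    next_id = 0
    closed: list[list[Detection]] = []
    # tracks currently ending at a detection of the previous frame
    prev_dets: list[Detection] = by_frame[frames[0]]
    prev_track_ids: list[int] = []
    for d in prev_dets:
        open_tracks[next_id] = [d]
        prev_track_ids.append(next_id)
        next_id += 1

    for fprev, fcur in zip(frames, frames[1:]):
        cur = by_frame[fcur]
        if fcur != fprev + 1:
            # gap in frames: no gap closing - everything open ends here
            closed.extend(open_tracks.values())
            open_tracks = {}
            prev_dets, prev_track_ids = [], []
        matched_prev = set()
        matched_cur = set()
        if prev_dets and cur:
            p = np.array([(d.x, d.y) for d in prev_dets])
            q = np.array([(d.x, d.y) for d in cur])
            d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_jump_px**2, d2, BIG)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if d2[i, j] <= max_jump_px**2:
                    matched_prev.add(i)
                    matched_cur.add(j)
                    open_tracks[prev_track_ids[i]].append(cur[j])
        # close unmatched tracks
        new_open: dict[int, list[Detection]] = {}
        new_prev_ids: list[int] = []
        new_prev_dets: list[Detection] = []
        for i, tid in enumerate(prev_track_ids):
            if i not in matched_prev:
                closed.append(open_tracks.pop(tid))
        for j, det in enumerate(cur):
            if j in matched_cur:
                # find which track got this detection
                for tid, dets in open_tracks.items():
                    if dets[-1] is det:
                        new_open[tid] = dets
                        new_prev_ids.append(tid)
                        new_prev_dets.append(det)
                        break
            else:
                new_open[next_id] = [det]
                new_prev_ids.append(next_id)
                new_prev_dets.append(det)
                next_id += 1
        open_tracks = new_open
        prev_track_ids = new_prev_ids
        prev_dets = new_prev_dets

    closed.extend(open_tracks.values())
    tracks = []
    tid = 0
    # deterministic output order: by (first frame, y, x) of the first detection
    closed.sort(key=lambda dets: (dets[0].frame, dets[0].y, dets[0].x))
    for dets in closed:
        if len(dets) < min_track_length:
            continue
        for a, b in zip(dets, dets[1:]):
            jump = np.hypot(b.x - a.x, b.y - a.y)
            assert jump <= max_jump_px + 1e-9, "link exceeds max_jump_px"
        tracks.append(Track(id=tid, detections=list(dets)))
        tid += 1
    return tracks


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks to the interchange schema (track_id, frame, x, y, brightness)."""
    rows = [
        (t.id, d.frame, d.x, d.y, d.brightness)
        for t in tracks
        for d in t.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "brightness"])


def table_to_tracks(table: pd.DataFrame) -> list[Track]:
    """Rebuild tracks from an interchange table (e.g. an external tracker export)."""
    tracks = []
    for tid, g in table.groupby("track_id"):
        g = g.sort_values("frame")
        dets = [
            Detection(
                x=float(r.x),
                y=float(r.y),
                frame=int(r.frame),
                brightness=float(getattr(r, "brightness", 0.0) or 0.0),
                sigma_px=float(getattr(r, "sigma_px", np.nan) or np.nan),
            )
            for r in g.itertuples()
        ]
        tracks.append(Track(id=int(tid), detections=dets))
    return tracks
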
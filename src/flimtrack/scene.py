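"""Ground-truth scenes: compartment geometry, particle motion, lifetimes.

Coordinates are 0-based with pixel centers at integer positions, row-major:
``x`` indexes columns, ``y`` rows.  Diffusion coefficients are expressed in
px^2/frame; per-axis step variance over one frame interval is ``2 D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, uniform_filter1d

__all__ = [
    "LABEL_CODES",
    "CompartmentMap",
    "GroundTruth",
    "make_compartment_map",
    "uniform_compartment_map",
    "simulate_tracks",
    "assign_lifetimes",
]

#: integer codes used in the label image
LABEL_CODES = {"extracellular": 0, "cytoplasm": 1, "nucleus": 2}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class CompartmentMap:
    """Per-pixel compartment labels plus boundary-band masks.

    ``labels`` holds integer codes (see :data:`LABEL_CODES`); every pixel has
    exactly one label.  ``boundary_masks`` maps boundary names
    (``"membrane"``, ``"nuclear"``) to boolean band masks of the configured
    width centred on the compartment interface.
    """

    labels: np.ndarray
    boundary_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        for name, m in self.boundary_masks.items():
            if m.shape != self.labels.shape:
                raise ValueError(f"boundary mask {name!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_at(self, x: float, y: float) -> str:
        """Compartment label of the pixel containing (x, y), clipped to bounds."""
        r = int(np.clip(round(y), 0, self.labels.shape[0] - 1))
        c = int(np.clip(round(x), 0, self.labels.shape[1] - 1))
        return CODE_LABELS[int(self.labels[r, c])]

    def mask(self, label: str) -> np.ndarray:
        return self.labels == LABEL_CODES[label]

    def boundary_band(self) -> np.ndarray:
        """Union of all boundary bands (False everywhere if no boundaries)."""
        band = np.zeros(self.labels.shape, dtype=bool)
        for m in self.boundary_masks.values():
            band |= m
        return band


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    a, b = radii  # (x, y) semi-axes
    if a <= 0 or b <= 0:
        return np.zeros(shape, dtype=bool)
    return ((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2 <= 1.0


def _edge_band(inside: np.ndarray, width_px: float) -> np.ndarray:
    """Pixels whose Euclidean distance to the region edge is <= width/2."""
    if not inside.any() or inside.all():
        return np.zeros(inside.shape, dtype=bool)
    d_in = distance_transform_edt(inside)
    d_out = distance_transform_edt(~inside)
    half = width_px / 2.0
    return (inside & (d_in <= half)) | (~inside & (d_out <= half))


def make_compartment_map(
    frame_shape: tuple[int, int],
    cell_radius_px: float | tuple[float, float] = 26.0,
    nucleus_radius_px: float | tuple[float, float] = 8.0,
    *,
    cell_center: tuple[float, float] | None = None,
    nucleus_center: tuple[float, float] | None = None,
    boundary_width_px: float = 2.0,
) -> CompartmentMap:
    """Concentric cell geometry: elliptical cell containing an elliptical nucleus.

    Radii may be scalars (circles) or ``(x, y)`` semi-axes.  A zero nucleus
    radius yields a two-label map.  Raises if the nucleus is not strictly
    inside the cell.
    """
    rows, cols = frame_shape
    if rows <= 0 or cols <= 0:
        raise ValueError("frame_shape must be positive")
    cr = (cell_radius_px, cell_radius_px) if np.isscalar(cell_radius_px) else tuple(cell_radius_px)
    nr = (
        (nucleus_radius_px, nucleus_radius_px)
        if np.isscalar(nucleus_radius_px)
        else tuple(nucleus_radius_px)
    )
    cc = cell_center if cell_center is not None else ((cols - 1) / 2.0, (rows - 1) / 2.0)
    nc = nucleus_center if nucleus_center is not None else cc

    if max(nr) > 0:
        # nucleus boundary sampled and tested against the cell ellipse
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        bx = nc[0] + nr[0] * np.cos(th)
        by = nc[1] + nr[1] * np.sin(th)
        if np.any(((bx - cc[0]) / cr[0]) ** 2 + ((by - cc[1]) / cr[1]) ** 2 >= 1.0):
            raise ValueError("nucleus is not inside the cell")

    cell = _ellipse_mask(frame_shape, cc, cr)
    nucleus = _ellipse_mask(frame_shape, nc, nr) & cell
    labels = np.zeros(frame_shape, dtype=np.int8)
    labels[cell] = LABEL_CODES["cytoplasm"]
    labels[nucleus] = LABEL_CODES["nucleus"]

    masks = {"membrane": _edge_band(cell, boundary_width_px)}
    if nucleus.any():
        masks["nuclear"] = _edge_band(nucleus, boundary_width_px)
    return CompartmentMap(labels=labels, boundary_masks=masks)


def uniform_compartment_map(frame_shape: tuple[int, int], label: str = "extracellular") -> CompartmentMap:
    """Homogeneous medium (e.g. an agarose pad): one label, no boundaries."""
    labels = np.full(frame_shape, LABEL_CODES[label], dtype=np.int8)
    return CompartmentMap(labels=labels, boundary_masks={})


@dataclass
class GroundTruth:
    """True particle trajectories with per-frame lifetimes and compartments.

    ``table`` columns: particle, frame, x, y, in_bounds, compartment, tau_ns
    (the last two filled by :func:`assign_lifetimes`).
    """

    table: pd.DataFrame
    frame_shape: tuple[int, int]
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"particle", "frame", "x", "y", "in_bounds"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ground-truth table missing columns {sorted(missing)}")

    @property
    def n_particles(self) -> int:
        return self.table["particle"].nunique()

    @property
    def n_frames(self) -> int:
        return int(self.table["frame"].max()) + 1 if len(self.table) else 0

    def particle_series(self, pid: int) -> pd.DataFrame:
        return self.table[self.table["particle"] == pid].sort_values("frame")

    def true_links(self) -> set[tuple[int, int, int]]:
        """Set of (particle, frame, frame+1) links where both ends are in bounds."""
        links = set()
        for pid, g in self.table.groupby("particle"):
            g = g.sort_values("frame")
            frames = g["frame"].to_numpy()
            inb = g["in_bounds"].to_numpy()
            for i in range(len(frames) - 1):
                if frames[i + 1] == frames[i] + 1 and inb[i] and inb[i + 1]:
                    links.add((int(pid), int(frames[i]), int(frames[i + 1])))
        return links


def simulate_tracks(
    n_particles: int,
    motion_model: str,
    n_frames: int,
    *,
    diffusion_px2_per_frame: float,
    frame_shape: tuple[int, int],
    region_mask: np.ndarray | None = None,
    starts: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> GroundTruth:
    """Simulate Brownian trajectories, optionally confined to a region.

    ``motion_model="free"`` draws unconstrained Gaussian steps with per-axis
    variance ``2 D`` per frame; particles may leave the frame (flagged via
    ``in_bounds``).  ``"confined"`` keeps particles inside ``region_mask``
    by redrawing steps that would cross the wall (a reflecting-wall
    surrogate that preserves in-region step statistics).
    """
    if diffusion_px2_per_frame < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if motion_model not in ("free", "confined"):
        raise ValueError(f"unknown motion_model {motion_model!r}")
    if motion_model == "confined" and region_mask is None:
        raise ValueError("confined motion requires a region_mask")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = frame_shape
    step_sigma = float(np.sqrt(2.0 * diffusion_px2_per_frame))

    def inside(x: float, y: float) -> bool:
        if motion_model == "free":
            return True
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < region_mask.shape[0] and 0 <= c < region_mask.shape[1]):
            return False
        return bool(region_mask[r, c])

    if starts is None:
        starts = np.empty((n_particles, 2))
        for i in range(n_particles):
            for _ in range(10000):
                x = rng.uniform(0, cols - 1)
                y = rng.uniform(0, rows - 1)
                if inside(x, y):
                    starts[i] = (x, y)
                    break
            else:
                raise ValueError("could not place particle inside region")
    else:
        starts = np.asarray(starts, dtype=float)
        if starts.shape != (n_particles, 2):
            raise ValueError("starts must have shape (n_particles, 2)")

    records = []
    for pid in range(n_particles):
        x, y = starts[pid]
        for f in range(n_frames):
            if f > 0:
                for _ in range(50):  # redraw wall-crossing steps
                    dx, dy = rng.normal(0.0, step_sigma, 2)
                    if inside(x + dx, y + dy):
                        x, y = x + dx, y + dy
                        break
            inb = (0 <= x <= cols - 1) and (0 <= y <= rows - 1)
            records.append((pid, f, x, y, inb))
    table = pd.DataFrame(records, columns=["particle", "frame", "x", "y", "in_bounds"])
    return GroundTruth(
        table=table,
        frame_shape=frame_shape,
        seed=seed if isinstance(seed, int) else None,
    )


def assign_lifetimes(
    ground_truth: GroundTruth,
    compartment_map: CompartmentMap,
    lifetime_table_ns: dict[str, float],
    transition_frames: int = 0,
) -> GroundTruth:
    """Attach per-frame compartments and lifetimes to a ground-truth table.

    Each particle-frame takes the lifetime of its current compartment; with
    ``transition_frames = k > 0`` the series is additionally smoothed with a
    (k+1)-frame moving average so that boundary crossings ramp over ~k frames
    instead of stepping.  Raises if a compartment present in the map lacks a
    table entry.
    """
    present = {CODE_LABELS[c] for c in np.unique(compartment_map.labels)}
    missing = present - set(lifetime_table_ns)
    if missing:
        raise ValueError(f"lifetime table missing labels {sorted(missing)}")
    for lbl, tau in lifetime_table_ns.items():
        if tau <= 0:
            raise ValueError(f"lifetime for {lbl!r} must be positive")

    t = ground_truth.table.copy()
    comps = [compartment_map.label_at(x, y) for x, y in zip(t["x"], t["y"])]
    t["compartment"] = comps
    t["tau_ns"] = [lifetime_table_ns[c] for c in comps]
    if transition_frames > 0:
        k = transition_frames + 1
        t["tau_ns"] = (
            t.sort_values(["particle", "frame"])
            .groupby("particle")["tau_ns"]
            .transform(lambda s: uniform_filter1d(s.to_numpy(float), size=k, mode="nearest"))
        )
    return GroundTruth(table=t, frame_shape=ground_truth.frame_shape, seed=ground_truth.seed)
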
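"""Spot detection and frame-to-frame linking."""

import itertools

import numpy as np
import pytest

from flimtrack.config import TrackerConfig
from flimtrack.tracking import Detection, detect, link, preprocess, table_to_tracks, tracks_to_table


def render_spots(shape, spots, rng, background=2.0):
    """Poisson image with Gaussian spots: spots = [(x, y, photons, sigma)]."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    rate = np.full(shape, float(background))
    for x, y, photons, sigma in spots:
        rate += (
            photons
            * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
            / (2 * np.pi * sigma**2)
        )
    return rng.poisson(rate).astype(float)


@pytest.fixture
def tracker():
    return TrackerConfig(brightness_min=750.0, max_jump_px=5.0, min_track_length=10)


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess(np.full((32, 32), 57.0))
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_large_scale_gradient_suppressed(self):
        """A pure linear ramp has no band-scale structure: residual < 5% of
        the input amplitude."""
        ramp = np.linspace(0, 100, 64)[None, :] * np.ones((64, 1))
        out = preprocess(ramp)
        inner = out[8:-8, 8:-8]
        assert np.abs(inner).max() < 0.05 * 100

    def test_spot_in_band_survives(self):
        rng = np.random.default_rng(0)
        img = render_spots((32, 32), [(16.0, 16.0, 2000, 0.9)], rng, background=50.0)
        out = preprocess(img)
        assert out[16, 16] > 0.3 * (img[16, 16] - 50.0)
        assert abs(np.median(out)) < 2.0  # offset removed

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((8, 8)), band_low_px=1.0, band_high_px=0.5)


class TestDetect:
    def test_subpixel_accuracy_on_bright_spot(self, tracker):
        """Brightness-2000 spots localize within 0.15 px of ground truth
        (averaged over repeated noise realizations)."""
        rng = np.random.default_rng(2)
        errors = []
        for _ in range(40):
            x0 = 14.0 + rng.uniform(-0.5, 0.5)
            y0 = 17.0 + rng.uniform(-0.5, 0.5)
            img = render_spots((32, 32), [(x0, y0, 2000, 1.0)], rng)
            dets = detect(preprocess(img), tracker)
            assert len(dets) == 1
            errors.append(np.hypot(dets[0].x - x0, dets[0].y - y0))
        assert np.mean(errors) < 0.15

    def test_dim_spot_removed_by_brightness_filter(self, tracker):
        rng = np.random.default_rng(3)
        img = render_spots((32, 32), [(16.0, 16.0, 300, 1.0)], rng)
        assert detect(preprocess(img), tracker) == []

    def test_two_separated_spots(self, tracker):
        rng = np.random.default_rng(4)
        img = render_spots((40, 40), [(12.0, 20.0, 2000, 1.0), (22.0, 20.0, 2000, 1.0)], rng)
        assert len(detect(preprocess(img), tracker)) == 2

    def test_size_window_excludes_wide_spots(self, tracker):
        rng = np.random.default_rng(5)
        img = render_spots((40, 40), [(20.0, 20.0, 5000, 3.0)], rng)
        assert detect(preprocess(img), tracker) == []

    def test_empty_frame_valid(self, tracker):
        rng = np.random.default_rng(6)
        img = rng.poisson(2.0, (32, 32)).astype(float)
        assert detect(preprocess(img), tracker) == []


def brute_force_two_particle_links(detections, max_jump):
    """Oracle: enumerate all one-to-one assignments per frame pair and pick
    the minimum summed squared displacement among gated pairs."""
    by_frame = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    links = []
    frames = sorted(by_frame)
    for fa, fb in zip(frames, frames[1:]):
        A, B = by_frame[fa], by_frame[fb]
        best, best_cost = [], np.inf
        for perm in itertools.permutations(range(len(B)), len(A)):
            pairs = [
                (a, B[j])
                for a, j in zip(A, perm)
                if np.hypot(a.x - B[j].x, a.y - B[j].y) <= max_jump
            ]
            cost = sum((a.x - b.x) ** 2 + (a.y - b.y) ** 2 for a, b in pairs)
            # prefer more links, then lower cost (a dropped pair is a worse solution)
            key = (-len(pairs), cost)
            if key < (-len(best), best_cost):
                best, best_cost = pairs, cost
        links.extend(((a.x, a.y, a.frame), (b.x, b.y, b.frame)) for a, b in best)
    return set(links)


class TestLink:
    def _d(self, x, y, frame):
        return Detection(x=x, y=y, frame=frame, brightness=1000.0, sigma_px=1.0)

    def test_pair_within_jump_linked(self):
        tracks = link([self._d(0, 0, 0), self._d(3, 0, 1)], max_jump_px=5, min_track_length=2)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_pair_beyond_jump_not_linked(self):
        tracks = link([self._d(0, 0, 0), self._d(6, 0, 1)], max_jump_px=5, min_track_length=2)
        assert tracks == []  # two singletons, both below min length

    def test_two_particle_recovery_matches_brute_force(self):
        rng = np.random.default_rng(7)
        dets = []
        x1, x2 = 5.0, 30.0  # separation >= 3 * max_jump
        for f in range(12):
            dets.append(self._d(x1, 10.0, f))
            dets.append(self._d(x2, 10.0, f))
            x1 += rng.uniform(-1.5, 1.5)
        tracks = link(dets, max_jump_px=5, min_track_length=10)
        assert len(tracks) == 2
        got = set()
        for t in tracks:
            for a, b in zip(t.detections, t.detections[1:]):
                got.add(((a.x, a.y, a.frame), (b.x, b.y, b.frame)))
        assert got == brute_force_two_particle_links(dets, 5.0)

    def test_no_link_exceeds_max_jump(self):
        rng = np.random.default_rng(8)
        dets = [
            self._d(rng.uniform(0, 50), rng.uniform(0, 50), f)
            for f in range(15)
            for _ in range(6)
        ]
        for t in link(dets, max_jump_px=4.0, min_track_length=2):
            p = t.positions
            assert (np.hypot(*np.diff(p, axis=0).T) <= 4.0 + 1e-9).all()

    def test_invariant_to_detection_order(self):
        rng = np.random.default_rng(9)
        dets = [
            self._d(rng.uniform(0, 30), rng.uniform(0, 30), f)
            for f in range(8)
            for _ in range(4)
        ]
        shuffled = list(dets)
        rng.shuffle(shuffled)
        a = [t.positions.tolist() for t in link(dets, 6.0, min_track_length=3)]
        b = [t.positions.tolist() for t in link(shuffled, 6.0, min_track_length=3)]
        assert a == b

    def test_short_tracks_discarded(self):
        dets = [self._d(0, 0, f) for f in range(5)]
        assert link(dets, 5.0, min_track_length=10) == []
        assert len(link(dets, 5.0, min_track_length=5)) == 1

    def test_table_round_trip(self):
        dets = [self._d(float(f), 2.0, f) for f in range(12)]
        tracks = link(dets, 5.0, min_track_length=10)
        table = tracks_to_table(tracks)
        back = table_to_tracks(table)
        assert len(back) == len(tracks)
        assert np.allclose(back[0].positions, tracks[0].positions)
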
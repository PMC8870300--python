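"""Trajectory lifetime series, smoothing, delta statistics, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimtrack.config import ClassifierConfig
from flimtrack.detector import simulate_pixel_photons
from flimtrack.flim import LifetimeImage, fast_lifetime
from flimtrack.scene import make_compartment_map
from flimtrack.tracking import Detection, Track
from flimtrack.trajectory import (
    boundary_report,
    classify,
    delta_stats,
    sample_track_lifetimes,
    smooth,
)


def make_track(n, x=10.0, y=10.0, start=0, tid=0):
    return Track(
        id=tid,
        detections=[
            Detection(x=x, y=y, frame=start + i, brightness=1000.0, sigma_px=1.0)
            for i in range(n)
        ],
    )


def uniform_image(shape, tau, intensity=100.0, frame=0):
    return LifetimeImage(
        intensity=np.full(shape, intensity),
        lifetime_ns=np.full(shape, float(tau)),
        frame_index=frame,
    )


class TestSampling:
    def test_uniform_patch_returns_patch_value(self):
        imgs = [uniform_image((32, 32), 3.0, frame=f) for f in range(5)]
        out = sample_track_lifetimes(make_track(5), imgs, 3.0)
        assert np.allclose(out, 3.0)

    def test_intensity_weighted_mean(self):
        """Two defined pixels in radius: 2 ns at 100 counts and 4 ns at 300
        counts average to (2*100 + 4*300)/400 = 3.5 ns."""
        inten = np.zeros((16, 16))
        tau = np.full((16, 16), np.nan)
        inten[8, 8], tau[8, 8] = 100.0, 2.0
        inten[8, 9], tau[8, 9] = 300.0, 4.0
        img = LifetimeImage(intensity=inten, lifetime_ns=tau, frame_index=0)
        out = sample_track_lifetimes(make_track(1, x=8.5, y=8.0), [img], 3.0)
        assert out[0] == pytest.approx(3.5)

    def test_no_defined_pixels_yields_nan_entry(self):
        empty = LifetimeImage(
            intensity=np.zeros((16, 16)), lifetime_ns=np.full((16, 16), np.nan),
            frame_index=1,
        )
        imgs = [uniform_image((16, 16), 3.0, frame=0), empty]
        out = sample_track_lifetimes(make_track(2), imgs, 3.0)
        assert out[0] == pytest.approx(3.0)
        assert np.isnan(out[1])

    def test_track_outside_stack_rejected(self):
        imgs = [uniform_image((16, 16), 3.0, frame=0)]
        with pytest.raises(ValueError, match="outside"):
            sample_track_lifetimes(make_track(3, start=10), imgs, 3.0)


class TestSmooth:
    def test_constant_series_unchanged(self):
        assert np.allclose(smooth(np.array([2.0, 2.0, 2.0, 2.0])), 2.0)

    def test_single_frame_spike_removed(self):
        out = smooth(np.array([2.0, 2.0, 3.5, 2.0, 2.0]))
        assert np.allclose(out, 2.0)

    def test_endpoints_pass_through(self):
        out = smooth(np.array([1.0, 4.0, 1.0]))
        assert np.allclose(out, [1.0, 1.0, 1.0])

    def test_nan_entries_stay_nan_and_are_excluded(self):
        out = smooth(np.array([2.0, np.nan, 2.2, 2.1, 2.3]))
        assert np.isnan(out[1])
        assert out[2] == pytest.approx(np.median([2.2, 2.1]))

    def test_all_nan_unchanged(self):
        out = smooth(np.full(5, np.nan))
        assert np.isnan(out).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(np.array([1.0, 2.0]), window=2)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0.1, 10.0), min_size=3, max_size=40),
        st.sampled_from([3, 5]),
    )
    def test_smoothing_never_increases_range(self, values, window):
        x = np.array(values)
        y = smooth(x, window)
        assert np.nanmax(y) - np.nanmin(y) <= np.nanmax(x) - np.nanmin(x) + 1e-12


class TestDeltaStats:
    def test_simple_series(self):
        s = delta_stats([np.array([2.0, 2.2, 2.1])])
        assert np.allclose(sorted(s.deltas_ns), [0.1, 0.2])
        assert s.mean_delta_ns == pytest.approx(0.15)
        assert s.n == 2

    def test_constant_series_zero_mean(self):
        s = delta_stats([np.full(6, 3.0)])
        assert s.mean_delta_ns == 0.0

    def test_nan_breaks_pairs(self):
        s = delta_stats([np.array([2.0, np.nan, 2.4, 2.5])])
        assert s.n == 1  # only the (2.4, 2.5) pair
        assert s.mean_delta_ns == pytest.approx(0.1)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            delta_stats([np.array([2.0]), np.array([np.nan, 1.0, np.nan])])

    def test_noise_scales_with_photon_count(self, clean_acq):
        """Mean |delta| from photon noise grows ~sqrt(2) when the photon
        count per frame is halved (tolerance 15%)."""
        rng = np.random.default_rng(12)

        def series(n_photons, n_frames=400):
            est = []
            for _ in range(n_frames):
                d = simulate_pixel_photons(
                    0.5, 3.0, clean_acq, seed=rng, n_pulses=int(n_photons / 0.5)
                )
                est.append(fast_lifetime(d, clean_acq))
            return np.array(est)

        full = delta_stats([series(2000)]).mean_delta_ns
        half = delta_stats([series(1000)]).mean_delta_ns
        assert half / full == pytest.approx(np.sqrt(2.0), rel=0.15)


class TestClassify:
    def _with_series(self, series, n=None):
        t = make_track(n if n is not None else len(series))
        t.lifetimes_ns = np.asarray(series, dtype=float)
        return t

    def test_range_above_threshold(self):
        cfg = ClassifierConfig(min_track_length=10)
        t = self._with_series([3.0] * 5 + [3.5] * 5)
        assert classify(t, cfg) == "above_threshold"
        assert t.lifetime_range_ns == pytest.approx(0.5)

    def test_constant_series_below(self):
        cfg = ClassifierConfig(min_track_length=10)
        t = self._with_series([3.0] * 10)
        assert classify(t, cfg) == "below_threshold"

    def test_range_exactly_equal_threshold_stays_below(self):
        # 0.5 is exactly representable, so range == threshold holds exactly
        # and exercises the strict-inequality tie rule
        cfg = ClassifierConfig(threshold_ns=0.5, min_track_length=10)
        t = self._with_series([3.0] * 5 + [3.5] * 5)
        assert t.lifetimes_ns.max() - t.lifetimes_ns.min() == 0.5
        assert classify(t, cfg) == "below_threshold"

    def test_short_track_unclassified(self):
        cfg = ClassifierConfig(min_track_length=10)
        t = self._with_series([3.0] * 5)
        assert classify(t, cfg) == "unclassified"

    def test_too_few_defined_entries_unclassified(self):
        cfg = ClassifierConfig(min_track_length=10)
        t = self._with_series([3.0] + [np.nan] * 9)
        assert classify(t, cfg) == "unclassified"

    def test_time_reversal_invariance(self):
        cfg = ClassifierConfig(min_track_length=10)
        rng = np.random.default_rng(3)
        series = 3.0 + 0.3 * rng.standard_normal(14)
        fwd = self._with_series(series)
        rev = self._with_series(series[::-1])
        assert classify(fwd, cfg) == classify(rev, cfg)
        assert fwd.lifetime_range_ns == pytest.approx(rev.lifetime_range_ns)

    def test_smoothing_protects_against_single_frame_spike(self):
        """A spike large enough to beat the threshold on the raw series is
        erased by the median filter: the track stays below threshold."""
        cfg = ClassifierConfig(threshold_ns=0.39, min_track_length=10)
        series = np.full(15, 3.0)
        series[7] += 0.8
        t = self._with_series(series)
        assert classify(t, cfg) == "below_threshold"


class TestBoundaryReport:
    def _classified(self, positions_labels):
        tracks = []
        for i, (x, y, label) in enumerate(positions_labels):
            t = make_track(10, x=x, y=y, tid=i)
            t.label = label
            tracks.append(t)
        return tracks

    def test_complete_separation_flagged_infinite(self):
        cm = make_compartment_map((48, 48), 18.0, 6.0)
        # above tracks on the membrane ring, below tracks at the center
        tracks = self._classified(
            [(23.5 + 18.0, 23.5, "above_threshold") for _ in range(3)]
            + [(26.0, 23.5, "below_threshold") for _ in range(3)]
        )
        rep = boundary_report(tracks, cm, band_px=3.0)
        assert rep["complete_separation"]
        assert np.isinf(rep["odds_ratio"])

    def test_shuffled_labels_give_unit_odds_ratio(self):
        """Permutation oracle: with labels shuffled, the boundary odds ratio
        averages ~1 over many shuffles."""
        cm = make_compartment_map((48, 48), 18.0, 6.0)
        rng = np.random.default_rng(11)
        pos = []
        for _ in range(40):
            th = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0, 17)
            pos.append((23.5 + r * np.cos(th), 23.5 + r * np.sin(th)))
        log_ors = []
        for _ in range(100):
            labels = ["above_threshold"] * 20 + ["below_threshold"] * 20
            rng.shuffle(labels)
            tracks = self._classified(
                [(x, y, lab) for (x, y), lab in zip(pos, labels)]
            )
            rep = boundary_report(tracks, cm, band_px=4.0)
            if np.isfinite(rep["odds_ratio"]) and rep["odds_ratio"] > 0:
                log_ors.append(np.log(rep["odds_ratio"]))
        assert np.exp(np.mean(log_ors)) == pytest.approx(1.0, abs=0.35)

    def test_invalid_band_rejected(self):
        cm = make_compartment_map((32, 32), 12.0, 4.0)
        with pytest.raises(ValueError):
            boundary_report([], cm, band_px=0.0)
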
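"""Unit tests for return maps, laminar segmentation, and duration shapes."""

import numpy as np
import pytest

from epiosc import (
    SimulationConfig,
    Trajectory,
    duration_ushape,
    episode_counts,
    extract_maxima,
    return_map,
    segment_laminar,
    tangency_gap,
)


def _make_traj(times, r_of_t, omega_fast=4.0):
    """Trajectory whose radius follows r_of_t with a fast phase."""
    r = r_of_t(times)
    x = r * np.cos(omega_fast * times)
    y = r * np.sin(omega_fast * times)
    return Trajectory(times, x[:, None], y[:, None], beta=0.0)


class TestExtractMaxima:
    def test_pure_sinusoid_maxima_equal_amplitude(self):
        t = np.arange(0.0, 50.0, 0.01)
        _, peaks = extract_maxima(2.3 * np.sin(1.7 * t), t)
        assert peaks.size >= 10
        assert np.allclose(peaks, 2.3, atol=1e-6)

    def test_monotone_signal_empty(self):
        t = np.linspace(0.0, 1.0, 100)
        t_pk, v_pk = extract_maxima(t**2, t)
        assert t_pk.size == 0 and v_pk.size == 0

    def test_two_band_alternation(self):
        # amplitude switches between 0.5 and 2.5 every half period block
        t = np.arange(0.0, 40.0, 0.01)
        amp = np.where((t // 10).astype(int) % 2 == 0, 0.5, 2.5)
        _, peaks = extract_maxima(amp * np.sin(2 * np.pi * t), t)
        lows = peaks[peaks < 1.0]
        highs = peaks[peaks > 1.0]
        assert lows.size > 0 and highs.size > 0
        assert np.allclose(lows, 0.5, atol=1e-3)
        assert np.allclose(highs, 2.5, atol=1e-3)

    def test_quadratic_refinement_beats_grid(self):
        # sample a parabola peak off-grid; refinement recovers it
        t = np.linspace(0.0, 2.0, 41)  # grid step 0.05, peak at 1.013
        v = 1.0 - (t - 1.013) ** 2
        t_pk, v_pk = extract_maxima(v, t)
        assert t_pk == pytest.approx([1.013], abs=1e-9)
        assert v_pk == pytest.approx([1.0], abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_maxima(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestReturnMap:
    def test_constant_sequence_on_diagonal(self):
        rm = return_map(np.full(5, 1.7))
        assert np.allclose(rm.pairs(), 1.7)

    def test_period_two_off_diagonal(self):
        rm = return_map(np.array([0.2, 1.9, 0.2, 1.9, 0.2]))
        pairs = {tuple(np.round(p, 6)) for p in rm.pairs()}
        assert pairs == {(0.2, 1.9), (1.9, 0.2)}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            return_map(np.array([1.0]))

    def test_logistic_tangency_channel(self):
        """Iterates of the logistic map just below the period-3 tangency
        crawl through a narrow channel next to the diagonal of the
        third-iterate return map."""
        # period-3 saddle-node of the logistic map at r = 1 + sqrt(8);
        # just below, x -> f^3(x) has a narrow channel near its fixed points
        r = 1.0 + np.sqrt(8.0) - 1e-4
        f = lambda x: r * x * (1.0 - x)
        x = 0.5
        third = []
        for _ in range(3000):
            x = f(f(f(x)))
            third.append(x)
        rm = return_map(np.array(third))
        gap, crossed = tangency_gap(rm, (0.49, 0.52))
        assert not crossed
        assert 0 < abs(gap) < 5e-3


class TestTangencyGap:
    def test_exact_diagonal_point_zero_gap(self):
        rm = return_map(np.array([0.5, 0.5, 0.9]))
        gap, _ = tangency_gap(rm, (0.4, 0.6))
        assert gap == 0.0

    def test_far_from_diagonal_large_gap(self):
        rm = return_map(np.array([0.0, 1.0, 0.0, 1.0]))
        gap, crossed = tangency_gap(rm, (-0.5, 1.5))
        assert abs(gap) == pytest.approx(1.0)
        assert crossed  # pairs sit on both sides of the diagonal

    def test_empty_window_rejected(self):
        rm = return_map(np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError):
            tangency_gap(rm, (5.0, 6.0))


class TestSegmentLaminar:
    def test_never_exceeding_threshold_empty(self):
        t = np.arange(0.0, 100.0, 0.01)
        traj = _make_traj(t, lambda t: np.full_like(t, 0.5))
        phases = segment_laminar(traj, 0, r_threshold=1.5)
        assert phases.n_episodes == 0

    def test_square_wave_durations(self):
        # r alternates 0.5 / 2.5 with dwell 10 starting low
        t = np.arange(0.0, 120.0, 0.005)
        traj = _make_traj(
            t, lambda t: np.where((t // 10).astype(int) % 2 == 0, 0.5, 2.5)
        )
        phases = segment_laminar(traj, 0, r_threshold=1.5, min_duration=1.0)
        assert phases.n_episodes == 6
        assert np.allclose(phases.durations, 10.0, atol=0.02)

    def test_min_duration_filters_grazing(self):
        t = np.arange(0.0, 100.0, 0.005)
        # one long episode (duration 20) and one graze (duration 0.5)
        def r_of_t(t):
            r = np.full_like(t, 0.5)
            r[(t >= 10) & (t < 30)] = 2.5
            r[(t >= 50) & (t < 50.5)] = 2.5
            return r
        traj = _make_traj(t, r_of_t)
        phases = segment_laminar(traj, 0, r_threshold=1.5, min_duration=5.0)
        assert phases.n_episodes == 1
        assert phases.durations[0] == pytest.approx(20.0, abs=0.02)

    def test_threshold_nesting(self):
        """Episodes at a higher threshold nest inside lower-threshold ones."""
        rng = np.random.default_rng(4)
        t = np.arange(0.0, 200.0, 0.01)
        # smooth random radius in [0.3, 2.7]
        slow = sum(
            np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) / (i + 1)
            for i, f in enumerate([0.011, 0.023, 0.04])
        )
        r = 1.5 + slow
        traj = _make_traj(t, lambda t: r)
        inner = segment_laminar(traj, 0, r_threshold=1.8, min_duration=0.0)
        outer = segment_laminar(traj, 0, r_threshold=1.2, min_duration=0.0)
        for s, e in inner.episodes:
            assert any(
                os <= s + 1e-9 and e - 1e-9 <= oe for os, oe in outer.episodes
            )

    def test_bad_threshold_rejected(self):
        t = np.arange(0.0, 10.0, 0.01)
        traj = _make_traj(t, lambda t: np.full_like(t, 1.0))
        with pytest.raises(ValueError):
            segment_laminar(traj, 0, r_threshold=-1.0)


class TestDurationUshape:
    def test_arcsine_durations_u_shaped(self):
        rng = np.random.default_rng(0)
        durations = 100.0 * rng.beta(0.5, 0.5, size=400)
        _, _, is_u = duration_ushape(durations)
        assert is_u is True

    def test_uniform_durations_not_u_shaped(self):
        rng = np.random.default_rng(1)
        durations = rng.uniform(0.0, 100.0, size=400)
        _, _, is_u = duration_ushape(durations)
        assert is_u is False

    def test_small_sample_returns_histogram_only(self):
        counts, edges, is_u = duration_ushape(np.arange(1.0, 11.0))
        assert counts.sum() == 10
        assert is_u is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            duration_ushape(np.array([]))


class TestTypeOneScaling:
    def test_mean_laminar_duration_grows_toward_onset(self):
        """Soft type-1 scaling: channel passages lengthen as the coupling
        approaches the locking onset from below (monotonicity only, no
        exponent asserted)."""
        from epiosc import SimulationConfig, integrate, preset

        cfg = preset("fig2")
        params, A = cfg.build_params(), cfg.build_adjacency()
        means = []
        for b in (1.5, 1.625, 1.7):
            sim = SimulationConfig(
                t_end=4000.0, t_transient=200.0, rel_tol=1e-8,
                abs_tol=1e-10, sample_dt=0.05, seed=0,
            )
            traj = integrate(params, A, b, sim, coupling="degree-normalized")
            phases = segment_laminar(traj.after(200.0), 2, 1.5)
            assert phases.n_episodes >= 10
            means.append(phases.durations.mean())
        assert means[0] < means[1] < means[2]


class TestEpisodeCounts:
    def test_counts_match_segmentations(self):
        t = np.arange(0.0, 120.0, 0.005)
        hi = _make_traj(
            t, lambda t: np.where((t // 10).astype(int) % 2 == 0, 0.5, 2.5)
        )
        lo = _make_traj(t, lambda t: np.full_like(t, 0.4))
        phases = [
            segment_laminar(hi, 0, 1.5, min_duration=1.0),
            segment_laminar(lo, 0, 1.5, min_duration=1.0),
        ]
        assert episode_counts(phases).tolist() == [6, 0]
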
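"""Burst detection, phase reconstruction, Kuramoto order parameter."""

import numpy as np
import pytest

from dbsnet.sync import (
    BurstTrain,
    bursts_from_spikes,
    compute_sync_series,
    detect_burst_onsets,
    mean_R,
    order_parameter,
    phase_from_onsets,
    spikes_per_burst,
)


class TestDetectBurstOnsets:
    def test_constant_subthreshold_trace_gives_empty_train(self):
        tr = detect_burst_onsets(np.full(1000, -1.0), dt=1.0, threshold=0.0)
        assert len(tr) == 0

    def test_recovers_known_onsets(self):
        dt = 1.0
        v = np.full(3000, -1.0)
        for t0 in (1000, 1500, 2000):
            v[t0 : t0 + 30] = 1.0
        tr = detect_burst_onsets(v, dt, threshold=0.0, min_gap=50.0)
        assert np.allclose(tr.onset_times, [1000, 1500, 2000], atol=dt)

    def test_close_crossings_merge_under_gap_rule(self):
        dt = 0.5
        v = np.full(2000, -1.0)
        v[100:102] = 1.0
        v[104:106] = 1.0  # 1 ms later: same burst
        tr = detect_burst_onsets(v, dt, threshold=0.0, min_gap=50.0)
        assert len(tr) == 1
        assert tr.onset_times[0] == pytest.approx(100 * dt, abs=dt)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_burst_onsets(np.array([0.0]), 1.0, 0.0)


class TestSpikeGrouping:
    def test_burst_segmentation_and_counts(self):
        spikes = np.array([0, 5, 10, 200, 205, 210, 215, 400])
        tr = bursts_from_spikes(spikes, min_gap=50.0)
        assert np.allclose(tr.onset_times, [0, 200, 400])
        counts = spikes_per_burst(spikes, min_gap=50.0)
        assert counts.tolist() == [3, 4, 1]

    def test_empty_input(self):
        assert len(bursts_from_spikes(np.empty(0))) == 0
        assert spikes_per_burst(np.empty(0)).size == 0


class TestPhaseFromOnsets:
    def test_zero_phase_at_onsets_and_pi_at_midpoint(self):
        tr = BurstTrain(np.array([100.0, 300.0, 500.0]))
        assert phase_from_onsets(tr, 100.0) % (2 * np.pi) == pytest.approx(0.0, abs=1e-12)
        assert phase_from_onsets(tr, 200.0) % (2 * np.pi) == pytest.approx(np.pi)

    def test_hand_evaluated_piecewise_value(self):
        # onsets at 0, 1, 3 s; t = 2 s is halfway through the second interval
        tr = BurstTrain(np.array([0.0, 1000.0, 3000.0]))
        assert phase_from_onsets(tr, 2000.0) == pytest.approx(2 * np.pi + np.pi)

    def test_outside_coverage_is_invalid(self):
        tr = BurstTrain(np.array([100.0, 200.0]))
        assert np.isnan(phase_from_onsets(tr, 50.0))
        assert np.isnan(phase_from_onsets(tr, 250.0))

    def test_linear_continuous_increasing_inside_coverage(self):
        tr = BurstTrain(np.array([0.0, 150.0, 450.0, 600.0]))
        t = np.linspace(0.0, 600.0, 1201)
        phi = phase_from_onsets(tr, t)
        assert np.all(np.isfinite(phi))
        assert np.all(np.diff(phi) > 0)
        assert phi[0] == pytest.approx(0.0, abs=1e-12)
        assert phi[-1] == pytest.approx(6 * np.pi, rel=1e-12)


class TestOrderParameter:
    def test_identical_phases_give_unity(self):
        r, theta = order_parameter(np.full(50, 1.3))
        assert r == pytest.approx(1.0)
        assert theta == pytest.approx(1.3)

    def test_uniformly_spaced_phases_cancel(self):
        phases = 2 * np.pi * np.arange(10) / 10
        r, _ = order_parameter(phases)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        r, _ = order_parameter(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(np.sqrt(2) / 2, rel=1e-12)

    def test_matches_brute_force_complex_sum_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            phi = rng.uniform(-50, 50, size=rng.integers(1, 40))
            r, theta = order_parameter(phi)
            # independent brute-force accumulation
            re = sum(np.cos(p) for p in phi) / len(phi)
            im = sum(np.sin(p) for p in phi) / len(phi)
            assert abs(r - np.hypot(re, im)) < 1e-12
            assert abs(theta - np.arctan2(im, re)) < 1e-9

    def test_invariance_under_global_shift_and_permutation(self):
        rng = np.random.default_rng(23)
        phi = rng.uniform(0, 2 * np.pi, 64)
        r0, _ = order_parameter(phi)
        for _ in range(10):
            shift = rng.uniform(-10, 10)
            perm = rng.permutation(64)
            r1, _ = order_parameter(phi[perm] + shift)
            assert r1 == pytest.approx(r0, abs=1e-12)

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([np.nan, np.nan]))


class TestMeanR:
    def _series(self, times, R):
        n = times.size
        return type("S", (), {})() if False else __import__("dbsnet.sync", fromlist=["SyncSeries"]).SyncSeries(
            times=times, phases=np.zeros((1, n)), R=R, Theta=np.zeros(n), n_valid=np.ones(n, int)
        )

    def test_constant_and_linear_ramp(self):
        t = np.linspace(0, 1000, 1001)
        assert mean_R(self._series(t, np.full(t.size, 0.5)), (0, 1000)) == pytest.approx(0.5)
        assert mean_R(self._series(t, t / 1000.0), (0, 1000)) == pytest.approx(0.5, abs=1e-3)

    def test_sampled_sine_over_whole_periods(self):
        t = np.arange(0.0, 4000.0, 1.0)
        R = 0.5 + 0.4 * np.sin(2 * np.pi * t / 1000.0)
        assert mean_R(self._series(t, R), (0, 3999)) == pytest.approx(0.5, abs=2e-3)

    def test_invalid_samples_excluded(self):
        t = np.linspace(0, 100, 101)
        R = np.full(101, 0.8)
        R[::2] = np.nan
        assert mean_R(self._series(t, R), (0, 100)) == pytest.approx(0.8)

    def test_empty_window_rejected(self):
        t = np.linspace(0, 100, 101)
        with pytest.raises(ValueError):
            mean_R(self._series(t, t), (200, 300))


class TestSyncSeries:
    def test_synchronous_trains_give_unity_R(self):
        base = np.arange(0.0, 5000.0, 250.0)
        trains = [BurstTrain(base) for _ in range(20)]
        ss = compute_sync_series(trains, np.linspace(0, 4750, 500))
        assert np.nanmin(ss.R) == pytest.approx(1.0)

    def test_strictly_increasing_onsets_enforced(self):
        with pytest.raises(ValueError):
            BurstTrain(np.array([3.0, 2.0]))
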
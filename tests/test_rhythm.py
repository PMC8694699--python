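"""Autocorrelation and Periodicity Index properties and oracles."""

import numpy as np
import pytest

from groomrhythm import boutcycles, rhythm, simgen
from groomrhythm.boutcycles import ConfidenceTrace
from groomrhythm.legmotion import dynamics_matrix, window_stack
from groomrhythm.rhythm import (AcfTrace, acf, long_scale_acf,
                                periodic_fraction, periodicity_index,
                                short_scale_acf)


def _brute_acf(x, max_lag):
    """Independent double-loop lagged-product oracle."""
    x = np.asarray(x, float) - np.mean(x)
    denom = np.sum(x * x)
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        s = 0.0
        for t in range(len(x) - k):
            s += x[t] * x[t + k]
        out[k] = s / denom
    return out


class TestAcf:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for n, max_lag in [(64, 20), (256, 60), (100, 99)]:
            x = rng.normal(size=n)
            np.testing.assert_allclose(acf(x, max_lag).values,
                                       _brute_acf(x, max_lag), atol=1e-10)

    def test_sinusoid_acf_is_cosine(self):
        t = np.arange(6000)
        f = 0.02  # cycles per frame
        trace = acf(np.sin(2 * np.pi * f * t), max_lag=200)
        expected = np.cos(2 * np.pi * f * trace.lags)
        np.testing.assert_allclose(trace.values, expected, atol=0.05)

    def test_white_noise_decorrelates(self):
        x = np.random.default_rng(1).normal(size=20000)
        trace = acf(x, max_lag=100)
        assert trace.values[0] == pytest.approx(1.0)
        assert np.max(np.abs(trace.values[1:])) < 3 / np.sqrt(x.size)

    def test_ar1_matches_simulation_oracle(self):
        # AR(1) with phi=0.5: ACF(k) ~= 0.5^k
        rng = np.random.default_rng(3)
        n = 100_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = 0.5 * x[i - 1] + eps[i]
        trace = acf(x, max_lag=8)
        np.testing.assert_allclose(trace.values, 0.5 ** trace.lags, atol=0.02)

    def test_constant_signal_degenerate(self):
        trace = acf(np.full(500, 3.3), max_lag=50)
        assert trace.degenerate
        assert periodicity_index(trace).is_periodic is False

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            acf(np.array([1.0, np.nan, 2.0]), 1)


class TestShortScaleAcf:
    def _window_with_columns(self, cols):
        vals = np.zeros((32, 1600))
        for c, col in cols.items():
            vals[:, c] = col
        from groomrhythm.legmotion import DynamicsMatrix
        return DynamicsMatrix(values=vals, threshold_used=5.0)

    def test_single_column_equals_own_acf(self):
        t = np.arange(32)
        col = 10 * np.sin(2 * np.pi * 6 * t / 60)
        d = self._window_with_columns({5: col})
        traces, stacked = short_scale_acf([d])
        np.testing.assert_allclose(traces[0].values, acf(col, 31).values)
        assert stacked.shape == (1, 60)

    def test_duplicate_columns_average_to_same(self):
        t = np.arange(32)
        col = 10 * np.sin(2 * np.pi * 6 * t / 60)
        one, _ = short_scale_acf([self._window_with_columns({5: col})])
        two, _ = short_scale_acf([self._window_with_columns({5: col, 9: col})])
        np.testing.assert_allclose(one[0].values, two[0].values)

    def test_six_hz_shoulder_near_ten_frames(self):
        t = np.arange(32)
        col = 10 * np.sin(2 * np.pi * 6 * t / 60)
        traces, _ = short_scale_acf([self._window_with_columns({5: col})])
        r = periodicity_index(traces[0])
        assert r.is_periodic
        assert abs(r.shoulder_lag_frames - 10) <= 1

    def test_empty_windows_omitted(self):
        from groomrhythm.legmotion import DynamicsMatrix
        d = DynamicsMatrix(values=np.zeros((32, 1600)), threshold_used=5.0)
        traces, stacked = short_scale_acf([d])
        assert traces == [] and stacked.shape == (0, 60)


class TestLongScaleAcf:
    def test_shoulder_at_slow_period(self):
        # 0.33 Hz BC: shoulder lag ~ 60/0.33 ~ 182 frames
        t = np.arange(4000) / 60.0
        bc = ConfidenceTrace(bc=0.5 * np.sin(2 * np.pi * 0.33 * t),
                             frame_rate_hz=60.0)
        traces = long_scale_acf(bc, hop=999)
        r = periodicity_index(traces[0])
        assert r.is_periodic
        assert abs(r.shoulder_lag_frames - 60 / 0.33) <= 2

    def test_short_trace_truncated_flag(self):
        bc = ConfidenceTrace(bc=np.sin(np.arange(500) / 10.0),
                             frame_rate_hz=60.0)
        traces = long_scale_acf(bc)
        assert len(traces) == 1 and traces[0].truncated

    def test_constant_bc_degenerate(self):
        bc = ConfidenceTrace(bc=np.zeros(2000), frame_rate_hz=60.0)
        traces = long_scale_acf(bc, hop=999)
        assert all(t.degenerate for t in traces)

    def test_window_flags_track_ground_truth(self, dusted18_traces):
        (traces, gt), _ = dusted18_traces
        bc = boutcycles.confidence(traces)
        per = np.zeros(gt.n_frames, bool)
        for e in gt.episodes:
            if e.periodic:
                per[e.start:e.end] = True
        groom = gt.grooming_mask
        agree = []
        for t in long_scale_acf(bc, hop=333):
            s = t.window_start_frame
            sl = slice(s, s + 999)
            if not groom[sl].all():
                continue
            truth_frac = per[sl].mean()
            if 0.1 < truth_frac < 0.9:   # windows straddling a mode switch
                continue
            r = periodicity_index(t)
            agree.append(r.is_periodic == (truth_frac >= 0.5))
        assert len(agree) > 30
        assert np.mean(agree) >= 0.80


class TestPeriodicityIndex:
    def test_pure_sinusoid_pi_is_one(self):
        t = np.arange(3600) / 60.0
        trace = acf(np.sin(2 * np.pi * 0.4 * t), max_lag=400)
        r = periodicity_index(trace)
        assert r.is_periodic
        assert r.pi == pytest.approx(1.0, abs=0.05)
        assert abs(r.shoulder_lag_frames - 150) <= 1

    def test_damped_sinusoid_closed_form(self):
        lam, period = 0.004, 125
        k = np.arange(500)
        vals = np.exp(-lam * k) * np.cos(2 * np.pi * k / period)
        r = periodicity_index(AcfTrace(lags=k, values=vals))
        # the damped-cosine maximum sits a lag or two before the period
        assert abs(r.shoulder_lag_frames - period) <= 2
        assert r.pi == pytest.approx(np.exp(-lam * period), abs=5e-3)

    def test_white_noise_not_periodic(self):
        rng = np.random.default_rng(0)
        flagged = sum(
            periodicity_index(acf(rng.normal(size=999), 400)).is_periodic
            for _ in range(100))
        assert flagged <= 5

    def test_pi_bounded_for_stationary_signals(self):
        rng = np.random.default_rng(4)
        t = np.arange(5000) / 60.0
        for sd in (0.0, 0.2, 0.5):
            x = np.sin(2 * np.pi * 0.4 * t) + rng.normal(0, sd, t.size)
            r = periodicity_index(acf(x, 400))
            if r.is_periodic:
                assert 0.0 < r.pi <= 1.0 + 1e-6

    def test_noise_never_raises_median_pi(self):
        # median PI over seeds is non-increasing along a noise grid
        t = np.arange(4000) / 60.0
        base = np.sin(2 * np.pi * 0.4 * t)
        grid = [0.0, 0.3, 0.8, 1.5]
        medians = []
        for sd in grid:
            pis = []
            for seed in range(20):
                x = base + np.random.default_rng(seed).normal(0, sd, t.size)
                r = periodicity_index(acf(x, 400))
                pis.append(r.pi if r.is_periodic else 0.0)
            medians.append(np.median(pis))
        assert all(a >= b - 1e-9 for a, b in zip(medians[:-1], medians[1:]))

    def test_sinusoid_always_classified_periodic(self):
        t = np.arange(999) / 60.0
        for f in (0.3, 0.4, 0.5):
            r = periodicity_index(acf(np.sin(2 * np.pi * f * t), 400))
            assert r.is_periodic


class TestPeriodicFraction:
    def test_all_and_none(self):
        assert periodic_fraction([True] * 5, [1.0] * 5) == 1.0
        assert periodic_fraction([False] * 5, [1.0] * 5) == 0.0

    def test_time_weighting(self):
        assert periodic_fraction([True, False], [3.0, 1.0]) == 0.75

    def test_empty_is_nan(self):
        assert np.isnan(periodic_fraction([], []))
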
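"""Temperature trends, normalized rates, and cross-time-scale coupling."""

import numpy as np
import pandas as pd
import pytest

from groomrhythm import simgen, thermal
from groomrhythm.thermal import (FlySummary, coupling, normalized_rates,
                                 summaries_frame, summarize_fly, thermal_trend)


def _summaries(values):
    """FlySummaries from {temp: [fast...]} (+ optional slow) dicts."""
    out = []
    for i, (temp, fast, slow) in enumerate(values):
        out.append(FlySummary(fly_id=f"fly{i}", condition="dusted",
                              temperature_C=temp, fast_mean_hz=fast,
                              slow_mean_hz=slow))
    return out


class TestSummarizeFly:
    def test_all_masked_recording_keeps_missing_markers(self):
        s = summarize_fly(None, None, None,
                          {"fly_id": "a", "temperature_C": 20.0})
        assert np.isnan(s.fast_mean_hz) and np.isnan(s.slow_mean_hz)
        assert s.n_cycles == 0

    def test_single_cycle_single_window(self):
        from groomrhythm.boutcycles import Cycle, CycleSet
        from groomrhythm.legmotion import LegFrequencySeries
        series = LegFrequencySeries(table=pd.DataFrame(
            [{"window_start": 0, "count": 3.0, "freq_hz": 6.0,
              "masked": False}]), frame_rate_hz=60.0)
        cycles = CycleSet(cycles=[Cycle("ff", 0, 120, 120, 2.0, 0.5)],
                          max_duration_frames=280, frame_rate_hz=60.0)
        s = summarize_fly(series, cycles, None,
                          {"fly_id": "a", "temperature_C": 20.0})
        assert s.fast_mean_hz == pytest.approx(6.0)
        assert s.slow_mean_hz == pytest.approx(0.5)

    def test_preset_recovery_end_to_end(self):
        # dusted 18 degC: summary lands near the generating frequencies
        from groomrhythm import boutcycles, legmotion
        cfg = simgen.preset("dusted", 18, duration_s=120, seed=31)
        stack, traces, eth, gt = simgen.generate_recording(cfg)
        series = legmotion.leg_frequency_series(stack, eth)
        cycles = boutcycles.extract_cycles(boutcycles.confidence(traces))
        s = summarize_fly(series, cycles, None,
                          {"fly_id": "a", "condition": "dusted",
                           "temperature_C": 18.0})
        assert s.fast_mean_hz == pytest.approx(5.7, rel=0.07)
        assert s.slow_mean_hz == pytest.approx(0.42, rel=0.12)


class TestThermalTrend:
    def test_exactly_linear_means(self):
        rows = [(18.0, 5.7, 0.42), (24.0, 6.15, 0.455), (30.0, 6.6, 0.49)]
        tr = thermal_trend(_summaries(rows), "fast")
        assert tr.r_squared == pytest.approx(1.0)
        assert tr.slope_hz_per_C == pytest.approx(0.075)
        assert tr.intercept_hz == pytest.approx(5.7 - 18 * 0.075)

    def test_constant_frequencies_zero_slope(self):
        rows = [(18.0, 6.0, 0.4), (24.0, 6.0, 0.4), (30.0, 6.0, 0.4)]
        tr = thermal_trend(_summaries(rows), "fast")
        assert tr.slope_hz_per_C == pytest.approx(0.0)

    def test_too_few_temperatures_rejected(self):
        rows = [(18.0, 5.7, 0.42), (30.0, 6.6, 0.49)]
        with pytest.raises(ValueError, match="3 distinct temperatures"):
            thermal_trend(_summaries(rows), "fast")

    def test_missing_flies_dropped_pairwise(self):
        rows = [(18.0, 5.7, 0.42), (24.0, np.nan, 0.455), (24.0, 6.15, 0.455),
                (30.0, 6.6, 0.49)]
        tr = thermal_trend(_summaries(rows), "fast")
        assert tr.n_flies.tolist() == [1, 1, 1]

    def test_r_squared_tends_to_one_as_noise_vanishes(self):
        temps = list(range(18, 31, 2))
        r2 = []
        for noise in (0.4, 0.1, 0.0):
            df = simgen.sample_fly_means("dusted", temps, 8, seed=2,
                                         fast_sd=noise)
            df = df.rename(columns={"fast_hz": "fast_mean_hz",
                                    "slow_hz": "slow_mean_hz"})
            r2.append(thermal_trend(df, "fast").r_squared)
        assert r2[0] < r2[-1]
        assert r2[-1] == pytest.approx(1.0, abs=1e-9)

    def test_preset_slope_recovery_across_seeds(self):
        # 8 flies x 7 temperatures at preset noise recovers the dusted
        # fast slope (0.075 Hz/degC) within 15% in >= 90% of 50 seeds
        temps = list(range(18, 31, 2))
        hits = 0
        for seed in range(50):
            df = simgen.sample_fly_means("dusted", temps, 8, seed=seed)
            df = df.rename(columns={"fast_hz": "fast_mean_hz",
                                    "slow_hz": "slow_mean_hz"})
            slope = thermal_trend(df, "fast").slope_hz_per_C
            hits += abs(slope - 0.075) <= 0.15 * 0.075
        assert hits >= 45


class TestNormalizedRates:
    def test_endpoint_rates(self):
        rows = [(18.0, 5.7, 0.42), (24.0, 5.7, 0.42), (30.0, 6.6, 0.49)]
        tr = thermal_trend(_summaries(rows), "fast")
        rates = normalized_rates(tr)
        assert rates.min() == 1.0
        assert rates[-1] == pytest.approx(6.6 / 5.7)

    def test_minimum_is_exactly_one(self):
        rng = np.random.default_rng(0)
        rows = [(t, 5 + rng.random(), 0.4) for t in (18.0, 22.0, 26.0, 30.0)]
        tr = thermal_trend(_summaries(rows), "fast")
        assert normalized_rates(tr).min() == 1.0

    def test_scale_invariance(self):
        rows = [(18.0, 5.7, 0.4), (24.0, 6.0, 0.4), (30.0, 6.6, 0.4)]
        tr = thermal_trend(_summaries(rows), "fast")
        scaled = thermal_trend(
            _summaries([(t, 3.1 * f, s) for t, f, s in rows]), "fast")
        np.testing.assert_allclose(normalized_rates(tr),
                                   normalized_rates(scaled))

    def test_zero_minimum_rejected(self):
        rows = [(18.0, 0.0, 0.4), (24.0, 6.0, 0.4), (30.0, 6.6, 0.4)]
        tr = thermal_trend(_summaries(rows), "fast")
        with pytest.raises(ValueError, match="minimum"):
            normalized_rates(tr)


class TestCoupling:
    def _trends(self, fast_rows, slow_rows):
        fast = thermal_trend(_summaries(fast_rows), "fast")
        slow = thermal_trend(_summaries(slow_rows), "slow")
        return fast, slow

    def test_identical_rate_vectors(self):
        rows = [(18.0, 5.7, 0.42), (24.0, 6.15, 0.455), (30.0, 6.6, 0.49)]
        fast, slow = self._trends(rows, rows)
        out = coupling(fast, slow)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_decoupled_constant_slow_gives_zero_slope(self):
        fast_rows = [(18.0, 5.7, 0.45), (24.0, 6.15, 0.45), (30.0, 6.6, 0.45)]
        fast, slow = self._trends(fast_rows, fast_rows)
        out = coupling(fast, slow)
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = thermal_trend(_summaries(
            [(18.0, 5.7, 0.42), (24.0, 6.15, 0.46), (30.0, 6.6, 0.49)]), "fast")
        b = thermal_trend(_summaries(
            [(18.0, 5.7, 0.42), (22.0, 6.0, 0.45), (30.0, 6.6, 0.49)]), "slow")
        with pytest.raises(ValueError, match="grids"):
            coupling(a, b)

    def test_coupled_exceeds_decoupled_r2(self):
        # dusted (coupled) presets beat spontaneous (decoupled) presets in
        # >= 95 of 100 seeded replicates
        temps = list(range(18, 31, 2))
        wins = 0
        for seed in range(100):
            win = {}
            for cond in ("dusted", "spontaneous"):
                df = simgen.sample_fly_means(cond, temps, 8, seed=seed)
                df = df.rename(columns={"fast_hz": "fast_mean_hz",
                                        "slow_hz": "slow_mean_hz"})
                fast = thermal_trend(df, "fast")
                slow = thermal_trend(df, "slow")
                win[cond] = coupling(fast, slow)["r_squared"]
            wins += win["dusted"] > win["spontaneous"]
        assert wins >= 95
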
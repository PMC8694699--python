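"""Per-fly aggregation and temperature scaling of the two grooming rhythms.

A hallmark of central-pattern-generator control is that rhythm frequency
rises with temperature.  This module aggregates one recording into a
:class:`FlySummary`, fits the linear temperature trend of per-temperature
mean frequencies for either time scale, normalizes the trend to rates of
change (every mean divided by the lowest mean, so the minimum is exactly
1.0), and regresses the slow rate of change on the fast one to quantify
cross-time-scale coupling — high R-squared means the two nested rhythms
contract together, as in dust-stimulated flies; spontaneously grooming
flies decouple.

Regressions run on per-temperature group means by default (matching how
the figures are drawn); a per-fly option is exposed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .boutcycles import CycleSet, cycle_frequency_stats, movements_per_cycle
from .legmotion import LegFrequencySeries
from .rhythm import PeriodicityResult, periodic_fraction

__all__ = [
    "FlySummary",
    "ThermalTrend",
    "summarize_fly",
    "thermal_trend",
    "normalized_rates",
    "coupling",
    "summaries_frame",
]


@dataclass
class FlySummary:
    """One recording's rhythm statistics; NaN marks missing components."""

    fly_id: str
    condition: str
    temperature_C: float
    fast_mean_hz: float = float("nan")
    fast_median_hz: float = float("nan")
    slow_mean_hz: float = float("nan")
    slow_median_hz: float = float("nan")
    movements_per_cycle_mean: float = float("nan")
    movements_per_cycle_median: float = float("nan")
    periodic_fraction_long: float = float("nan")
    pi_short_mean: float = float("nan")
    pi_long_mean: float = float("nan")
    n_cycles: int = 0
    n_leg_windows: int = 0


@dataclass
class ThermalTrend:
    """OLS fit of per-temperature mean frequency on temperature."""

    scale: str                       # "fast" | "slow"
    slope_hz_per_C: float
    intercept_hz: float
    r_squared: float
    p_value: float
    temperatures: np.ndarray
    means_hz: np.ndarray
    sds_hz: np.ndarray
    n_flies: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature_C": self.temperatures,
            "mean_hz": self.means_hz,
            "sd_hz": self.sds_hz,
            "n_flies": self.n_flies,
        })


def summarize_fly(
    leg_series: LegFrequencySeries | None,
    cycles: CycleSet | None,
    rhythm_results: dict | None,
    metadata: dict,
) -> FlySummary:
    """Aggregate one fly's pipeline outputs.

    ``rhythm_results`` may carry ``short`` / ``long`` lists of
    :class:`PeriodicityResult` and ``long_window_s`` for time weighting.
    Empty or missing components leave NaN markers rather than zeros, so a
    fully masked recording is distinguishable from a genuinely zero rate.
    """
    out = FlySummary(
        fly_id=str(metadata["fly_id"]),
        condition=str(metadata.get("condition", "")),
        temperature_C=float(metadata["temperature_C"]),
    )
    if leg_series is not None:
        un = leg_series.unmasked
        out.n_leg_windows = int(len(un))
        if len(un):
            out.fast_mean_hz = float(un["freq_hz"].mean())
            out.fast_median_hz = float(un["freq_hz"].median())
    if cycles is not None:
        st = cycle_frequency_stats(cycles, "both")
        out.n_cycles = st["n"]
        out.slow_mean_hz = st["mean_hz"]
        out.slow_median_hz = st["median_hz"]
        if leg_series is not None and len(cycles):
            mpc = movements_per_cycle(cycles, leg_series)["movements"]
            if len(mpc):
                out.movements_per_cycle_mean = float(mpc.mean())
                out.movements_per_cycle_median = float(mpc.median())
    if rhythm_results:
        short: Sequence[PeriodicityResult] = rhythm_results.get("short", [])
        long: Sequence[PeriodicityResult] = rhythm_results.get("long", [])
        s_pi = [r.pi for r in short if r.is_periodic]
        l_pi = [r.pi for r in long if r.is_periodic]
        if s_pi:
            out.pi_short_mean = float(np.mean(s_pi))
        if l_pi:
            out.pi_long_mean = float(np.mean(l_pi))
        if long:
            w = float(rhythm_results.get("long_window_s", 1.0))
            out.periodic_fraction_long = periodic_fraction(
                [r.is_periodic for r in long], [w] * len(long))
    return out


def summaries_frame(summaries: Sequence[FlySummary]) -> pd.DataFrame:
    """Tidy DataFrame of per-fly summaries, one row per fly."""
    return pd.DataFrame([asdict(s) for s in summaries])


def _per_temperature(df: pd.DataFrame, col: str):
    grouped = df.groupby("temperature_C")[col]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    n = grouped.count()
    keep = means.notna()
    return (means[keep].index.to_numpy(dtype=float),
            means[keep].to_numpy(),
            sds[keep].to_numpy(),
            n[keep].to_numpy())


def thermal_trend(
    summaries: Sequence[FlySummary] | pd.DataFrame,
    scale: str = "fast",
    per_fly: bool = False,
) -> ThermalTrend:
    """Linear temperature dependence of rhythm frequency.

    Ordinary least squares of per-temperature mean frequency (default) or
    per-fly frequency (``per_fly=True``) on temperature, with the
    two-sided slope p-value.  Requires at least three distinct
    temperatures; flies with missing frequency are dropped pairwise.
    """
    if scale not in ("fast", "slow"):
        raise ValueError("scale must be 'fast' or 'slow'")
    df = (summaries if isinstance(summaries, pd.DataFrame)
          else summaries_frame(summaries))
    col = f"{scale}_mean_hz"
    df = df[np.isfinite(df[col])]
    temps, means, sds, n = _per_temperature(df, col)
    if temps.size < 3:
        raise ValueError(
            f"need >= 3 distinct temperatures with data, got {temps.size}"
        )
    if per_fly:
        fit = stats.linregress(df["temperature_C"], df[col])
    else:
        fit = stats.linregress(temps, means)
    return ThermalTrend(
        scale=scale,
        slope_hz_per_C=float(fit.slope),
        intercept_hz=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        temperatures=temps,
        means_hz=means,
        sds_hz=sds,
        n_flies=n,
    )


def normalized_rates(trend: ThermalTrend) -> np.ndarray:
    """Rates of change: per-temperature means over the lowest mean.

    The minimum is exactly 1.0 by construction ("no change"); values
    above 1.0 quantify the relative frequency increase, which makes the
    fast (Hz-scale) and slow (sub-Hz) rhythms comparable.
    """
    m = np.min(trend.means_hz)
    if m <= 0:
        raise ValueError("cannot normalize: minimum per-temperature mean <= 0")
    return trend.means_hz / m


def coupling(trend_fast: ThermalTrend, trend_slow: ThermalTrend) -> dict:
    """Cross-time-scale coupling of temperature responses.

    OLS of the slow rhythm's normalized rates on the fast rhythm's, over
    a shared temperature grid.  Returns slope, R-squared and the
    two-sided p-value; R-squared near 1 with p < 0.05 indicates the two
    rhythms contract together.
    """
    if (trend_fast.temperatures.size != trend_slow.temperatures.size
            or not np.allclose(trend_fast.temperatures, trend_slow.temperatures)):
        raise ValueError("temperature grids of the two trends do not match")
    x = normalized_rates(trend_fast)
    y = normalized_rates(trend_slow)
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "r_squared": float(fit.rvalue ** 2),
        "p_value": float(fit.pvalue),
        "n": int(x.size),
    }
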
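"""Autocorrelation, Periodicity Index, and periodic/non-periodic labels.

Periodicity of either grooming time scale is quantified from the
autocorrelation function (ACF) of the relevant signal: dynamics-matrix
columns for the fast leg rhythm, the behavioral-confidence trace for the
slow bout alternation.  The ACF is mean-subtracted and normalized so the
central (zero-lag) peak is exactly 1; the Periodicity Index (PI) is then
the height of the prominent peak nearest zero lag — the "shoulder" — over
the central peak.  A perfect sinusoid has PI = 1; weakly periodic signals
approach 0.  If no positive-lag peak reaches the prominence and height
thresholds (both 0.2), the signal is classified non-periodic and no PI is
assigned.

Fast-scale ACFs are computed per surviving column of a dynamics matrix
and averaged within the 32-frame window; slow-scale ACFs use sliding
999-frame (16.6 s) windows of the BC trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .boutcycles import ConfidenceTrace
from .legmotion import DynamicsMatrix

__all__ = [
    "PI_PROMINENCE",
    "PI_HEIGHT",
    "LONG_WINDOW_FRAMES",
    "AcfTrace",
    "PeriodicityResult",
    "acf",
    "short_scale_acf",
    "long_scale_acf",
    "periodicity_index",
    "periodic_fraction",
]

logger = logging.getLogger(__name__)

PI_PROMINENCE = 0.2
PI_HEIGHT = 0.2
LONG_WINDOW_FRAMES = 999
LONG_MAX_LAG = 400
SHORT_STACK_LAGS = 60      # lag bins retained in the stacked fast-scale array


@dataclass
class AcfTrace:
    """Normalized autocorrelation over lags 0..max_lag.

    ``values[0] == 1`` after normalization unless the source signal had
    zero variance, in which case ``degenerate`` is set and ``values`` are
    NaN.
    """

    lags: np.ndarray
    values: np.ndarray
    source: str = "generic_1d"          # short_scale | long_scale | generic_1d
    degenerate: bool = False
    window_start_frame: int | None = None
    truncated: bool = False

    @property
    def max_lag(self) -> int:
        return int(self.lags[-1])


@dataclass
class PeriodicityResult:
    """Shoulder-peak periodicity measurement for one ACF.

    ``pi`` is defined (and in (0, 1] for stationary signals) exactly when
    ``is_periodic`` is true; non-periodic ACFs carry no index.
    """

    pi: float | None
    shoulder_lag_frames: int | None
    is_periodic: bool
    prominence_threshold: float = PI_PROMINENCE
    height_threshold: float = PI_HEIGHT

    def __post_init__(self) -> None:
        if self.is_periodic != (self.pi is not None):
            raise ValueError("pi must be defined iff is_periodic")


def acf(signal: np.ndarray, max_lag: int, source: str = "generic_1d") -> AcfTrace:
    """Mean-subtracted, zero-lag-normalized autocorrelation.

    r(k) = sum_t (x_t - mean)(x_{t+k} - mean) / sum_t (x_t - mean)^2 for
    k = 0..max_lag, computed by direct lagged products.  A constant
    (zero-variance) signal yields a degenerate trace with NaN values.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if x.size <= max_lag:
        raise ValueError(f"signal length {x.size} must exceed max_lag {max_lag}")
    lags = np.arange(max_lag + 1)
    scale = float(np.max(np.abs(x))) or 1.0
    x = x - x.mean()
    denom = float(np.dot(x, x))
    # zero variance up to float cancellation error relative to the signal
    if denom <= x.size * (1e-12 * scale) ** 2:
        return AcfTrace(lags=lags, values=np.full(max_lag + 1, np.nan),
                        source=source, degenerate=True)
    full = np.correlate(x, x, mode="full")
    values = full[x.size - 1:x.size + max_lag] / denom
    return AcfTrace(lags=lags, values=values, source=source)


def short_scale_acf(
    d_windows: list[DynamicsMatrix], max_lag: int = 31
) -> tuple[list[AcfTrace], np.ndarray]:
    """Column-averaged ACF per dynamics-matrix window (fast time scale).

    For each window, ACFs of the surviving columns are averaged into one
    mean ACF; windows with no surviving column are omitted (logged).
    Returns the per-window traces and the stacked symmetric-lag array
    (``SHORT_STACK_LAGS`` central bins of the full correlation per window,
    lags -(SHORT_STACK_LAGS/2 - 1)..SHORT_STACK_LAGS/2), one row per
    retained window.
    """
    traces: list[AcfTrace] = []
    stacked_rows = []
    half = SHORT_STACK_LAGS // 2
    for d in d_windows:
        cols = d.surviving_columns
        if cols.size == 0:
            logger.debug("window %d omitted: no surviving columns",
                         d.window_start_frame)
            continue
        per_col = []
        for c in cols:
            t = acf(d.values[:, c], max_lag=max_lag)
            if not t.degenerate:
                per_col.append(t.values)
        if not per_col:
            logger.debug("window %d omitted: all columns degenerate",
                         d.window_start_frame)
            continue
        mean_vals = np.mean(per_col, axis=0)
        traces.append(AcfTrace(lags=np.arange(max_lag + 1), values=mean_vals,
                               source="short_scale",
                               window_start_frame=d.window_start_frame))
        # symmetric stacking: ACF is even, so mirror the positive lags
        sym = np.concatenate([mean_vals[half - 1:0:-1], mean_vals[:half + 1]])
        stacked_rows.append(sym)
    stacked = (np.vstack(stacked_rows) if stacked_rows
               else np.empty((0, SHORT_STACK_LAGS)))
    return traces, stacked


def long_scale_acf(
    bc: ConfidenceTrace,
    window_frames: int = LONG_WINDOW_FRAMES,
    hop: int = 1,
    max_lag: int = LONG_MAX_LAG,
) -> list[AcfTrace]:
    """Sliding-window ACFs of the behavioral-confidence trace.

    Windows of ``window_frames`` (999 frames = 16.6 s at 60 Hz) advance by
    ``hop``.  A trace shorter than one window yields a single truncated
    window flagged ``truncated`` (max_lag shrunk to fit if needed).
    """
    x = bc.bc
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if x.size < window_frames:
        logger.warning("BC trace of %d frames is shorter than the %d-frame "
                       "window; computing one truncated ACF", x.size,
                       window_frames)
        t = acf(x, max_lag=min(max_lag, x.size - 1), source="long_scale")
        t.window_start_frame = 0
        t.truncated = True
        return [t]
    out = []
    for start in range(0, x.size - window_frames + 1, hop):
        t = acf(x[start:start + window_frames], max_lag=max_lag,
                source="long_scale")
        t.window_start_frame = start
        out.append(t)
    return out


def periodicity_index(
    trace: AcfTrace,
    prominence: float = PI_PROMINENCE,
    height: float = PI_HEIGHT,
) -> PeriodicityResult:
    """Shoulder-peak Periodicity Index of one ACF.

    Positive-lag peaks are screened at the prominence and height
    thresholds; the qualifying peak nearest zero lag is the shoulder, and
    PI = shoulder height (the central peak is 1 after normalization).
    With no qualifying peak — or a degenerate ACF — the signal is
    non-periodic and PI is undefined.  Only positive lags are searched:
    the ACF is even, so negative lags are redundant.
    """
    if trace.degenerate:
        return PeriodicityResult(pi=None, shoulder_lag_frames=None,
                                 is_periodic=False,
                                 prominence_threshold=prominence,
                                 height_threshold=height)
    vals = trace.values
    idx, _ = find_peaks(vals[1:], prominence=prominence, height=height)
    if idx.size == 0:
        return PeriodicityResult(pi=None, shoulder_lag_frames=None,
                                 is_periodic=False,
                                 prominence_threshold=prominence,
                                 height_threshold=height)
    shoulder = int(idx[0] + 1)
    return PeriodicityResult(pi=float(vals[shoulder]),
                             shoulder_lag_frames=shoulder, is_periodic=True,
                             prominence_threshold=prominence,
                             height_threshold=height)


def periodic_fraction(
    flags: np.ndarray | list[bool], durations_s: np.ndarray | list[float]
) -> float:
    """Time-weighted fraction of analyzed windows classified periodic.

    Returns NaN when there are no analyzed windows (distinguished from a
    genuine 0, which means every window was non-periodic).
    """
    flags = np.asarray(flags, dtype=bool)
    dur = np.asarray(durations_s, dtype=float)
    if flags.shape != dur.shape:
        raise ValueError("flags and durations must align")
    total = dur.sum()
    if flags.size == 0 or total <= 0:
        return float("nan")
    return float(dur[flags].sum() / total)
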
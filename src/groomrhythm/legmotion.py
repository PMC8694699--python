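"""Short-time-scale leg-movement counting from video pixel dynamics.

Grooming flies stand in place, so the dominant frame-to-frame pixel
changes in a cropped 80x80 view are made by the sweeping front legs.  The
counter works on non-overlapping (by default) 32-frame windows:

1. ``window_stack`` bins each 80x80 frame 2x2 (mean) down to 40x40 and
   flattens it row-major into 1600 pixel columns, giving a 32 x 1600
   windowed pixel matrix W.  (An 80x80 frame has 6400 pixels; the 1600
   columns of W imply this one-level spatial binning, which also makes
   neighboring pixels share signal.)
2. ``dynamics_matrix`` takes the central-difference temporal gradient of W,
   smooths it with a Gaussian (sigma 2 along time, 5 along the flattened
   pixel axis), and zeroes every column whose cumulative absolute change
   falls below a threshold theta = 5.0, keeping only pixels crossed by
   large periodic movements.  The result is the dynamics matrix D.
3. ``count_movements`` counts intensity peaks down each surviving column of
   D and takes the median count over columns: the number of leg sweeps or
   rubs in the window.
4. ``leg_frequency_series`` masks windows to frames the ethogram labels as
   anterior grooming and converts counts to a frequency in Hz.

A peak needs a sample on each side, so only the inner ``n_frames - 2``
rows of a window can host one; at 60 frames/s that is exactly 0.5 s for a
32-frame window, and counts are normalized by this effective duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import find_peaks

from .simgen import GROOMING_LABELS, FrameStack

__all__ = [
    "WINDOW_FRAMES",
    "WindowedPixelMatrix",
    "DynamicsMatrix",
    "LegFrequencySeries",
    "window_stack",
    "dynamics_matrix",
    "count_movements",
    "leg_frequency_series",
]

logger = logging.getLogger(__name__)

WINDOW_FRAMES = 32

# column-peak detection: minimum spacing 3 frames (caps the countable
# rhythm at ~10 Hz, above the ~7 Hz flies reach) and prominence 10% of the
# column's amplitude to ignore smoothing ripple
PEAK_MIN_DISTANCE = 3
PEAK_PROMINENCE_FRAC = 0.10


@dataclass
class WindowedPixelMatrix:
    """One 32 x 1600 window of flattened pixel intensities (matrix W)."""

    values: np.ndarray
    window_start_frame: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_FRAMES, 1600):
            raise ValueError(
                f"W must be {WINDOW_FRAMES} x 1600, got {self.values.shape}"
            )


@dataclass
class DynamicsMatrix:
    """Smoothed, thresholded temporal-gradient matrix D for one window."""

    values: np.ndarray
    threshold_used: float
    window_start_frame: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WINDOW_FRAMES, 1600):
            raise ValueError(
                f"D must be {WINDOW_FRAMES} x 1600, got {self.values.shape}"
            )

    @property
    def surviving_columns(self) -> np.ndarray:
        """Indices of columns not zeroed by the threshold."""
        return np.nonzero(np.any(self.values != 0.0, axis=0))[0]


@dataclass
class LegFrequencySeries:
    """Per-window movement counts and frequencies over a recording.

    ``table`` has one row per window: ``window_start``, ``count``,
    ``freq_hz`` (NaN where masked), ``masked``.  ``window_duration_s`` is
    the peak-detectable span ``(window - 2) / frame_rate`` used to convert
    counts to Hz, and ``freq_hz = count / window_duration_s`` for every
    unmasked window.
    """

    table: pd.DataFrame
    frame_rate_hz: float
    window_frames: int = WINDOW_FRAMES

    @property
    def window_duration_s(self) -> float:
        return (self.window_frames - 2) / self.frame_rate_hz

    @property
    def unmasked(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[~self.table["masked"].astype(bool)]

    @property
    def mean_frequency_hz(self) -> float:
        vals = self.unmasked["freq_hz"]
        return float(vals.mean()) if len(vals) else float("nan")


def window_stack(frames: FrameStack | np.ndarray, window_start: int) -> WindowedPixelMatrix:
    """Extract the 32-frame window starting at ``window_start`` as W.

    Each 80x80 frame is 2x2 mean-binned to 40x40 and flattened row-major,
    so row t of W holds frame ``window_start + t`` and binned pixel (i, j)
    maps to column ``i * 40 + j``.

    Raises ``ValueError`` if fewer than 32 frames remain from
    ``window_start``.
    """
    arr = frames.frames if isinstance(frames, FrameStack) else np.asarray(frames)
    if window_start < 0 or window_start + WINDOW_FRAMES > arr.shape[0]:
        raise ValueError(
            f"window [{window_start}, {window_start + WINDOW_FRAMES}) exceeds "
            f"the {arr.shape[0]}-frame stack"
        )
    win = np.asarray(arr[window_start:window_start + WINDOW_FRAMES], dtype=float)
    binned = win.reshape(WINDOW_FRAMES, 40, 2, 40, 2).mean(axis=(2, 4))
    w = binned.reshape(WINDOW_FRAMES, 1600)
    return WindowedPixelMatrix(values=w, window_start_frame=window_start)


def dynamics_matrix(
    w: WindowedPixelMatrix,
    sigma_time: float = 2.0,
    sigma_space: float = 5.0,
    theta: float = 5.0,
) -> DynamicsMatrix:
    """Temporal-gradient dynamics matrix D with smoothing and thresholding.

    Central-difference gradient down each column, Gaussian smoothing with
    ``sigma = (sigma_time, sigma_space)``, then any column whose summed
    absolute change is below ``theta`` is zeroed in full.
    """
    if not np.all(np.isfinite(w.values)):
        raise ValueError("pixel values must be finite")
    d = np.gradient(w.values, axis=0)
    d = gaussian_filter(d, sigma=(sigma_time, sigma_space))
    cumulative = np.sum(np.abs(d), axis=0)
    d[:, cumulative < theta] = 0.0
    return DynamicsMatrix(values=d, threshold_used=theta,
                          window_start_frame=w.window_start_frame)


def _column_peak_count(col: np.ndarray) -> int:
    amp = float(col.max() - col.min())
    if amp <= 0.0:
        return 0
    peaks, _ = find_peaks(col, distance=PEAK_MIN_DISTANCE,
                          prominence=PEAK_PROMINENCE_FRAC * amp)
    return int(len(peaks))


def count_movements(d: DynamicsMatrix) -> float:
    """Median per-column peak count over surviving columns of D.

    Returns 0 when no column survives thresholding (degenerate window).
    """
    cols = d.surviving_columns
    if cols.size == 0:
        logger.debug("window %d: no columns survived thresholding",
                     d.window_start_frame)
        return 0.0
    counts = [_column_peak_count(d.values[:, c]) for c in cols]
    return float(np.median(counts))


def leg_frequency_series(
    frames: FrameStack,
    ethogram: np.ndarray,
    hop: int = WINDOW_FRAMES,
    sigma_time: float = 2.0,
    sigma_space: float = 5.0,
    theta: float = 5.0,
) -> LegFrequencySeries:
    """Sliding-window leg-movement frequency over a recording.

    Windows advance by ``hop`` frames (default 32 = non-overlapping).  A
    window enters the series only if every one of its frames carries an
    anterior-grooming label (front-leg rub or head clean); all other
    windows are masked and carry no frequency.
    """
    ethogram = np.asarray(ethogram)
    if ethogram.shape[0] != frames.n_frames:
        raise ValueError(
            f"ethogram length {ethogram.shape[0]} does not match the "
            f"{frames.n_frames}-frame stack"
        )
    if hop < 1:
        raise ValueError("hop must be >= 1")
    grooming = np.isin(ethogram, sorted(GROOMING_LABELS))
    duration = (WINDOW_FRAMES - 2) / frames.frame_rate_hz

    # Gradient and smoothing run over each maximal contiguous grooming run,
    # then the result is sliced into windows.  Smoothing every 32-frame
    # window in isolation flattens real peaks within ~2*sigma_time of the
    # window edges (boundary padding has no data to extend), which
    # systematically undercounts; smoothing within runs keeps windows
    # interior to a run artifact-free while masked frames never influence
    # any analyzed window.
    n = frames.n_frames
    binned = (np.asarray(frames.frames, dtype=float)
              .reshape(n, 40, 2, 40, 2).mean(axis=(2, 4)).reshape(n, 1600))
    dyn = np.zeros_like(binned)
    padded = np.concatenate([[False], grooming, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= 2:
            dyn[a:b] = gaussian_filter(np.gradient(binned[a:b], axis=0),
                                       sigma=(sigma_time, sigma_space))

    rows = []
    for start in range(0, n - WINDOW_FRAMES + 1, hop):
        stop = start + WINDOW_FRAMES
        if not grooming[start:stop].all():
            rows.append({"window_start": start, "count": np.nan,
                         "freq_hz": np.nan, "masked": True})
            continue
        dwin = dyn[start:stop].copy()
        dwin[:, np.sum(np.abs(dwin), axis=0) < theta] = 0.0
        d = DynamicsMatrix(values=dwin, threshold_used=theta,
                           window_start_frame=start)
        count = count_movements(d)
        rows.append({"window_start": start, "count": count,
                     "freq_hz": count / duration, "masked": False})
    table = pd.DataFrame(rows, columns=["window_start", "count", "freq_hz", "masked"])
    return LegFrequencySeries(table=table, frame_rate_hz=frames.frame_rate_hz)
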
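"""Behavioral-confidence signal and long-time-scale bout cycles.

The slow rhythm of anterior grooming is the alternation between bouts of
front-leg rubbing (f) and head cleaning (h).  It is quantified from the
classifier probabilities through the behavioral confidence

    BC = P(f) - P(h),

a signal in [-1, 1] whose maxima sit at f-bout centers and minima at
h-bout centers.  BC is denoised with two consecutive Savitzky-Golay passes
(31-frame window, 0.5 s at 60 Hz).  Peaks and valleys are detected with
prominence 0.1 and minimum height 0.05 (valleys on the negated signal);
the span between consecutive peaks is an ff-cycle and between consecutive
valleys an hh-cycle, each with frequency f = 1/L for cycle length L in
seconds.  Cycles longer than a cutoff (280 frames, ~4.7 s; 380 for the
TNT sensory-inhibition condition whose cycles run long) are discarded as
transitions between grooming episodes rather than genuine alternations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .legmotion import LegFrequencySeries
from .simgen import ProbabilityTracePair

__all__ = [
    "SMOOTHING_WINDOW_FRAMES",
    "MAX_CYCLE_FRAMES",
    "MAX_CYCLE_FRAMES_TNT",
    "ConfidenceTrace",
    "Cycle",
    "CycleSet",
    "confidence",
    "extract_cycles",
    "cycle_frequency_stats",
    "movements_per_cycle",
]

logger = logging.getLogger(__name__)

SMOOTHING_WINDOW_FRAMES = 31
SMOOTHING_POLYORDER = 3      # filter family and window are fixed; order is ours
PEAK_PROMINENCE = 0.1
PEAK_HEIGHT = 0.05
MAX_CYCLE_FRAMES = 280
MAX_CYCLE_FRAMES_TNT = 380


@dataclass
class ConfidenceTrace:
    """Smoothed behavioral-confidence signal BC = P(f) - P(h)."""

    bc: np.ndarray
    frame_rate_hz: float
    smoothing_window_frames: int = SMOOTHING_WINDOW_FRAMES

    def __post_init__(self) -> None:
        self.bc = np.asarray(self.bc, dtype=float)

    @property
    def n_frames(self) -> int:
        return int(self.bc.size)


@dataclass(frozen=True)
class Cycle:
    """One bout cycle: peak-to-peak (ff) or valley-to-valley (hh) span."""

    kind: str                  # "ff" or "hh"
    start_frame: int
    end_frame: int
    length_frames: int
    length_s: float
    frequency_hz: float


@dataclass
class CycleSet:
    """All retained ff- and hh-cycles of one recording."""

    cycles: list[Cycle]
    max_duration_frames: int
    frame_rate_hz: float

    def __post_init__(self) -> None:
        for c in self.cycles:
            if c.length_frames > self.max_duration_frames:
                raise ValueError(
                    f"cycle of {c.length_frames} frames exceeds the "
                    f"{self.max_duration_frames}-frame cutoff"
                )

    def __len__(self) -> int:
        return len(self.cycles)

    def select(self, which: str = "both") -> list[Cycle]:
        if which not in ("ff", "hh", "both"):
            raise ValueError("which must be 'ff', 'hh' or 'both'")
        if which == "both":
            return list(self.cycles)
        return [c for c in self.cycles if c.kind == which]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"kind": c.kind, "start_frame": c.start_frame,
              "end_frame": c.end_frame, "length_frames": c.length_frames,
              "length_s": c.length_s, "frequency_hz": c.frequency_hz}
             for c in self.cycles],
            columns=["kind", "start_frame", "end_frame", "length_frames",
                     "length_s", "frequency_hz"],
        )


def confidence(traces: ProbabilityTracePair) -> ConfidenceTrace:
    """Behavioral confidence BC = P(f) - P(h), smoothed twice.

    Two consecutive Savitzky-Golay passes (31-frame window, polynomial
    order 3) remove classifier flicker while preserving bout plateaus;
    smoothing leaves constants unchanged.
    """
    for name, p in (("p_f", traces.p_f), ("p_h", traces.p_h)):
        if np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0:
            raise ValueError(f"{name} contains values outside [0, 1]")
    bc = traces.p_f - traces.p_h
    if bc.size >= SMOOTHING_WINDOW_FRAMES:
        bc = savgol_filter(bc, SMOOTHING_WINDOW_FRAMES, SMOOTHING_POLYORDER)
        bc = savgol_filter(bc, SMOOTHING_WINDOW_FRAMES, SMOOTHING_POLYORDER)
    return ConfidenceTrace(bc=bc, frame_rate_hz=traces.frame_rate_hz)


def _centers(idx: np.ndarray, props: dict) -> np.ndarray:
    """Peak positions with plateau peaks resolved to the plateau midpoint."""
    if "left_edges" in props and len(idx):
        return ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    return idx


def extract_cycles(
    bc: ConfidenceTrace,
    max_duration_frames: int = MAX_CYCLE_FRAMES,
    prominence: float = PEAK_PROMINENCE,
    height: float = PEAK_HEIGHT,
) -> CycleSet:
    """Detect BC peaks/valleys and form ff- and hh-cycles.

    Peaks mark f-bout centers, valleys (peaks of -BC) h-bout centers.  No
    extremum is accepted within half a smoothing window of either trace
    end, where the filter output is boundary-dominated.  A flat trace
    yields an empty cycle set.
    """
    x = bc.bc
    fs = bc.frame_rate_hz
    edge = bc.smoothing_window_frames // 2
    cycles: list[Cycle] = []
    for kind, signal in (("ff", x), ("hh", -x)):
        idx, props = find_peaks(signal, prominence=prominence, height=height,
                                plateau_size=1)
        centers = _centers(idx, props)
        centers = centers[(centers >= edge) & (centers < x.size - edge)]
        for a, b in zip(centers[:-1], centers[1:]):
            length = int(b - a)
            if length > max_duration_frames:
                continue
            length_s = length / fs
            cycles.append(Cycle(kind=kind, start_frame=int(a), end_frame=int(b),
                                length_frames=length, length_s=length_s,
                                frequency_hz=1.0 / length_s))
    cycles.sort(key=lambda c: (c.start_frame, c.kind))
    return CycleSet(cycles=cycles, max_duration_frames=max_duration_frames,
                    frame_rate_hz=fs)


def cycle_frequency_stats(cycles: CycleSet, which: str = "both") -> dict:
    """Mean and median of the per-cycle frequencies 1/L.

    Returns ``{"mean_hz": nan, "median_hz": nan, "n": 0}`` for an empty
    selection, so downstream aggregation can distinguish missing data.
    """
    sel = cycles.select(which)
    if not sel:
        return {"mean_hz": float("nan"), "median_hz": float("nan"), "n": 0}
    f = np.array([c.frequency_hz for c in sel])
    return {"mean_hz": float(f.mean()), "median_hz": float(np.median(f)),
            "n": int(f.size)}


def movements_per_cycle(
    cycles: CycleSet, leg_series: LegFrequencySeries
) -> pd.DataFrame:
    """Leg movements within each bout cycle.

    Integrates the per-window movement rate over each cycle span: each
    unmasked counting window contributes its rate weighted by the overlap
    (in seconds) between the window and the cycle, and the overlap-weighted
    mean rate is multiplied by the cycle duration, so partial windows are
    prorated and coverage gaps (masked windows inside a cycle) do not read
    as missing movements.  Cycles with no unmasked window overlap are
    skipped.  Returns one row per retained cycle with columns
    ``kind, start_frame, end_frame, movements``.
    """
    un = leg_series.unmasked
    fs = leg_series.frame_rate_hz
    win = leg_series.window_frames
    starts = un["window_start"].to_numpy()
    rates = un["freq_hz"].to_numpy(dtype=float)
    rows = []
    for c in cycles.cycles:
        lo = np.maximum(c.start_frame, starts)
        hi = np.minimum(c.end_frame, starts + win)
        overlap_s = np.clip(hi - lo, 0, None) / fs
        covered = overlap_s.sum()
        if covered <= 0:
            logger.debug("cycle at frame %d has no unmasked windows; skipped",
                         c.start_frame)
            continue
        mean_rate = float(np.sum(rates * overlap_s) / covered)
        rows.append({"kind": c.kind, "start_frame": c.start_frame,
                     "end_frame": c.end_frame,
                     "movements": mean_rate * c.length_s})
    return pd.DataFrame(rows, columns=["kind", "start_frame", "end_frame",
                                       "movements"])
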
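"""Synthetic generator for nested-oscillator grooming recordings.

Anterior grooming in *Drosophila* is rhythmic on two nested time scales:
individual leg sweeps and rubs repeat at ~5-7 Hz (the fast oscillator),
while bouts of head cleaning and front-leg rubbing alternate at ~0.3-0.6 Hz
(the slow oscillator).  This module emulates the three observables the
analysis pipeline consumes -- 80x80 grayscale video, per-frame behavior
probabilities P(f)/P(h) from a classifier, and a 7-category ethogram --
driven by a single latent state so that all three are mutually consistent,
together with a :class:`GroundTruth` record for recovery testing.

Grooming time is split into episodes separated by non-grooming gaps
(walking, standing, posterior grooming).  Each episode is either
*phase-coherent* (a latent phase advances uniformly at the slow frequency
and bouts are a soft square wave of that phase) or *non-coherent* (bout
durations are drawn from a gamma distribution with the same mean but no
phase memory).  The mixture of the two modes is balanced so that the
realized phase-coherent share of grooming time tracks
``periodic_fraction``.

Presets encode the study conditions: dust-stimulated flies, optogenetic
activation of mechanosensory bristles, spontaneous grooming (where the two
time scales decouple), and TNT sensory-feedback inhibition (slower bout
alternation).  Frequencies interpolate linearly over the 18-30 degC range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

__all__ = [
    "ETHOGRAM_LABELS",
    "GROOMING_LABELS",
    "CONDITIONS",
    "SimConfig",
    "GroundTruth",
    "Episode",
    "FrameStack",
    "ProbabilityTracePair",
    "VideoGeometry",
    "preset",
    "generate_traces",
    "generate_video",
    "generate_recording",
    "sample_fly_means",
]

#: The seven behavior categories of the ethogram alphabet.
ETHOGRAM_LABELS = (
    "front_leg_rub",
    "head_clean",
    "back_leg_rub",
    "abdominal_clean",
    "wing_clean",
    "walking",
    "standing",
)

#: Anterior-grooming labels: the two behaviors carrying both rhythms.
GROOMING_LABELS = frozenset({"front_leg_rub", "head_clean"})

CONDITIONS = ("dusted", "optogenetic", "spontaneous", "tnt")

# Logistic steepness of the soft square wave mapping slow phase -> bout
# identity.  5.0 gives bout plateaus (p ~ 0.99 mid-bout) with smooth,
# sub-second transitions, matching classifier confidence traces.
BOUT_STEEPNESS = 5.0

# Non-coherent bout durations: a 0.5 s floor (a bout is a run of repeated
# leg movements, so anything under ~3 movements at ~6 Hz is not scoreable
# as a bout) plus a gamma(2) excess, with the mean matched to half a slow
# cycle so coherent and non-coherent episodes share a mean bout length.
NONPERIODIC_GAMMA_SHAPE = 2.0
BOUT_MIN_S = 0.5

# Episode/gap structure (seconds).  Dusted flies groom in sustained
# episodes broken by brief walking or posterior-grooming interludes.
# Each episode carries one coherence flag; keeping episode durations in a
# common band for both modes makes windowed statistics weight the two
# modes by time, not by island length.
EPISODE_MEAN_S = 45.0
EPISODE_MIN_S = 20.0
EPISODE_MAX_S = 60.0
GAP_MEAN_S = 5.0
GAP_MIN_S = 1.0
GAP_MAX_S = 15.0

_GAP_LABELS = ("walking", "standing", "back_leg_rub", "abdominal_clean", "wing_clean")
_GAP_PROBS = (0.55, 0.25, 0.07, 0.07, 0.06)

# Observation-noise conversion.  ``noise_sd`` is a single unitless level:
# on the probability channel it is applied on the logit scale with
# sd = 4*noise_sd (the logistic slope at p=0.5 is 1/4, so the induced
# probability-scale sd near 0.5 is ~noise_sd); on the video it becomes
# additive pixel noise of sd = 20*noise_sd intensity units on the 0-255
# scale (default 0.05 -> sd 1.0, typical of an 8-bit sensor).
LOGIT_NOISE_SCALE = 4.0
PIXEL_NOISE_SCALE = 20.0


# --------------------------------------------------------------------------
# configuration and presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic recording."""

    condition: str
    temperature_C: float
    duration_s: float
    f_fast_hz: float
    f_slow_hz: float
    periodic_fraction: float
    frame_rate_hz: float = 60.0
    noise_sd: float = 0.05
    fast_jitter_cv: float = 0.15
    bout_freq_split: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 < self.f_slow_hz < self.f_fast_hz < self.frame_rate_hz / 2.0):
            raise ValueError(
                "require 0 < f_slow_hz < f_fast_hz < frame_rate_hz/2 "
                f"(got f_slow={self.f_slow_hz}, f_fast={self.f_fast_hz}, "
                f"rate={self.frame_rate_hz}); the fast rhythm must stay below "
                "the Nyquist limit"
            )
        if not (0.0 <= self.periodic_fraction <= 1.0):
            raise ValueError("periodic_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fast_jitter_cv < 0:
            raise ValueError("fast_jitter_cv must be non-negative")
        if not (0.0 <= self.bout_freq_split < 1.0):
            raise ValueError("bout_freq_split must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def max_cycle_frames(self) -> int:
        """Bout-cycle duration cutoff: 380 frames for the TNT condition
        (whose cycles are extraordinarily long), 280 otherwise."""
        return 380 if self.condition == "tnt" else 280


# Preset endpoint tables: values at 18 degC and 30 degC, interpolated
# linearly in between.  Dusted endpoints are the measured means (fast
# 5.7->6.6 Hz, slow 0.42->0.49 Hz, 80% of long-time-scale behavior
# phase-coherent at 18 degC); optogenetic frequencies are similar but the
# coherent share drops to 62%; spontaneous flies run faster fast rhythms
# (5.85->7.15 Hz) with a temperature-insensitive slow rhythm (the two
# oscillators decouple); TNT sensory inhibition slows the bout alternation.
_PRESETS: dict[str, dict[str, tuple[float, float] | float]] = {
    "dusted": {"f_fast": (5.7, 6.6), "f_slow": (0.42, 0.49), "pf": 0.80},
    "optogenetic": {"f_fast": (5.7, 6.6), "f_slow": (0.42, 0.49), "pf": 0.62},
    "spontaneous": {"f_fast": (5.85, 7.15), "f_slow": (0.45, 0.45), "pf": 0.50},
    "tnt": {"f_fast": (5.4, 6.3), "f_slow": (0.30, 0.35), "pf": 0.70},
}

_T_LO, _T_HI = 18.0, 30.0


def _interp(endpoints: tuple[float, float], temperature_C: float) -> float:
    lo, hi = endpoints
    w = (temperature_C - _T_LO) / (_T_HI - _T_LO)
    return lo + w * (hi - lo)


def preset(
    condition: str,
    temperature_C: float,
    *,
    duration_s: float = 780.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> SimConfig:
    """Study-condition preset at a given temperature.

    Parameters
    ----------
    condition:
        One of ``dusted``, ``optogenetic``, ``spontaneous``, ``tnt``.
    temperature_C:
        Recording temperature, 18-30 degC.
    duration_s:
        Recording length; defaults to the 13-minute protocol.

    Returns
    -------
    SimConfig
        Generator configuration with fast/slow frequencies interpolated
        between that condition's 18 degC and 30 degC endpoints.
    """
    if condition not in _PRESETS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    if not (_T_LO <= temperature_C <= _T_HI):
        raise ValueError(
            f"temperature {temperature_C} degC outside the study range "
            f"[{_T_LO}, {_T_HI}]"
        )
    tab = _PRESETS[condition]
    return SimConfig(
        condition=condition,
        temperature_C=float(temperature_C),
        duration_s=float(duration_s),
        f_fast_hz=_interp(tab["f_fast"], temperature_C),
        f_slow_hz=_interp(tab["f_slow"], temperature_C),
        periodic_fraction=float(tab["pf"]),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Episode:
    """One grooming episode, half-open frame span [start, end)."""

    start: int
    end: int
    periodic: bool

    @property
    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class GroundTruth:
    """Latent state of a synthetic recording, the oracle for recovery tests.

    ``mode`` holds one character per frame: ``'f'`` (front-leg-rub bout),
    ``'h'`` (head-clean bout) or ``'n'`` (non-grooming).  Generating
    frequencies are constant over a recording, so they are stored as
    scalars; the per-frame instantaneous value is that scalar wherever
    ``mode != 'n'``.
    """

    mode: np.ndarray
    f_fast_hz: float
    f_slow_hz: float
    bout_boundaries: np.ndarray
    episodes: list[Episode]
    frame_rate_hz: float
    #: per-frame instantaneous fast frequency (Hz); equals the nominal
    #: ``f_fast_hz`` when jitter is disabled, meaningful only while grooming
    f_fast_inst_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.bout_boundaries)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("bout boundaries must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.mode.size)

    @property
    def grooming_mask(self) -> np.ndarray:
        return self.mode != "n"

    @property
    def realized_periodic_fraction(self) -> float:
        """Share of grooming time inside phase-coherent episodes."""
        groom = int(np.count_nonzero(self.grooming_mask))
        if groom == 0:
            return float("nan")
        per = sum(e.n_frames for e in self.episodes if e.periodic)
        return per / groom


@dataclass
class ProbabilityTracePair:
    """Per-frame classifier probabilities for front-leg rubbing and head
    cleaning, both in [0, 1]."""

    p_f: np.ndarray
    p_h: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.p_f = np.asarray(self.p_f, dtype=float)
        self.p_h = np.asarray(self.p_h, dtype=float)
        if self.p_f.shape != self.p_h.shape:
            raise ValueError("p_f and p_h must have equal length")
        for name, p in (("p_f", self.p_f), ("p_h", self.p_h)):
            if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class FrameStack:
    """Time-ordered stack of 80x80 grayscale frames."""

    frames: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (80, 80):
            raise ValueError(
                f"frames must be T x 80 x 80, got shape {self.frames.shape}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# --------------------------------------------------------------------------
# latent-state simulation
# --------------------------------------------------------------------------

@dataclass
class _Latent:
    mode: np.ndarray            # 'f'/'h'/'n' per frame
    logit_f: np.ndarray         # latent classifier logit for f
    logit_h: np.ndarray
    fast_phase: np.ndarray      # radians, advances only during grooming
    f_fast_inst: np.ndarray     # instantaneous fast frequency per frame
    ethogram: np.ndarray        # full 7-category labels
    bout_boundaries: np.ndarray
    episodes: list[Episode]


def _segment_timeline(config: SimConfig, rng: np.random.Generator):
    """Alternate grooming episodes and non-grooming gaps over the recording.

    Each episode is flagged phase-coherent or not by a deficit rule —
    coherent whenever accumulated coherent time trails
    ``periodic_fraction`` of grooming time (anticipating half a mean
    episode) — so the realized mixture tracks the target tightly at any
    duration.  The rule never looks at the current episode's length,
    keeping flags independent of duration: combined with the common
    episode-length band this makes windowed statistics (which weight each
    grooming island by its length minus the window span) see the two
    modes in their time proportions.  The final episode is the one
    exception: its flag minimizes the closing error.
    """
    fs = config.frame_rate_hz
    n = config.n_frames
    target = config.periodic_fraction

    spans: list[tuple[int, int]] = []
    gaps: list[tuple[int, int, str]] = []
    t = 0
    grooming = True  # recordings open with grooming
    while t < n:
        if grooming:
            dur_s = float(np.clip(rng.exponential(EPISODE_MEAN_S),
                                  EPISODE_MIN_S, EPISODE_MAX_S))
            end = min(n, t + int(round(dur_s * fs)))
            spans.append((t, end))
        else:
            dur_s = float(np.clip(rng.exponential(GAP_MEAN_S),
                                  GAP_MIN_S, GAP_MAX_S))
            end = min(n, t + int(round(dur_s * fs)))
            label = str(rng.choice(_GAP_LABELS, p=_GAP_PROBS))
            gaps.append((t, end, label))
        t = end
        grooming = not grooming

    episodes: list[Episode] = []
    t_periodic = 0
    t_groom = 0
    # mean of the clipped exponential episode-length distribution
    half_mean = 0.5 * fs * min(EPISODE_MEAN_S, 0.5 * (EPISODE_MIN_S
                                                      + EPISODE_MAX_S))
    for i, (start, end) in enumerate(spans):
        d = end - start
        if t_groom == 0:
            flag = bool(rng.random() < target)
        else:
            flag = t_periodic < target * (t_groom + half_mean)
        if i == len(spans) - 1 and t_groom > 0:
            err_p = abs((t_periodic + d) / (t_groom + d) - target)
            err_n = abs(t_periodic / (t_groom + d) - target)
            flag = err_p <= err_n
        t_groom += d
        if flag:
            t_periodic += d
        episodes.append(Episode(start, end, flag))
    return episodes, gaps


def _simulate_latent(config: SimConfig, rng: np.random.Generator) -> _Latent:
    fs = config.frame_rate_hz
    n = config.n_frames
    if n < fs / config.f_slow_hz:
        raise ValueError(
            f"duration {config.duration_s} s is too short to contain one "
            f"slow cycle (1/f_slow = {1.0 / config.f_slow_hz:.2f} s)"
        )
    episodes, gaps = _segment_timeline(config, rng)

    mode = np.full(n, "n", dtype="<U1")
    ethogram = np.full(n, "standing", dtype="<U16")
    logit_f = np.full(n, -BOUT_STEEPNESS)
    logit_h = np.full(n, -BOUT_STEEPNESS)
    boundaries: list[int] = []

    mean_bout_s = 1.0 / (2.0 * config.f_slow_hz)
    for ep in episodes:
        t = np.arange(ep.n_frames)
        if ep.periodic:
            phi0 = rng.uniform(0.0, 2.0 * np.pi)
            theta = phi0 + 2.0 * np.pi * config.f_slow_hz * t / fs
            s = np.sin(theta)
            sign = np.where(s >= 0, 1.0, -1.0)
            latent = s
        else:
            # No phase coherence: bout identities are independent draws
            # (flies choose subroutines stochastically, repeats included),
            # not forced f/h alternation -- forced alternation with jittered
            # timing would still be a rhythm.
            sign = np.empty(ep.n_frames)
            pos = 0
            excess = max(mean_bout_s - BOUT_MIN_S, 0.1 * mean_bout_s)
            while pos < ep.n_frames:
                d_s = BOUT_MIN_S + rng.gamma(NONPERIODIC_GAMMA_SHAPE,
                                             excess / NONPERIODIC_GAMMA_SHAPE)
                d = max(3, int(round(d_s * fs)))
                sign[pos:pos + d] = 1.0 if rng.random() < 0.5 else -1.0
                pos += d
            # soften bout edges so transitions resemble classifier output
            latent = gaussian_filter1d(sign, sigma=0.1 * fs, mode="nearest")
        sl = slice(ep.start, ep.end)
        mode[sl] = np.where(sign > 0, "f", "h")
        ethogram[sl] = np.where(sign > 0, "front_leg_rub", "head_clean")
        logit_f[sl] = BOUT_STEEPNESS * latent
        logit_h[sl] = -BOUT_STEEPNESS * latent
        flips = np.nonzero(np.diff(sign))[0]
        boundaries.extend((ep.start + flips + 1).tolist())

    for start, end, label in gaps:
        ethogram[start:end] = label

    # Fast phase advances only while grooming (legs otherwise idle or
    # walking).  The instantaneous fast frequency carries multiplicative
    # Ornstein-Uhlenbeck jitter (mean f_fast, stationary CV
    # ``fast_jitter_cv``, correlation time ~1 s): real sweep rhythms show
    # cycle-to-cycle variability, visible as several Hz of within-fly
    # spread in leg-movement frequency histograms.
    groom = mode != "n"
    if config.fast_jitter_cv > 0:
        tau_s = 1.0
        a = math.exp(-1.0 / (tau_s * fs))
        eps = rng.normal(0.0, config.fast_jitter_cv * math.sqrt(1 - a * a), n)
        jitter = np.empty(n)
        prev = rng.normal(0.0, config.fast_jitter_cv)
        for i in range(n):
            prev = a * prev + eps[i]
            jitter[i] = prev
        f_inst = config.f_fast_hz * np.maximum(0.1, 1.0 + jitter)
    else:
        f_inst = np.full(n, config.f_fast_hz)
    # Head sweeps and leg rubs have distinct characteristic frequencies;
    # the combined analysis averages the two.  h-bouts run a fraction
    # ``bout_freq_split`` above the nominal fast frequency and f-bouts the
    # same fraction below, preserving the grooming-time mean.
    if config.bout_freq_split > 0:
        f_inst = f_inst * np.where(mode == "h", 1.0 + config.bout_freq_split,
                                   np.where(mode == "f",
                                            1.0 - config.bout_freq_split, 1.0))
    dphi = np.where(groom, 2.0 * np.pi * f_inst / fs, 0.0)
    fast_phase = np.concatenate([[0.0], np.cumsum(dphi)[:-1]]) + rng.uniform(
        0.0, 2.0 * np.pi
    )

    return _Latent(
        mode=mode,
        logit_f=logit_f,
        logit_h=logit_h,
        fast_phase=fast_phase,
        f_fast_inst=f_inst,
        ethogram=ethogram,
        bout_boundaries=np.asarray(sorted(set(boundaries)), dtype=int),
        episodes=episodes,
    )


def _ground_truth(config: SimConfig, latent: _Latent) -> GroundTruth:
    return GroundTruth(
        mode=latent.mode,
        f_fast_hz=config.f_fast_hz,
        f_slow_hz=config.f_slow_hz,
        bout_boundaries=latent.bout_boundaries,
        episodes=latent.episodes,
        frame_rate_hz=config.frame_rate_hz,
        f_fast_inst_hz=latent.f_fast_inst,
    )


# --------------------------------------------------------------------------
# trace generation
# --------------------------------------------------------------------------

def _traces_from_latent(
    config: SimConfig, latent: _Latent, rng: np.random.Generator
) -> ProbabilityTracePair:
    n = latent.mode.size
    sd = LOGIT_NOISE_SCALE * config.noise_sd
    eps_f = rng.normal(0.0, sd, n) if sd > 0 else 0.0
    eps_h = rng.normal(0.0, sd, n) if sd > 0 else 0.0
    p_f = np.clip(expit(latent.logit_f + eps_f), 0.0, 1.0)
    p_h = np.clip(expit(latent.logit_h + eps_h), 0.0, 1.0)
    return ProbabilityTracePair(p_f=p_f, p_h=p_h,
                                frame_rate_hz=config.frame_rate_hz)


def generate_traces(config: SimConfig) -> tuple[ProbabilityTracePair, GroundTruth]:
    """Simulate classifier probability traces P(f), P(h).

    Bouts follow the phase-coherent / non-coherent episode mixture; the
    probabilities are a logistic soft square wave of the latent bout state
    with i.i.d. Gaussian observation noise on the logit scale.  Identical
    config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, rng)
    traces = _traces_from_latent(config, latent, rng)
    return traces, _ground_truth(config, latent)


# --------------------------------------------------------------------------
# video generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VideoGeometry:
    """Pixel geometry of the rendered fly.

    The body is a static elliptical Gaussian; each front leg is a bright
    round blob oscillating along a fixed straight path near the head.
    During f-bouts (leg rubbing) the two legs move in anti-phase, during
    h-bouts (head cleaning) in phase.  Walking gaps translate the whole
    figure.  All paths must stay on the 80x80 canvas (with a margin for
    the walking excursion); this is validated before rendering.
    """

    body_center: tuple[float, float] = (46.0, 40.0)   # (row, col)
    body_sigma: tuple[float, float] = (13.0, 8.0)
    body_amplitude: float = 90.0
    left_leg_path: tuple[tuple[float, float], tuple[float, float]] = (
        (30.0, 31.0), (16.0, 26.0))                    # base -> tip
    right_leg_path: tuple[tuple[float, float], tuple[float, float]] = (
        (30.0, 49.0), (16.0, 54.0))
    leg_sigma: float = 2.0
    leg_amplitude: float = 160.0
    walk_amplitude_px: float = 5.0
    walk_rate_hz: float = 0.4

    def validate(self) -> None:
        margin = 2.0 * self.leg_sigma + self.walk_amplitude_px
        for (r0, c0), (r1, c1) in (self.left_leg_path, self.right_leg_path):
            for r, c in ((r0, c0), (r1, c1)):
                if not (margin <= r <= 80 - margin and margin <= c <= 80 - margin):
                    raise ValueError(
                        f"leg path point ({r}, {c}) leaves the 80x80 canvas "
                        f"(margin {margin:.1f} px incl. walking excursion)"
                    )

    def leg_tip_pixels(self) -> list[tuple[int, int]]:
        """Integer pixels at the path tips: these brighten exactly once per
        fast cycle (the leg's turning point), so their intensity trace
        oscillates at the generating fast frequency."""
        return [
            (int(round(self.left_leg_path[1][0])), int(round(self.left_leg_path[1][1]))),
            (int(round(self.right_leg_path[1][0])), int(round(self.right_leg_path[1][1]))),
        ]


def _render_blob(canvas: np.ndarray, r: float, c: float,
                 sigma: float, amp: float) -> None:
    rad = int(math.ceil(4.0 * sigma))
    r0, r1 = max(0, int(r) - rad), min(canvas.shape[0], int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(canvas.shape[1], int(c) + rad + 1)
    yy = np.arange(r0, r1)[:, None] - r
    xx = np.arange(c0, c1)[None, :] - c
    canvas[r0:r1, c0:c1] += amp * np.exp(-(yy * yy + xx * xx) / (2.0 * sigma ** 2))


def _video_from_latent(
    config: SimConfig,
    latent: _Latent,
    rng: np.random.Generator,
    geometry: VideoGeometry,
) -> FrameStack:
    geometry.validate()
    n = latent.mode.size
    fs = config.frame_rate_hz

    yy = np.arange(80)[:, None]
    xx = np.arange(80)[None, :]
    br, bc = geometry.body_center
    sr, sc = geometry.body_sigma
    body = geometry.body_amplitude * np.exp(
        -((yy - br) ** 2 / (2 * sr ** 2) + (xx - bc) ** 2 / (2 * sc ** 2))
    ).astype(np.float64)

    (lb, lt) = geometry.left_leg_path
    (rb, rt) = geometry.right_leg_path
    lb, lt, rb, rt = map(np.asarray, (lb, lt, rb, rt))

    phase = latent.fast_phase
    groom = latent.mode != "n"
    h_bout = latent.mode == "h"
    walking = latent.ethogram == "walking"

    # leg position parameter s in [0, 1] along base->tip
    s_left = 0.5 + 0.5 * np.sin(phase)
    # anti-phase during f-bouts, in-phase during h-bouts
    s_right = np.where(h_bout, 0.5 + 0.5 * np.sin(phase),
                       0.5 + 0.5 * np.sin(phase + np.pi))
    s_left = np.where(groom, s_left, 0.5)
    s_right = np.where(groom, s_right, 0.5)

    # whole-figure translation during walking gaps
    t = np.arange(n) / fs
    wphase = 2.0 * np.pi * geometry.walk_rate_hz * t + rng.uniform(0, 2 * np.pi)
    off_r = np.where(walking, geometry.walk_amplitude_px * np.sin(wphase), 0.0)
    off_c = np.where(walking, geometry.walk_amplitude_px * np.cos(wphase), 0.0)

    frames = np.empty((n, 80, 80), dtype=np.float32)
    pixel_sd = PIXEL_NOISE_SCALE * config.noise_sd
    for i in range(n):
        if off_r[i] or off_c[i]:
            canvas = np.roll(body, (int(round(off_r[i])), int(round(off_c[i]))),
                             axis=(0, 1)).copy()
        else:
            canvas = body.copy()
        lpos = lb + s_left[i] * (lt - lb)
        rpos = rb + s_right[i] * (rt - rb)
        _render_blob(canvas, lpos[0] + off_r[i], lpos[1] + off_c[i],
                     geometry.leg_sigma, geometry.leg_amplitude)
        _render_blob(canvas, rpos[0] + off_r[i], rpos[1] + off_c[i],
                     geometry.leg_sigma, geometry.leg_amplitude)
        frames[i] = canvas
    if pixel_sd > 0:
        frames += rng.normal(0.0, pixel_sd, frames.shape).astype(np.float32)
    np.clip(frames, 0.0, 255.0, out=frames)
    return FrameStack(frames=frames, frame_rate_hz=fs)


def generate_video(
    config: SimConfig, geometry: VideoGeometry | None = None
) -> tuple[FrameStack, GroundTruth, np.ndarray]:
    """Simulate an 80x80 grooming video plus its ethogram.

    Returns the frame stack, the ground truth, and a per-frame ethogram
    array over the 7-category alphabet.
    """
    geometry = geometry or VideoGeometry()
    rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, rng)
    stack = _video_from_latent(config, latent, rng, geometry)
    return stack, _ground_truth(config, latent), latent.ethogram.copy()


def generate_recording(
    config: SimConfig, geometry: VideoGeometry | None = None
) -> tuple[FrameStack, ProbabilityTracePair, np.ndarray, GroundTruth]:
    """Simulate video, probability traces and ethogram from one shared
    latent state, so the short- and long-time-scale observables of a
    recording are mutually consistent.

    Returns ``(frames, traces, ethogram, ground_truth)``.
    """
    geometry = geometry or VideoGeometry()
    rng = np.random.default_rng(config.seed)
    latent = _simulate_latent(config, rng)
    traces = _traces_from_latent(config, latent, rng)
    stack = _video_from_latent(config, latent, rng, geometry)
    return stack, traces, latent.ethogram.copy(), _ground_truth(config, latent)


# --------------------------------------------------------------------------
# summary-level generator (for temperature-trend Monte Carlo)
# --------------------------------------------------------------------------

def sample_fly_means(
    condition: str,
    temperatures: Sequence[float],
    n_flies: int,
    seed: int,
    fast_sd: float = 0.2,
    slow_sd: tuple[float, float] = (0.02, 0.04),
):
    """Draw per-fly mean frequencies directly from a condition's presets.

    A lightweight stand-in for running the full video/trace pipeline on
    every fly: each fly's mean fast and slow frequency is the preset value
    at its temperature plus Gaussian between-fly scatter (fast scatter
    ``fast_sd`` Hz; slow scatter interpolating ``slow_sd`` across 18-30
    degC, matching the reported per-temperature dispersions).  Used for
    Monte-Carlo checks of the temperature-trend and coupling statistics.

    Returns a tidy :class:`pandas.DataFrame` with columns
    ``fly_id, condition, temperature_C, fast_hz, slow_hz``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for temp in temperatures:
        cfg = preset(condition, temp)
        ssd = _interp(slow_sd, temp)
        for i in range(n_flies):
            rows.append({
                "fly_id": f"{condition}_T{temp:g}_fly{i}",
                "condition": condition,
                "temperature_C": float(temp),
                "fast_hz": cfg.f_fast_hz + rng.normal(0.0, fast_sd),
                "slow_hz": cfg.f_slow_hz + rng.normal(0.0, ssd),
            })
    return pd.DataFrame(rows)
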
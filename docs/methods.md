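# Methods

## The model

Anterior grooming is treated as a two-level nested oscillator. A slow
oscillator (frequency `f_slow`, ~0.3–0.6 Hz) drives the alternation
between front-leg-rub (f) and head-clean (h) bouts; a fast oscillator
(`f_fast`, ~5–7 Hz) drives individual leg sweeps and rubs inside every
bout. Both frequencies rise linearly with temperature in the condition
presets, and in the coupled conditions (dusted, optogenetic) they rise at
the same relative rate. The analysis chain measures each level
independently — pixel-dynamics counting for the fast level, behavioral
confidence `BC = P(f) − P(h)` for the slow level — and the thermal module
asks whether the two measured trends are proportional.

## Synthetic recordings

The generator (`simgen`) emulates the three observables a real
experiment yields — video, classifier probabilities, ethogram — from one
latent state, so cross-stage analyses (e.g. movements per cycle) are
self-consistent.

**Timeline.** A recording alternates grooming episodes (exponential mean
45 s, clipped to 20–60 s) and non-grooming gaps (exponential mean 5 s,
clipped to 1–15 s; labeled walking, standing, or posterior grooming).
Dusted flies groom in sustained episodes with brief interludes; the gap
labels exercise ethogram masking downstream.

**Phase-coherent vs non-coherent grooming.** Grooming time is a mixture
of phase-coherent spans (a latent phase advances uniformly at `f_slow`;
bout identity is a logistic soft square wave of that phase, steepness 5,
giving plateau-like bouts with smooth transitions) and non-coherent spans
(bout durations 0.5 s + gamma(2) excess with mean matched to half a slow
cycle; bout identity an independent coin flip per bout). Two modeling
points matter here:

- *Bout floor.* A bout is a run of repeated leg movements; anything under
  ~3 movements (0.5 s at 6 Hz) is not scoreable as a bout, and without
  the floor the duration distribution produces unphysically short cycles
  that inflate mean `1/L`.
- *Independent identities.* "No phase coherence" must mean stochastic
  subroutine choice (repeats included), not forced f/h alternation with
  jittered timing — forced alternation is still a rhythm and classifies
  as periodic at this window length.

Each grooming episode carries one coherence flag, assigned by a deficit
rule that tracks the target `periodic_fraction` without looking at the
current episode's length; realized mixture fractions are within ±0.03 of
the target for 13-minute recordings. Flag–length independence matters
beyond fidelity: windowed statistics weight each grooming island by its
length minus the window span, so coherent and non-coherent episodes must
share one duration distribution (20–60 s here) for those statistics to
see the two modes in their time proportions.

**Fast oscillator.** The instantaneous fast frequency carries
multiplicative Ornstein–Uhlenbeck jitter (stationary CV 0.15, correlation
time 1 s) and h-bouts run 5 % above / f-bouts 5 % below the nominal
frequency (head sweeps and leg rubs have distinct characteristic
frequencies; the combined analysis averages them). Both effects are
mean-preserving. They reproduce the several-Hz within-fly spread of
per-window frequency estimates seen in real recordings — and that spread
is what lets the count-quantized estimator (one count per 0.5 s window,
i.e. 2 Hz steps) average to the true mean rather than snapping to the
nearest integer count.

**Video.** A static elliptical body blob plus two bright leg blobs
oscillating along fixed straight paths near the head: anti-phase during
f-bouts (rubbing), in-phase during h-bouts (head sweeps). Walking gaps
translate the whole figure; other gaps are still. Pixel noise is additive
Gaussian with sd `20·noise_sd` intensity units on a 0–255 scale (default
1.0, typical 8-bit sensor noise). Leg-path geometry is validated against
the canvas at call time; the path-tip pixels brighten exactly once per
fast cycle and are exposed for spectral checks.

**Observation noise.** `noise_sd` is one unitless level: probability
traces receive i.i.d. Gaussian noise on the logit scale with
sd `4·noise_sd` (≈ `noise_sd` on the probability scale near 0.5) before
the logistic squashing; video receives the pixel noise above. Process
variability (oscillator jitter) is deliberately separate from observation
noise — `noise_sd = 0` gives clean observations of a still-variable
rhythm, and `fast_jitter_cv = 0` freezes the oscillator itself.

**What the generator does not emulate.** Photorealistic flies, dust
dynamics, classifier-specific error structure (real CNN confidence dips
are state-dependent, not i.i.d.), posterior grooming kinematics, and any
within-fly temperature drift. Passing recovery tests therefore shows the
*pipeline* is correct and well-calibrated on data with the assumed
statistical structure, not that the biological estimates from real video
are unbiased.

## Analysis choices

**Windowed pixel matrix.** An 80×80 frame has 6400 pixels but the matrix
`W` has 1600 columns; frames are 2×2 mean-binned to 40×40 before
row-major flattening, which also makes neighboring pixels share signal.

**Frequency normalization.** `scipy.signal.find_peaks` cannot place a
peak on either boundary sample, so a 32-frame window has a 30-frame
(0.5 s at 60 Hz) peak-detectable span; counts are divided by this
effective duration, which is unbiased (dividing by the full 32/60 s
would undercount by 6 %).

**Run-wise smoothing.** The temporal gradient and Gaussian smoothing for
the leg counter run over each maximal contiguous grooming run, then the
result is sliced into windows. Smoothing 32-frame windows in isolation
flattens genuine peaks within ~2σ of the window edges and undercounts by
~15 %; run-wise smoothing removes the artifact while masked (non-grooming)
frames still never influence any analyzed window.

**Regime of validity of the counter.** Below ~5.5 Hz the temporal
smoothing (σ = 2 frames) no longer suppresses the double-crossing
harmonic — interior path pixels brighten twice per cycle — and counts
bias upward (≈ +10 % at 4 Hz). The counter is accurate (≤ 5 % mean error)
in the 5.5–7 Hz range flies actually use; tests assert recovery there and
only the 2 Hz quantization bound outside it.

**Movements per cycle.** Each cycle's movement total is the
overlap-weighted mean rate of the counting windows intersecting the
cycle, times the cycle duration. This prorates partial windows and is
robust to coverage gaps (masked windows inside a cycle do not read as
zero movements). Under the preset frequency ratios the expected value is
`f_fast/f_slow` ≈ 13.5–13.9 across temperatures.

**Cycle extraction details.** Savitzky–Golay order 3 for the 31-frame
smoother (the filter family and window are fixed; the order is this
package's choice — order 3 tracks bout plateaus without ringing).
Plateau peaks resolve to the plateau midpoint; no extremum is accepted
within half a smoothing window of either trace end, where the filter
output is boundary-dominated.

**ACF and PI.** The ACF is computed by direct lagged products,
mean-subtracted and normalized by the zero-lag autocovariance, so the
central peak is exactly 1 and the PI equals the shoulder height. Only
positive lags are searched (the ACF is even). A signal whose variance
cancels to float precision is flagged degenerate and classified
non-periodic. The shoulder must clear both the prominence and the height
threshold (0.2 each); the nearest qualifying peak defines PI and lag.
The stacked fast-scale ACF array keeps 60 symmetric lag bins per window
(lags −29…+30), mirroring the even positive-lag ACF.

**Long-scale windows.** 999 frames (16.6 s) with a configurable hop
(dense hop = 1 supported; drivers default to hop 333 ≈ 5.5 s, which
changes the periodic-fraction estimate by well under its seed-to-seed
spread at a third of the cost). A window enters the periodic-fraction
statistic only if all its frames are anterior grooming. At this window
length the BC of a non-coherent episode has only ~14 effectively
independent stretches (bout correlation time ~1 s), so the sample ACF
fluctuates with sd ≈ 0.25 and chance shoulders clear the 0.2 thresholds
in roughly a third of non-coherent windows. This inflates the classified
periodic fraction of an 80 % mixture to ~85–87 % — a property of the
shoulder rule at the stated window length that any data with this
structure shares, so measured periodic fractions should be read as upper
bounds on the true phase-coherent share.

**Thermal statistics.** Trends are OLS on per-temperature group means
(matching how per-temperature panels are drawn); a per-fly option is
exposed. Normalized rates divide by the minimum mean, so the minimum is
exactly 1. Missing flies or temperatures are dropped pairwise, never
imputed, and no outlier handling is applied.

**Summary-level Monte Carlo.** `simgen.sample_fly_means` draws per-fly
mean frequencies directly from the presets with between-fly scatter
(fast 0.2 Hz; slow 0.02→0.04 Hz across 18→30 °C, matching the reported
dispersions) for trend/coupling power checks without simulating video.

## Defaults and problem sizes

| Parameter | Default | Meaning |
|---|---|---|
| `frame_rate_hz` | 60 | recording rate; fast rhythm must stay below 30 Hz (Nyquist) |
| `theta` | 5.0 | dynamics-matrix column threshold (intensity units) |
| window | 32 frames | fast-scale counting window (0.5 s effective) |
| smoothing | σ = (2, 5) | Gaussian sigmas on (time, flattened pixel) axes |
| BC smoothing | 31 frames ×2 | Savitzky–Golay window, two passes, order 3 |
| cycle peaks | prom 0.1 / height 0.05 | BC extremum detection |
| cycle cutoff | 280 frames (380 TNT) | maximum ff/hh-cycle duration |
| PI thresholds | prom 0.2 / height 0.2 | shoulder qualification |
| long window | 999 frames | slow-scale ACF window (16.6 s) |
| `noise_sd` | 0.05 | observation-noise level (see conversions above) |
| `fast_jitter_cv` | 0.15 | fast-oscillator cycle-to-cycle CV |
| `bout_freq_split` | 0.05 | h/f bout frequency asymmetry |

Recovery tests and the acceptance script use 1–3 minute videos and
13-minute traces; the movements-per-cycle grand mean uses 8 flies × 7
temperatures × 90 s recordings. These sizes put Monte-Carlo error well
inside each quantity's tolerance while the whole acceptance run stays at
a few minutes on one CPU.

## Known limitations

- The leg counter is specific to the standing-fly, cropped-view setting;
  whole-body translation breaks the one-pixel-one-path assumption, which
  is why non-grooming windows must be masked, not just down-weighted.
- The PI's periodic/non-periodic boundary is threshold-based; weakly
  periodic behavior near PI ≈ 0.2 is classified unstably, and short
  windows (few slow cycles) have an irreducible false-positive rate for
  irregular bout sequences (quantified above).
- Mean `1/L` is convex in cycle length, so mean cycle frequency reads a
  few percent above the generating rate whenever the length distribution
  has mass below its mean; the median is the more robust location
  estimate and both are reported.
- Temperature enters only through the preset frequency endpoints; no
  Q10-style mechanistic model is implied.
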
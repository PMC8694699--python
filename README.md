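# groomrhythm

Quantitative analysis of the two nested rhythms of *Drosophila* anterior
grooming, for behavioral neuroscientists studying central pattern
generator (CPG) control.

Dust-covered flies groom with fast, stereotyped leg sweeps and rubs
(~5–7 Hz) organized into bouts of head cleaning (h) and front-leg rubbing
(f) that themselves alternate rhythmically (~0.3–0.6 Hz). Both rhythms
speed up with temperature — a hallmark of CPG control — and in stimulated
flies they speed up at the same relative rate, suggesting the fast and
slow oscillators are nested and linked. `groomrhythm` implements the full
measurement chain for these claims, plus a synthetic-recording generator
so every stage can be exercised and validated without any video data.

## The measurements

**Fast time scale (leg movements).** 80×80 grooming video is analyzed in
32-frame windows. Frames are binned to 40×40, flattened into a 32×1600
pixel matrix `W`; its temporal gradient is smoothed (Gaussian σ = [2, 5])
and columns whose cumulative absolute change falls below θ = 5.0 are
zeroed, giving the dynamics matrix `D`. Peaks are counted down each
surviving column and the **median count across columns** is the number of
leg sweeps/rubs in the window; counts per effective 0.5 s window give the
movement frequency.

**Slow time scale (bout cycles).** From classifier probabilities the
behavioral confidence is

    BC = P(f) − P(h),

smoothed twice with a 31-frame Savitzky–Golay filter. BC maxima mark
f-bout centers and minima h-bout centers (peak prominence 0.1, height
0.05). The span between consecutive maxima is an *ff-cycle*, between
consecutive minima an *hh-cycle*, with frequency `f = 1/L` for cycle
length `L` (cycles over 280 frames ≈ 4.7 s are discarded as transitions;
380 frames for the TNT sensory-inhibition condition).

**Periodicity.** For either scale, the autocorrelation function (ACF) is
mean-subtracted and normalized to 1 at zero lag. The **Periodicity Index
(PI)** is the height of the prominent shoulder peak nearest zero lag
(prominence and height thresholds both 0.2): 1 for a perfect sinusoid,
undefined — and the behavior non-periodic — when no shoulder qualifies.
The time-weighted fraction of 999-frame BC windows classified periodic
quantifies how much of grooming is rhythmic.

**Temperature scaling.** Per-fly summaries are aggregated into
per-temperature means, fit by OLS against temperature, and normalized by
the lowest mean (rate of change, minimum ≡ 1.0). Regressing the slow
rhythm's rates on the fast one's measures cross-time-scale coupling.

## Worked example

```bash
python examples/01_fast_rhythm_from_video.py
```

```
generating fast frequency : 5.70 Hz
grooming windows analyzed : 108 of 112
recovered mean frequency  : 5.85 Hz
per-window counts         : [2, 3, 4]
```

One minute of synthetic dusted-fly video at 18 °C is generated (fast
rhythm 5.7 Hz), non-grooming windows are masked out via the ethogram, and
the pixel-dynamics counter recovers the generating frequency within a few
percent; individual windows hold 2–4 movements each (quantization is one
count per 0.5 s). `examples/02…05` do the same for bout cycles (median
cycle frequency 0.420 Hz recovered from 13-minute traces at the 0.42 Hz
preset), the Periodicity Index (PI ≈ 0.96 for a pure sinusoid, white
noise rejected, classified periodic fraction ≈ 0.90 on an ~0.79
phase-coherent mixture — the shoulder rule overshoots by several points
on 16.6 s windows; see `docs/methods.md`), temperature trends and
coupling (dusted coupling R² ≈ 0.87 vs spontaneous ≈ 0.17), and the
end-to-end pipeline with its JSON report.

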
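"""Count leg movements from a synthetic grooming video.

Generates one minute of dusted-fly video at 18 degC (fast rhythm preset
5.7 Hz), runs the pixel-dynamics counter over grooming-masked 32-frame
windows, and prints the recovered movement frequency.
"""

from groomrhythm import legmotion, simgen

cfg = simgen.preset("dusted", 18, duration_s=60, seed=1)
stack, truth, ethogram = simgen.generate_video(cfg)
series = legmotion.leg_frequency_series(stack, ethogram)

un = series.unmasked
print(f"generating fast frequency : {truth.f_fast_hz:.2f} Hz")
print(f"grooming windows analyzed : {len(un)} of {len(series.table)}")
print(f"recovered mean frequency  : {series.mean_frequency_hz:.2f} Hz")
print(f"per-window counts         : {sorted(int(c) for c in un['count'].unique())}")
# The counter sees ~3 leg sweeps per 0.5 s window; the mean over windows
# recovers the generating frequency to within a few percent.
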
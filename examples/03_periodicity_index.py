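"""Classify periodic vs non-periodic grooming with the Periodicity Index.

The PI is the height of the autocorrelation's first prominent shoulder
peak over the central peak: 1 for a perfect sinusoid, undefined (and the
signal non-periodic) when no shoulder clears the 0.2 prominence/height
thresholds.  This script shows the index on a pure sinusoid, on white
noise, and on a dusted-preset mixture of phase-coherent and non-coherent
grooming.
"""

import numpy as np

from groomrhythm import boutcycles, rhythm, simgen

t = np.arange(3600) / 60.0
for name, signal in [
    ("0.4 Hz sinusoid", np.sin(2 * np.pi * 0.4 * t)),
    ("white noise", np.random.default_rng(0).normal(size=t.size)),
]:
    r = rhythm.periodicity_index(rhythm.acf(signal, max_lag=400))
    pi = f"{r.pi:.3f}" if r.is_periodic else "undefined"
    print(f"{name:18s}: periodic={r.is_periodic}  PI={pi}")

# 80% phase-coherent mixture, averaged over a few 13-minute recordings
fracs, mixtures, n_windows = [], [], 0
for seed in (3, 4, 5):
    traces, truth = simgen.generate_traces(simgen.preset("dusted", 18,
                                                         seed=seed))
    bc = boutcycles.confidence(traces)
    flags, durs = [], []
    for trace in rhythm.long_scale_acf(bc, hop=333):
        s = trace.window_start_frame
        if not truth.grooming_mask[s:s + 999].all():
            continue
        flags.append(rhythm.periodicity_index(trace).is_periodic)
        durs.append(999 / 60.0)
    fracs.append(rhythm.periodic_fraction(flags, durs))
    mixtures.append(truth.realized_periodic_fraction)
    n_windows += len(flags)
print(f"dusted 18C mixture: {n_windows} grooming windows over 3 recordings, "
      f"classified periodic fraction {np.mean(fracs):.2f} "
      f"(generator mixture {np.mean(mixtures):.2f})")
# The sinusoid scores PI ~ 1, noise is rejected, and the classified
# fraction tracks the generator's phase-coherent share of grooming time
# (a few points high: chance ACF shoulders in short windows, see docs).
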
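"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

from groomrhythm import simgen


@pytest.fixture(scope="session")
def dusted18_traces():
    """13-minute dusted 18 degC probability traces with ground truth."""
    cfg = simgen.preset("dusted", 18, seed=11)
    return simgen.generate_traces(cfg), cfg


@pytest.fixture(scope="session")
def dusted18_video():
    """One-minute dusted 18 degC video with ethogram and ground truth."""
    cfg = simgen.preset("dusted", 18, duration_s=60, seed=21)
    stack, gt, eth = simgen.generate_video(cfg)
    return stack, gt, eth, cfg


@pytest.fixture()
def clean_config():
    """Fully deterministic oscillator: no observation noise, no jitter."""
    def make(f_fast=6.0, f_slow=0.5, duration_s=30.0, periodic_fraction=1.0,
             seed=0, **kw):
        return simgen.SimConfig(
            condition="dusted", temperature_C=22.0, duration_s=duration_s,
            f_fast_hz=f_fast, f_slow_hz=f_slow,
            periodic_fraction=periodic_fraction, noise_sd=0.0,
            fast_jitter_cv=0.0, bout_freq_split=0.0, seed=seed, **kw)
    return make
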
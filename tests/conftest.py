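"""Shared fixtures: wavelet families and preprocessed synthetic recordings.

Session-scoped so that expensive syntheses and decompositions are built
once and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import swripple as sw
from swripple.preprocess import Recording, preprocess


@pytest.fixture(scope="session")
def family_1k() -> sw.WaveletFamily:
    return sw.build_wavelets(1000.0)


@pytest.fixture(scope="session")
def family_500() -> sw.WaveletFamily:
    return sw.build_wavelets(500.0)


@pytest.fixture(scope="session")
def nrem_run():
    """5-min two-channel NREM synthesis, preprocessed and decomposed.

    Strong, frequent ripples with co-occurring partners and SPWs: the
    workhorse input for detection, co-occurrence and locked analyses.
    """
    cfg = sw.SynthConfig(duration_s=300.0, seed=101,
                         ripple_rate_per_min=(12.0, 6.0),
                         ripple_amp_uv=(12.0, 10.0),
                         cooccurrence_prob=0.5,
                         cooccurrence_lag_sd_ms=15.0,
                         artifact_rate_per_min=0.5)
    channels, truth = sw.generate_recording(cfg)
    rec = Recording(channels=channels, fs=cfg.fs,
                    stages=["N2"] * int(cfg.duration_s / 20))
    clean, trials = preprocess(rec)
    return cfg, truth, clean, trials


@pytest.fixture(scope="session")
def nrem_events(nrem_run):
    """Detected ripples plus surrogate sets for both channels."""
    cfg, truth, clean, trials = nrem_run
    out = {}
    for ch in ("HPC", "AMY"):
        ev = sw.detect_ripples(clean.channels[ch], cfg.fs, trials,
                               channel=ch)
        surr = sw.make_surrogate_events(ev, trials, clean.n_samples, cfg.fs,
                                        n_sets=1000, seed=7)
        out[ch] = (ev, surr)
    return out


@pytest.fixture(scope="session")
def tf_runs(nrem_run, family_1k):
    cfg, truth, clean, trials = nrem_run
    return {ch: sw.decompose_trials(clean.channels[ch], cfg.fs, trials,
                                    family_1k, channel=ch)
            for ch in ("HPC", "AMY")}
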
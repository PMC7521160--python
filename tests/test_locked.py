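"""Ripple-locked ERP, ERP spectra, TF power and ITPC maps."""

import numpy as np
import pytest

import swripple as sw
from swripple.locked import erp_spectrum, locked_erp, locked_itpc, \
    locked_tf_power
from swripple.ripples import SurrogateEventSets
from swripple.timefreq import TFRun

FS = 1000.0


def _surrogates(rng, n_samples, n_sets, n_events, margin=760):
    peaks = rng.integers(margin, n_samples - margin, (n_sets, n_events))
    return SurrogateEventSets(channel="c", peaks=peaks)


def test_noiseless_identical_waveform_recovered():
    """ERP equals the (mean-centred) waveform; CI excludes its peak."""
    rng = np.random.default_rng(0)
    n = 300000
    x = 0.01 * rng.standard_normal(n)
    wave = np.sin(2 * np.pi * 4.0 * np.arange(1501) / FS)
    peaks = np.arange(5000, n - 5000, 5000)
    for p in peaks:
        x[p - 750:p + 751] += wave
    surr = _surrogates(rng, n, 300, len(peaks))
    t, erp, ci, low = locked_erp(x, peaks, surr, FS)
    assert not low
    np.testing.assert_allclose(erp, wave - wave.mean(), atol=0.01)
    ipk = np.argmax(np.abs(erp))
    assert erp[ipk] > ci[1, ipk] or erp[ipk] < ci[0, ipk]


def test_null_events_fall_inside_ci():
    """Random events on stationary noise: ERP inside the CI >=90%."""
    rng = np.random.default_rng(1)
    n = 200000
    x = rng.standard_normal(n)
    peaks = rng.integers(760, n - 760, 40)
    surr = _surrogates(rng, n, 400, 40)
    _, erp, ci, _ = locked_erp(x, peaks, surr, FS)
    inside = (erp >= ci[0]) & (erp <= ci[1])
    assert inside.mean() >= 0.9


def test_erp_spectrum_resolution_and_peak():
    """1.25-s windows zero-padded to 2048 give 0.488-Hz bins; a 4-Hz ERP
    peaks within one bin of 4 Hz."""
    rng = np.random.default_rng(2)
    erp = np.sin(2 * np.pi * 4.0 * np.arange(1501) / FS)
    surr_erps = 0.1 * rng.standard_normal((200, 1501))
    freqs, raw, z = erp_spectrum(erp, surr_erps, FS)
    assert np.diff(freqs)[0] == pytest.approx(1000.0 / 2048, rel=1e-9)
    assert np.diff(freqs)[0] == pytest.approx(0.488, abs=5e-4)
    assert abs(freqs[np.argmax(raw)] - 4.0) <= 0.49
    assert z[np.argmax(raw)] > 3.0


def _tf_run_from_noise(rng, n_cols, nf=50):
    vals = rng.standard_normal((nf, n_cols)) \
        + 1j * rng.standard_normal((nf, n_cols))
    return TFRun(channel="c", freqs=np.geomspace(0.5, 200, nf), fs_eff=250.0,
                 values=vals, col_sample=np.arange(n_cols) * 4,
                 col_stage=np.full(n_cols, "N2", dtype=object),
                 col_trial=np.zeros(n_cols, int))


def test_itpc_of_identical_snippets_is_one():
    rng = np.random.default_rng(3)
    run = _tf_run_from_noise(rng, 4000)
    period = 1000
    run.values[:] = np.tile(run.values[:, :period], (1, 4))
    peaks = (np.array([500, 1500, 2500]) * 4)
    surr = SurrogateEventSets(
        channel="c", peaks=(rng.integers(200, 3800, (100, 3)) * 4))
    mag = np.abs(run.values)
    phasors = run.values / mag
    cols = np.array([run.column_of_sample(p) for p in peaks])
    itpc = np.abs(phasors[:, cols[:, None]
                          + np.arange(-188, 189)].mean(axis=1))
    np.testing.assert_allclose(itpc, 1.0, atol=1e-12)


def test_null_itpc_z_calibrated():
    """Random events on noise: |z| < 2 for >=95% of map bins."""
    rng = np.random.default_rng(4)
    run = _tf_run_from_noise(rng, 30000, nf=20)
    peaks = rng.integers(800, 29000, 40) * 4
    surr = SurrogateEventSets(channel="c",
                              peaks=rng.integers(800, 29000, (400, 40)) * 4)
    _, z, levels, clusters = locked_itpc(run, peaks, surr)
    assert np.isfinite(z).all()
    assert np.mean(np.abs(z) < 2.0) >= 0.95


def test_null_power_z_calibrated():
    rng = np.random.default_rng(5)
    run = _tf_run_from_noise(rng, 30000, nf=20)
    peaks = rng.integers(800, 29000, 40) * 4
    surr = SurrogateEventSets(channel="c",
                              peaks=rng.integers(800, 29000, (400, 40)) * 4)
    _, z, levels, clusters = locked_tf_power(run, peaks, surr)
    assert np.mean(np.abs(z) < 2.0) >= 0.95
    assert not clusters


def test_locked_map_dimensions_and_determinism(tf_runs, nrem_events,
                                               nrem_run):
    cfg, truth, clean, trials = nrem_run
    events, surr = nrem_events["HPC"]
    run = tf_runs["HPC"]
    t, z1, lev1, cl1 = locked_tf_power(run, events, surr)
    _, z2, _, _ = locked_tf_power(run, events, surr)
    np.testing.assert_array_equal(z1, z2)
    assert z1.shape == (50, 377)
    assert t[0] == pytest.approx(-0.752) and t[-1] == pytest.approx(0.752)


def test_ripple_locked_maps_show_injected_structure(tf_runs, nrem_events,
                                                    nrem_run, family_1k):
    """Same-site maps: ripple-band power cluster at t~0 and 2-8-Hz ITPC
    cluster (ripples locked to the SPW phase)."""
    cfg, truth, clean, trials = nrem_run
    events, surr = nrem_events["HPC"]
    run = tf_runs["HPC"]
    lm = sw.locked_analyses(clean.channels["HPC"], run, events, surr, cfg.fs)
    freqs = family_1k.center_freqs
    band = (freqs >= 70) & (freqs <= 110)
    center = np.abs(lm.tf_t) < 0.05
    assert lm.power_z[np.ix_(band, center)].max() > max(lm.power_levels)
    spw_rows = (freqs >= 2) & (freqs <= 8)
    near = np.abs(lm.tf_t) < 0.3
    assert lm.itpc_z[np.ix_(spw_rows, near)].max() > 3.0
    # ERP shows a supra-CI deflection around the ripple
    mid = np.abs(lm.erp_t) < 0.3
    out = (lm.erp[mid] > lm.erp_ci[1, mid]) | (lm.erp[mid] < lm.erp_ci[0, mid])
    assert out.any()
    # ERP spectrum has a strong 2-8-Hz (SPW) peak
    spw_bins = (lm.erp_freqs >= 2) & (lm.erp_freqs <= 8)
    assert lm.erp_spectrum_z[spw_bins].max() > 3.0
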
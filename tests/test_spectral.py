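"""Welch spectra with duration weighting and 1/f adjustment."""

import numpy as np
import pytest

import swripple as sw
from swripple.preprocess import Trial
from swripple.spectral import Spectrum


def _trials(n, fs=1000.0, pieces=1):
    per = n // pieces
    return [Trial(channel="c", start=i * per, end=(i + 1) * per, stage="N2")
            for i in range(pieces)]


def test_welch_bin_spacing_is_printed_resolution():
    """3-s windows zero-padded to 4096 at 1 kHz give 0.244-Hz bins."""
    x = np.random.default_rng(0).standard_normal(30000)
    spec = sw.welch_psd(_trials(30000), x, 1000.0)
    assert np.diff(spec.freqs)[0] == pytest.approx(1000.0 / 4096, rel=1e-9)
    assert np.diff(spec.freqs)[0] == pytest.approx(0.244, abs=5e-4)


def test_sinusoid_peak_location():
    fs = 1000.0
    t = np.arange(30000) / fs
    x = np.sin(2 * np.pi * 10.0 * t)
    spec = sw.welch_psd(_trials(30000), x, fs)
    assert abs(spec.freqs[np.argmax(spec.power)] - 10.0) <= 0.25


def test_white_noise_total_power_parseval():
    """Integrated PSD recovers the white-noise variance within 10%."""
    rng = np.random.default_rng(1)
    sigma2 = 4.0
    x = np.sqrt(sigma2) * rng.standard_normal(120000)
    spec = sw.welch_psd(_trials(120000, pieces=4), x, 1000.0)
    total = np.sum(spec.power) * np.diff(spec.freqs)[0]
    assert total == pytest.approx(sigma2, rel=0.1)


def test_duration_weighted_average():
    """Two identical trials average to the same spectrum as one; a long
    trial outweighs a short one in proportion to its duration."""
    rng = np.random.default_rng(2)
    x = rng.standard_normal(40000)
    one = sw.welch_psd([Trial("c", 0, 20000, "N2")], x, 1000.0)
    two = sw.welch_psd([Trial("c", 0, 20000, "N2"),
                        Trial("c", 0, 20000, "N2")], x, 1000.0)
    np.testing.assert_allclose(one.power, two.power)
    assert two.total_weight == pytest.approx(2 * one.total_weight)
    # manual weighted mean across two different trials
    ta, tb = Trial("c", 0, 30000, "N2"), Trial("c", 30000, 40000, "N2")
    pa = sw.welch_psd([ta], x, 1000.0)
    pb = sw.welch_psd([tb], x, 1000.0)
    both = sw.welch_psd([ta, tb], x, 1000.0)
    manual = (30 * pa.power + 10 * pb.power) / 40
    np.testing.assert_allclose(both.power, manual, rtol=1e-10)


def test_empty_trials_error():
    with pytest.raises(ValueError):
        sw.welch_psd([], np.zeros(10), 1000.0)


def _power_law_spectrum(a=10.0, b=-2.0):
    freqs = np.fft.rfftfreq(4096, 1e-3)[1:]  # 0.244-Hz grid from ~0.24 Hz
    return Spectrum(freqs=freqs, power=a * freqs ** b, total_weight=60.0)


def test_pure_power_law_adjusts_to_zero():
    spec = _power_law_spectrum()
    adj = sw.adjust_one_over_f(spec)
    # notch-region interpolation perturbs the fit at the 1e-4 level
    assert adj.fit_b == pytest.approx(-2.0, abs=1e-3)
    assert adj.fit_a == pytest.approx(10.0, rel=1e-2)
    sel = (adj.freqs_log >= 4) & (adj.freqs_log <= 175)
    local = 10.0 * adj.freqs_log[sel] ** -2.0
    assert np.all(np.abs(adj.adjusted_power[sel]) < 0.01 * local)


def test_gaussian_bump_recovered_at_80hz():
    spec = _power_law_spectrum()
    bump = 0.02 * np.exp(-0.5 * ((spec.freqs - 80.0) / 5.0) ** 2)
    spec = Spectrum(spec.freqs, spec.power + bump, 60.0)
    adj = sw.adjust_one_over_f(spec)
    sel = adj.freqs_log >= 4
    peak = adj.freqs_log[sel][np.argmax(adj.adjusted_power[sel])]
    assert abs(peak - 80.0) <= 3.0


def test_notch_interpolation_bounded_by_flanks():
    """Zeroed 50+/-5-Hz bins are rebuilt between the flanking values."""
    spec = _power_law_spectrum()
    power = spec.power.copy()
    notch = np.abs(spec.freqs - 50.0) <= 5.0
    power[notch] = 0.0
    from swripple.spectral import _interpolate_notches
    fixed = _interpolate_notches(spec.freqs, power)
    f44 = power[np.argmin(np.abs(spec.freqs - 44.0))]
    f56 = power[np.argmin(np.abs(spec.freqs - 56.0))]
    inside = fixed[np.abs(spec.freqs - 50.0) <= 2.0]
    assert np.all(inside <= max(f44, f56) * 1.01)
    assert np.all(inside >= min(f44, f56) * 0.99)


def test_nonpositive_power_in_fit_range_raises():
    spec = _power_law_spectrum()
    power = spec.power.copy()
    power[np.argmin(np.abs(spec.freqs - 20.0))] = 0.0
    with pytest.raises(ValueError):
        sw.adjust_one_over_f(Spectrum(spec.freqs, power, 60.0))


def test_smoothing_nearly_mass_preserving():
    """Each smoothing pass changes the interior mean by under 1%."""
    from swripple.spectral import _smooth_shrinking
    rng = np.random.default_rng(3)
    x = 1.0 + 0.3 * rng.standard_normal(200)
    sm = _smooth_shrinking(x, 5)
    assert abs(sm[5:-5].mean() - x[5:-5].mean()) < 0.01 * abs(x[5:-5].mean())


def test_ripple_band_peak_present_iff_ripples_injected(nrem_run):
    """Adjusted spectra show a 70-85-Hz local peak only with ripples on."""
    cfg, truth, clean, trials = nrem_run
    adj = sw.adjust_one_over_f(
        sw.welch_psd(trials, clean.channels["HPC"], cfg.fs))
    band = (adj.freqs_log >= 60) & (adj.freqs_log <= 100)
    peak_f = adj.freqs_log[band][np.argmax(adj.adjusted_power[band])]
    assert abs(peak_f - cfg.ripple_freq_hz) <= 5.0

    quiet = sw.SynthConfig(duration_s=300.0, seed=101,
                           ripple_rate_per_min=(0.0, 0.0),
                           spindle_rate_per_min=0.0,
                           artifact_rate_per_min=0.0)
    channels, _ = sw.generate_recording(quiet)
    from swripple.preprocess import Recording, preprocess
    rec = Recording(channels=channels, fs=quiet.fs, stages=["N2"] * 15)
    c2, t2 = preprocess(rec)
    adj0 = sw.adjust_one_over_f(sw.welch_psd(t2, c2.channels["HPC"],
                                             quiet.fs))
    ripple_rows = (adj0.freqs_log >= 70) & (adj0.freqs_log <= 85)
    # without ripples the band residual is no larger than elsewhere
    rest = (adj0.freqs_log >= 20) & (adj0.freqs_log <= 60)
    assert adj0.adjusted_power[ripple_rows].max() <= \
        np.percentile(np.abs(adj0.adjusted_power[rest]), 99) * 3
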
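"""FWHM-parametrized Morlet decomposition and 60-s segmentation."""

import numpy as np
import pytest

import swripple as sw
from swripple.preprocess import Trial
from swripple.timefreq import TFRun, decompose, segment_60s


def _measured_spectral_fwhm(kernel, fs):
    nfft = 1 << 19
    mag = np.abs(np.fft.fft(kernel, nfft))
    freqs = np.fft.fftfreq(nfft, 1.0 / fs)
    above = freqs[mag >= mag.max() / 2]
    return above.max() - above.min()


def test_family_layout(family_1k):
    f = family_1k.center_freqs
    assert len(f) == 50
    assert f[0] == pytest.approx(0.5) and f[-1] == pytest.approx(200.0)
    assert np.allclose(np.diff(np.log(f)), np.diff(np.log(f))[0])
    h = family_1k.temporal_fwhm
    assert h[0] == pytest.approx(3.0) and h[-1] == pytest.approx(0.025)


@pytest.mark.parametrize("idx, expected", [(0, 0.3), (-1, 35.0)])
def test_spectral_fwhm_matches_printed_values(family_1k, idx, expected):
    """h=3 s gives ~0.3-Hz and h=0.025 s gives ~35-Hz spectral FWHM.

    The analytic width 4 ln2 / (pi h) must sit within 2% of the nominal
    value, and the FFT-measured width of the discrete kernel within 2%
    of the analytic one.
    """
    analytic = family_1k.spectral_fwhm[idx]
    assert analytic == pytest.approx(expected, rel=0.02)
    measured = _measured_spectral_fwhm(family_1k.kernels[idx], family_1k.fs)
    assert measured == pytest.approx(analytic, rel=0.02)


def test_envelope_half_maximum_at_half_h(family_1k):
    """The envelope's interpolated half-max crossing sits at t = h/2."""
    for idx in (0, 25, 49):
        k = family_1k.kernels[idx]
        h = family_1k.temporal_fwhm[idx]
        center = (len(k) - 1) // 2
        env = np.abs(k[center:])
        half = env[0] / 2
        i = int(np.argmax(env < half))
        frac = (env[i - 1] - half) / (env[i - 1] - env[i])
        t_cross = (i - 1 + frac) / family_1k.fs
        assert t_cross == pytest.approx(h / 2, abs=1.0 / family_1k.fs)


def test_kernels_unit_energy(family_1k):
    for k in family_1k.kernels:
        assert np.sum(np.abs(k) ** 2) == pytest.approx(1.0, rel=1e-12)


def test_build_requires_nyquist():
    with pytest.raises(ValueError):
        sw.build_wavelets(300.0)


def test_tuning_to_80hz(family_1k):
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    tf = decompose(np.sin(2 * np.pi * 80.0 * t), fs, family_1k)
    profile = np.abs(tf).mean(axis=1)
    best = family_1k.center_freqs[np.argmax(profile)]
    nearest = family_1k.center_freqs[
        np.argmin(np.abs(family_1k.center_freqs - 80.0))]
    assert best == nearest


def test_chirp_ridge_increases(family_1k):
    from scipy.signal import chirp
    fs = 1000.0
    t = np.arange(int(30 * fs)) / fs
    x = chirp(t, f0=5.0, f1=20.0, t1=30.0)
    tf = decompose(x, fs, family_1k)
    cols = tf.shape[1]
    interior = np.linspace(int(0.1 * cols), int(0.9 * cols), 8).astype(int)
    ridge = family_1k.center_freqs[np.argmax(np.abs(tf[:, interior]), axis=0)]
    assert np.all(np.diff(ridge) >= 0)
    assert ridge[-1] > ridge[0]


def test_output_length_and_timestamps(family_1k):
    fs = 1000.0
    for n in (3000, 3001, 3003):
        tf = decompose(np.random.default_rng(0).standard_normal(n), fs,
                       family_1k)
        assert tf.shape == (50, int(np.ceil(n / 4)))


def test_linearity(family_1k):
    rng = np.random.default_rng(4)
    x, y = rng.standard_normal((2, 5000))
    fs = 1000.0
    both = decompose(x + y, fs, family_1k)
    sep = decompose(x, fs, family_1k) + decompose(y, fs, family_1k)
    np.testing.assert_allclose(both, sep, atol=1e-9)


def test_envelope_flat_for_center_frequency_sinusoid(family_1k):
    """Unit sinusoid at an exact centre frequency: interior envelope has
    coefficient of variation under 5%."""
    fs = 1000.0
    f0 = family_1k.center_freqs[40]  # ~60 Hz
    t = np.arange(int(10 * fs)) / fs
    tf = decompose(np.sin(2 * np.pi * f0 * t), fs, family_1k)
    env = np.abs(tf[40])
    interior = env[len(env) // 4: -len(env) // 4]
    assert interior.std() / interior.mean() < 0.05


def _fake_run(n_cols, fs_eff=250.0, stages=None):
    vals = (np.arange(n_cols)[None, :] * np.ones((50, 1))).astype(complex)
    stages = stages if stages is not None else np.full(n_cols, "N2",
                                                       dtype=object)
    return TFRun(channel="c", freqs=np.geomspace(0.5, 200, 50),
                 fs_eff=fs_eff, values=vals,
                 col_sample=np.arange(n_cols) * 4,
                 col_stage=stages, col_trial=np.zeros(n_cols, int))


def test_segment_count_and_discard():
    """150 s -> 2 whole segments, remainder discarded; 59.9 s -> none."""
    segs = segment_60s(_fake_run(int(150 * 250)))
    assert len(segs) == 2
    assert all(s.values.shape[1] == 15000 for s in segs)
    with pytest.warns(UserWarning, match="no segments"):
        assert segment_60s(_fake_run(int(59.9 * 250))) == []


def test_segmentation_respects_trial_order():
    run = _fake_run(4 * 15000)
    segs = segment_60s(run)
    assert len(segs) == 4
    starts = [s.values[0, 0].real for s in segs]
    assert starts == sorted(starts)
    np.testing.assert_array_equal(segs[1].col_sample,
                                  run.col_sample[15000:30000])


def test_stage_restriction():
    stages = np.array(["N2"] * 15000 + ["N3"] * 20000, dtype=object)
    run = _fake_run(35000, stages=stages)
    assert len(segment_60s(run, "N2")) == 1
    assert len(segment_60s(run, "N3")) == 1
    assert len(segment_60s(run)) == 2


def test_column_of_sample_round_trip(tf_runs):
    run = tf_runs["HPC"]
    for col in (0, 1000, len(run.col_sample) - 1):
        assert run.column_of_sample(int(run.col_sample[col])) == col
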
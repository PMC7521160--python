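"""FWHM-parametrized complex Morlet time-frequency decomposition.

Wavelets are defined by their temporal resolution h (the full width at
half maximum of the Gaussian envelope, in seconds):

    w(t) = exp(i 2 pi f t) * exp(-4 ln2 t^2 / h^2)

with 50 logarithmically spaced centre frequencies f in [0.5, 200] Hz and
h log-spaced from 3 s (at 0.5 Hz) to 0.025 s (at 200 Hz), giving
spectral FWHMs of 4 ln2 / (pi h): ~0.3 Hz and ~35 Hz at the extremes.
Trials are reflection-padded by 5 s, convolved, trimmed, and downsampled
by 4.  Per-stage results are concatenated and cut into 60-s segments for
connectivity and PAC statistics; the column-to-sample bookkeeping kept
in :class:`TFRun` serves the ripple-locked analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft

from .preprocess import Trial

__all__ = [
    "WaveletFamily",
    "TFRun",
    "TFSegment",
    "build_wavelets",
    "decompose",
    "decompose_trials",
    "segment_60s",
]

N_FREQS = 50
F_RANGE_HZ = (0.5, 200.0)
H_RANGE_S = (3.0, 0.025)
PAD_S = 5.0
DOWNSAMPLE = 4
SEGMENT_S = 60.0
ENVELOPE_CUTOFF = 1e-4  # kernels truncated where envelope < cutoff * peak


@dataclass
class WaveletFamily:
    """Bank of unit-energy complex Morlet kernels."""

    fs: float
    center_freqs: np.ndarray      # Hz, ascending
    temporal_fwhm: np.ndarray     # h, seconds per frequency
    kernels: list[np.ndarray]     # complex, odd length, peak at centre
    _fft_cache: dict = field(default_factory=dict, repr=False)

    @property
    def spectral_fwhm(self) -> np.ndarray:
        """Frequency-domain FWHM, 4 ln2 / (pi h), in Hz."""
        return 4 * np.log(2) / (np.pi * self.temporal_fwhm)

    @property
    def max_kernel_len(self) -> int:
        return max(len(k) for k in self.kernels)


def build_wavelets(fs: float, n_freqs: int = N_FREQS,
                   f_range_hz: tuple[float, float] = F_RANGE_HZ,
                   h_range_s: tuple[float, float] = H_RANGE_S
                   ) -> WaveletFamily:
    """Construct the log-spaced FWHM-parametrized wavelet family."""
    if fs < 2 * f_range_hz[1]:
        raise ValueError("sampling rate below Nyquist for the top frequency")
    freqs = np.geomspace(*f_range_hz, n_freqs)
    hs = np.geomspace(*h_range_s, n_freqs)
    kernels = []
    for f, h in zip(freqs, hs):
        # envelope reaches cutoff at |t| = h * sqrt(-ln(cutoff) / (4 ln 2))
        t_max = h * np.sqrt(-np.log(ENVELOPE_CUTOFF) / (4 * np.log(2)))
        half = int(np.ceil(t_max * fs))
        t = np.arange(-half, half + 1) / fs
        k = np.exp(2j * np.pi * f * t) * np.exp(
            -4 * np.log(2) * t ** 2 / h ** 2)
        k /= np.sqrt(np.sum(np.abs(k) ** 2))  # unit energy
        kernels.append(k)
    return WaveletFamily(fs=fs, center_freqs=freqs, temporal_fwhm=hs,
                         kernels=kernels)


def decompose(series: np.ndarray, fs: float, family: WaveletFamily,
              pad_s: float = PAD_S, downsample: int = DOWNSAMPLE
              ) -> np.ndarray:
    """Convolve one trial with every kernel; trim padding; keep every 4th.

    The trial is extended by ``pad_s`` seconds of reflected signal on
    each side to limit edge artifacts.  Output shape is
    ``(n_freqs, ceil(len(series) / downsample))``, rows ordered by centre
    frequency; column k corresponds to input sample ``downsample * k``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    pad = int(round(pad_s * fs))
    xp = np.pad(x, pad, mode="reflect") if pad else x
    if family.max_kernel_len > len(xp):
        raise ValueError("trial too short for the longest wavelet")
    nfft = sp_fft.next_fast_len(len(xp) + family.max_kernel_len - 1)
    key = nfft
    if key not in family._fft_cache:
        family._fft_cache[key] = [
            sp_fft.fft(k, nfft) for k in family.kernels]
    kf = family._fft_cache[key]
    xf = sp_fft.fft(xp, nfft)
    out = np.empty((len(family.kernels), int(np.ceil(n / downsample))),
                   dtype=np.complex128)
    for i, (k, kfft) in enumerate(zip(family.kernels, kf)):
        full = sp_fft.ifft(xf * kfft)
        half = (len(k) - 1) // 2
        same = full[half:half + len(xp)]  # 'same'-mode alignment
        out[i] = same[pad:pad + n:downsample]
    return out


@dataclass
class TFSegment:
    """One 60-s complex time-frequency fragment of one channel/stage."""

    channel: str
    stage: str
    index: int
    values: np.ndarray  # (n_freqs, segment_len) complex
    col_sample: np.ndarray  # original recording sample of each column
    fs_eff: float


@dataclass
class TFRun:
    """Concatenated decomposition of all trials of one channel.

    Columns are in trial temporal order; ``col_sample`` maps each column
    back to its sample index in the original recording, ``col_stage``
    records the trial's sleep stage, and ``col_trial`` the trial index.
    """

    channel: str
    freqs: np.ndarray
    fs_eff: float
    values: np.ndarray      # (n_freqs, n_cols) complex
    col_sample: np.ndarray  # (n_cols,) int
    col_stage: np.ndarray   # (n_cols,) object
    col_trial: np.ndarray   # (n_cols,) int

    def power_zscore(self) -> np.ndarray:
        """Per-frequency z-score of squared magnitude over all columns."""
        p = np.abs(self.values) ** 2
        mu = p.mean(axis=1, keepdims=True)
        sd = p.std(axis=1, keepdims=True)
        return (p - mu) / sd

    def column_of_sample(self, sample: int) -> int:
        """Column whose source sample is nearest to ``sample``."""
        i = int(np.searchsorted(self.col_sample, sample))
        if i == 0:
            return 0
        if i >= len(self.col_sample):
            return len(self.col_sample) - 1
        before, after = self.col_sample[i - 1], self.col_sample[i]
        return i if after - sample < sample - before else i - 1


def decompose_trials(series: np.ndarray, fs: float, trials: Sequence[Trial],
                     family: WaveletFamily, channel: str = "",
                     pad_s: float = PAD_S, downsample: int = DOWNSAMPLE
                     ) -> TFRun:
    """Decompose every trial and concatenate in temporal order."""
    if not trials:
        raise ValueError("no trials to decompose")
    blocks, samples, stages, ids = [], [], [], []
    for j, tr in enumerate(sorted(trials, key=lambda t: t.start)):
        tf = decompose(series[tr.start:tr.end], fs, family,
                       pad_s=pad_s, downsample=downsample)
        blocks.append(tf)
        cols = tr.start + downsample * np.arange(tf.shape[1])
        samples.append(cols)
        stages.append(np.full(tf.shape[1], tr.stage, dtype=object))
        ids.append(np.full(tf.shape[1], j))
    return TFRun(channel=channel, freqs=family.center_freqs,
                 fs_eff=fs / downsample,
                 values=np.concatenate(blocks, axis=1),
                 col_sample=np.concatenate(samples),
                 col_stage=np.concatenate(stages),
                 col_trial=np.concatenate(ids))


def segment_60s(run: TFRun, stage: str | None = None,
                segment_s: float = SEGMENT_S) -> list[TFSegment]:
    """Cut a run's (optionally stage-restricted) columns into 60-s pieces.

    Trials of the requested stage are concatenated in temporal order and
    split into consecutive whole segments; the trailing incomplete
    remainder is discarded.  Fewer than one segment yields an empty list.
    """
    if stage is None:
        keep = np.ones(run.values.shape[1], dtype=bool)
        stage_label = "NREM"
    else:
        keep = run.col_stage == stage
        stage_label = stage
    vals = run.values[:, keep]
    cols = run.col_sample[keep]
    seg_len = int(round(segment_s * run.fs_eff))
    n_seg = vals.shape[1] // seg_len
    if n_seg == 0 and vals.shape[1] > 0:
        import warnings
        warnings.warn(f"under {segment_s:g} s of decomposed {stage_label} "
                      "data: no segments", stacklevel=2)
    return [
        TFSegment(channel=run.channel, stage=stage_label, index=i,
                  values=vals[:, i * seg_len:(i + 1) * seg_len],
                  col_sample=cols[i * seg_len:(i + 1) * seg_len],
                  fs_eff=run.fs_eff)
        for i in range(n_seg)
    ]
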
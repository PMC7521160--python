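"""Welch power spectra and 1/f adjustment.

Per-trial Welch spectra (3-s Hann windows, 80% overlap, zero-padded to
the next power of two: 0.244-Hz bins at 1 kHz) are averaged with trial
durations as weights.  The aperiodic 1/f component is then removed: the
notch-filtered regions are bridged by modified-Akima interpolation, a
power law a*f^b is fitted by log-log least squares over 4-175 Hz and
subtracted, and the residual is resampled to a log-spaced grid and
smoothed, exposing narrowband (ripple, spindle) peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.interpolate import Akima1DInterpolator

from .preprocess import Trial

__all__ = ["Spectrum", "AdjustedSpectrum", "welch_psd", "adjust_one_over_f"]

WINDOW_S = 3.0
OVERLAP_FRAC = 0.8
FIT_RANGE_HZ = (4.0, 175.0)
NOTCH_CENTERS_HZ = (50.0, 100.0, 150.0, 200.0)
NOTCH_HALF_WIDTH_HZ = 5.0
LOG_GRID_HZ = (0.5, 200.0)
N_LOG_BINS = 200
SMOOTH_WINDOW = 5
SMOOTH_PASSES = 3


@dataclass
class Spectrum:
    """Duration-weighted mean power spectral density (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    total_weight: float  # seconds of data behind the average

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class AdjustedSpectrum:
    """Power-law-adjusted residual spectrum on a log-spaced grid."""

    freqs_log: np.ndarray
    adjusted_power: np.ndarray  # residual; may be negative
    fit_a: float
    fit_b: float


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def welch_psd(trials: Sequence[Trial], series: np.ndarray, fs: float,
              window_s: float = WINDOW_S,
              overlap_frac: float = OVERLAP_FRAC) -> Spectrum:
    """Per-trial Welch PSD averaged with trial durations as weights.

    Windows never cross a trial boundary; each window is zero-padded to
    the next power of two (4096 samples at fs=1000 for 3-s windows, i.e.
    0.2441-Hz bin spacing).
    """
    if not trials:
        raise ValueError("no trials to average")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap_frac * nperseg))
    nfft = _next_pow2(nperseg)
    acc = None
    wsum = 0.0
    freqs = None
    for tr in trials:
        seg = np.asarray(series[tr.start:tr.end], dtype=float)
        if len(seg) < nperseg:
            raise ValueError("every trial must be at least one window long")
        freqs, pxx = signal.welch(seg, fs=fs, window="hann", nperseg=nperseg,
                                  noverlap=noverlap, nfft=nfft,
                                  detrend="constant")
        w = len(seg) / fs
        acc = w * pxx if acc is None else acc + w * pxx
        wsum += w
    return Spectrum(freqs=freqs, power=acc / wsum, total_weight=wsum)


def _interpolate_notches(freqs: np.ndarray, power: np.ndarray) -> np.ndarray:
    """Replace notch-filtered bins by modified-Akima interpolation."""
    notched = np.zeros_like(freqs, dtype=bool)
    for f0 in NOTCH_CENTERS_HZ:
        notched |= np.abs(freqs - f0) <= NOTCH_HALF_WIDTH_HZ
    out = power.copy()
    if notched.any():
        interp = Akima1DInterpolator(freqs[~notched], power[~notched],
                                     method="makima")
        out[notched] = interp(freqs[notched])
    return out


def _smooth_shrinking(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at edges."""
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    cnt = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / cnt


def adjust_one_over_f(spectrum: Spectrum,
                      fit_range_hz: tuple[float, float] = FIT_RANGE_HZ
                      ) -> AdjustedSpectrum:
    """Remove the aperiodic a*f^b component from a spectrum.

    Steps: notch-region interpolation; ordinary least squares of
    log10(power) on log10(freq) restricted to ``fit_range_hz``; residual
    observed - a*f^b; resampling onto 200 log-spaced bins 0.5-200 Hz;
    three passes of a centred 5-bin moving average.
    """
    freqs, power = spectrum.freqs, spectrum.power
    if freqs[0] > LOG_GRID_HZ[0] or freqs[-1] < LOG_GRID_HZ[1]:
        raise ValueError("spectrum must cover 0.5-200 Hz")
    power = _interpolate_notches(freqs, power)
    sel = (freqs >= fit_range_hz[0]) & (freqs <= fit_range_hz[1])
    if np.any(power[sel] <= 0):
        raise ValueError("nonpositive power inside the fit range")
    lx = np.log10(freqs[sel])
    ly = np.log10(power[sel])
    slope, intercept = np.polyfit(lx, ly, 1)
    a, b = 10.0 ** intercept, slope
    residual = power - a * np.where(freqs > 0, freqs, np.nan) ** b
    grid = np.geomspace(*LOG_GRID_HZ, N_LOG_BINS)
    adj = np.interp(np.log10(grid), np.log10(freqs[freqs > 0]),
                    residual[freqs > 0])
    for _ in range(SMOOTH_PASSES):
        adj = _smooth_shrinking(adj, SMOOTH_WINDOW)
    return AdjustedSpectrum(freqs_log=grid, adjusted_power=adj,
                            fit_a=float(a), fit_b=float(b))
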
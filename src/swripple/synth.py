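"""Synthetic two-channel NREM-sleep LFP with known ground truth.

Generates hippocampus-like ("HPC") and amygdala-like ("AMY") bipolar
channels containing a 1/f background, ~80-Hz ripple bursts riding on
2-8-Hz sharp-wave (SPW) transients, waxing-waning ~13-Hz spindles,
controllable cross-channel ripple co-occurrence, delta-phase modulation
of ripple amplitude (PAC), and injected high-amplitude artifacts.

Every injected event is recorded in a :class:`GroundTruth` object so that
detection, co-occurrence, coupling and event-locked analyses can be
validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_background",
    "inject_events",
    "generate_recording",
]

#: channel labels, in order (channel 0 spawns co-occurring events on channel 1)
CHANNELS = ("HPC", "AMY")

#: minimum separation of same-channel ripples (s); the detector assumes
#: separable events
RIPPLE_MIN_SEP_S = 0.2

#: events are kept away from the record edges by this margin (s)
EDGE_MARGIN_S = 1.5


@dataclass
class SynthConfig:
    """Parameters of the synthetic NREM recording.

    Per-channel parameters are ``(HPC, AMY)`` pairs.  Defaults emulate the
    reported NREM phenomenology of human hippocampus and amygdala: ripple
    densities of ~5.5 and ~2.6 per minute, ~50-ms ~80-Hz ripples with
    amplitudes of ~12 and ~6 uV riding on 2-8-Hz sharp waves, ~13-Hz
    spindles, and a modest fraction of co-occurring cross-channel ripples.
    """

    duration_s: float = 300.0
    fs: float = 1000.0
    # aperiodic background a*f^b (power density in uV^2/Hz at 1 Hz; b < 0);
    # a = 500 puts the ripple-band (70-110 Hz) SD near 1.6 uV, so default
    # ripple amplitudes sit at a realistic ~4-7x band SD
    background_a: float = 500.0
    background_b: float = -2.0
    # ripples; duration is the envelope FWHM (the quantity a dual-threshold
    # detector reports); amplitude is the peak of the 70-110-Hz band-passed
    # waveform (the quantity the property tables report)
    ripple_rate_per_min: tuple[float, float] = (5.5, 2.6)
    ripple_freq_hz: float = 80.0
    ripple_dur_ms: float = 50.0
    ripple_dur_sd_ms: float = 8.0
    ripple_amp_uv: tuple[float, float] = (12.0, 6.0)
    # sharp-wave transient accompanying each ripple
    spw_freq_hz: tuple[float, float] = (2.0, 8.0)
    spw_amp_uv: float = 50.0
    spw_ripple_phase: float = 0.0
    spw_polarity: int = 1  # bipolar referencing leaves polarity undetermined
    # spindles
    spindle_rate_per_min: float = 2.0
    spindle_freq_hz: float = 13.0
    spindle_dur_s: float = 1.0
    spindle_amp_uv: float = 20.0
    # cross-channel coupling
    cooccurrence_prob: float = 0.2
    cooccurrence_lag_sd_ms: float = 20.0
    # delta-phase -> ripple-amplitude coupling; the modulator is a
    # narrowband stochastic oscillation (its phase drifts, as real delta
    # does, so >=1-s time shifts decorrelate it from the events)
    pac_depth: float = 0.0
    pac_delta_freq_hz: float = 4.0
    pac_delta_bw_hz: float = 2.0
    pac_delta_amp_uv: float = 25.0
    # artifacts
    artifact_rate_per_min: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 2 * self.ripple_freq_hz:
            raise ValueError("fs must exceed twice the ripple frequency")
        rates = (*self.ripple_rate_per_min, self.spindle_rate_per_min,
                 self.artifact_rate_per_min)
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be non-negative")
        for name in ("pac_depth", "cooccurrence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.duration_s <= 2 * EDGE_MARGIN_S and any(
                r > 0 for r in rates):
            raise ValueError("recording too short to place events")


@dataclass
class ChannelTruth:
    """Injected events of one channel (times in seconds)."""

    ripple_times: list[float] = field(default_factory=list)
    ripple_durations_ms: list[float] = field(default_factory=list)
    ripple_amplitudes_uv: list[float] = field(default_factory=list)
    spw_times: list[float] = field(default_factory=list)
    spw_freqs_hz: list[float] = field(default_factory=list)
    spindle_times: list[float] = field(default_factory=list)
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Everything that was injected, for validation of downstream stages."""

    channels: dict[str, ChannelTruth]
    #: (index into HPC ripples, index into AMY ripples) for spawned pairs
    pairs: list[tuple[int, int]] = field(default_factory=list)
    #: lag (s) of each spawned AMY ripple relative to its HPC parent
    pair_lags_s: list[float] = field(default_factory=list)
    delta_freq_hz: float = 0.0
    #: analytic phase of the delta modulator, one value per sample
    delta_phase_series: np.ndarray | None = None
    fs: float = 0.0

    def delta_phase(self, t: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous phase of the delta modulator at time ``t`` (s)."""
        if self.delta_phase_series is None:
            raise ValueError("no delta modulator was injected")
        idx = np.clip((np.asarray(t) * self.fs).astype(int), 0,
                      len(self.delta_phase_series) - 1)
        return self.delta_phase_series[idx]

    def to_dict(self) -> dict:
        return {
            "channels": {k: asdict(v) for k, v in self.channels.items()},
            "pairs": [list(p) for p in self.pairs],
            "pair_lags_s": list(self.pair_lags_s),
            "delta_freq_hz": self.delta_freq_hz,
        }


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def generate_background(duration_s: float, fs: float, a: float, b: float,
                        seed: int | np.random.Generator) -> np.ndarray:
    """Zero-mean noise whose power spectral density follows ``a * f**b``.

    Gaussian white noise is shaped in the frequency domain with amplitude
    proportional to ``f**(b/2)``, which gives the exact expected log-log
    slope ``b`` and density scale ``a`` (uV^2/Hz at 1 Hz).
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    # unit-variance white noise has one-sided density 2/fs
    gain[1:] = np.sqrt(a * freqs[1:] ** b * fs / 2.0)
    x = np.fft.irfft(spec * gain, n)
    return x - x.mean()


# ---------------------------------------------------------------------------
# event waveforms
# ---------------------------------------------------------------------------

def _ripple_waveform(fs: float, freq: float, fwhm_s: float,
                     amp: float) -> np.ndarray:
    """Raised-cosine (Hann) windowed sinusoid burst.

    ``fwhm_s`` is the envelope full width at half maximum (the Hann
    support spans twice that).  ``amp`` is calibrated so that the peak of
    the 70-110-Hz band-passed waveform equals ``amp`` — matching how
    ripple amplitude is measured downstream.
    """
    n = max(int(round(2 * fwhm_s * fs)), 3)
    t = (np.arange(n) - (n - 1) / 2) / fs
    w = np.hanning(n) * np.cos(2 * np.pi * freq * t)
    return amp / _band_attenuation(fs, freq, n) * w


_ATTENUATION_CACHE: dict[tuple[float, float, int], float] = {}


def _band_attenuation(fs: float, freq: float, n: int) -> float:
    """Peak of the ripple band-pass response to a unit Hann burst."""
    key = (fs, freq, n)
    if key not in _ATTENUATION_CACHE:
        from .ripples import ripple_bandpass
        t = (np.arange(n) - (n - 1) / 2) / fs
        w = np.hanning(n) * np.cos(2 * np.pi * freq * t)
        padded = np.zeros(n + int(4 * fs))
        padded[len(padded) // 2 - n // 2:
               len(padded) // 2 - n // 2 + n] = w
        _ATTENUATION_CACHE[key] = float(np.max(np.abs(
            ripple_bandpass(padded, fs))))
    return _ATTENUATION_CACHE[key]


def _spw_waveform(fs: float, freq: float, amp: float, phase: float,
                  polarity: int) -> np.ndarray:
    """One Gaussian-windowed cycle of a 2-8-Hz sharp-wave transient.

    The analytic phase at the waveform centre equals ``phase``.
    """
    half = 1.0 / freq  # one full cycle of support
    n = 2 * int(round(half * fs)) + 1
    t = (np.arange(n) - (n - 1) / 2) / fs
    fwhm = 1.0 / freq
    env = np.exp(-4 * np.log(2) * t ** 2 / fwhm ** 2)
    return polarity * amp * env * np.cos(2 * np.pi * freq * t + phase)


def _spindle_waveform(fs: float, freq: float, dur_s: float,
                      amp: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 3)
    t = (np.arange(n) - (n - 1) / 2) / fs
    return amp * np.hanning(n) * np.sin(2 * np.pi * freq * t)


def _add_centered(x: np.ndarray, waveform: np.ndarray, center: int) -> None:
    """Add ``waveform`` to ``x`` in place, centred on sample ``center``."""
    half = (len(waveform) - 1) // 2
    lo, hi = center - half, center - half + len(waveform)
    wlo = max(0, -lo)
    whi = len(waveform) - max(0, hi - len(x))
    lo, hi = max(lo, 0), min(hi, len(x))
    x[lo:hi] += waveform[wlo:whi]


def _narrowband_oscillation(rng: np.random.Generator, n: int, fs: float,
                            f0: float, bw_hz: float, amp: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Narrowband Gaussian process at ``f0`` with spectral FWHM ``bw_hz``.

    Returns (waveform scaled so the mean Hilbert envelope equals ``amp``,
    analytic phase per sample).  The phase decorrelates over ~1/bw_hz
    seconds, as in physiological slow oscillations.
    """
    from scipy.signal import hilbert

    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.exp(-4 * np.log(2) * (freqs - f0) ** 2 / bw_hz ** 2)
    x = np.fft.irfft(spec * gain, n)
    analytic = hilbert(x)
    env = np.abs(analytic)
    x *= amp / env.mean()
    return x, np.angle(analytic)


def _poisson_times(rng: np.random.Generator, rate_per_min: float,
                   duration_s: float, min_sep_s: float) -> np.ndarray:
    """Sorted Poisson event times thinned to a minimum separation."""
    if rate_per_min <= 0:
        return np.empty(0)
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    lo, hi = EDGE_MARGIN_S, duration_s - EDGE_MARGIN_S
    times = np.sort(rng.uniform(lo, hi, n))
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep_s:
            kept.append(t)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# injection
# ---------------------------------------------------------------------------

def inject_events(background: np.ndarray | Sequence[np.ndarray],
                  config: SynthConfig,
                  seed: int | np.random.Generator | None = None,
                  ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Add ripples, SPWs, spindles, PAC and artifacts to two backgrounds.

    ``background`` is a (2, n) array or a pair of equal-length series.
    Returns the channel dict (labels :data:`CHANNELS`) and the
    :class:`GroundTruth` bookkeeping of everything that was injected.
    """
    config.validate()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    if bg.shape[0] != 2:
        raise ValueError("background must provide two channels")
    n = bg.shape[1]
    fs = config.fs
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    # independent sub-streams per concern keep channels reproducible
    streams = rng.spawn(5)
    ev_rng, co_rng, spin_rng, art_rng, pac_rng = streams

    out = {ch: bg[i].copy() for i, ch in enumerate(CHANNELS)}
    truth = GroundTruth(channels={ch: ChannelTruth() for ch in CHANNELS})

    # delta modulator (continuous narrowband process, shared across
    # channels; its analytic phase is the PAC ground truth)
    truth.fs = fs
    if config.pac_depth > 0:
        truth.delta_freq_hz = config.pac_delta_freq_hz
        delta, phase = _narrowband_oscillation(
            pac_rng, n, fs, config.pac_delta_freq_hz,
            config.pac_delta_bw_hz, config.pac_delta_amp_uv)
        truth.delta_phase_series = phase
        for ch in CHANNELS:
            out[ch] += delta

    # ripple times: channel 0 independent; channel 1 = independent + spawned
    sep = RIPPLE_MIN_SEP_S
    if config.cooccurrence_prob > 0:
        sep += 6 * config.cooccurrence_lag_sd_ms / 1000.0
    times0 = _poisson_times(ev_rng, config.ripple_rate_per_min[0],
                            config.duration_s, sep)
    times1 = list(_poisson_times(ev_rng, config.ripple_rate_per_min[1],
                                 config.duration_s, RIPPLE_MIN_SEP_S))
    spawned: list[tuple[int, float, float]] = []  # (parent idx, time, lag)
    for i, t0 in enumerate(times0):
        if co_rng.uniform() < config.cooccurrence_prob:
            lag = co_rng.normal(0.0, config.cooccurrence_lag_sd_ms / 1000.0)
            t1 = t0 + lag
            if EDGE_MARGIN_S < t1 < config.duration_s - EDGE_MARGIN_S:
                spawned.append((i, t1, lag))

    per_channel_times = {CHANNELS[0]: list(times0), CHANNELS[1]: times1}

    def _place_ripples(ch: str, times: Sequence[float], amp0: float) -> None:
        ct = truth.channels[ch]
        for t0 in times:
            dur = float(np.clip(round(
                ev_rng.normal(config.ripple_dur_ms, config.ripple_dur_sd_ms)),
                38.0, 90.0)) / 1000.0  # ms precision keeps waveforms cached
            amp = amp0
            if config.pac_depth > 0:
                amp = amp0 * (1.0 + config.pac_depth
                              * np.cos(truth.delta_phase(t0)))
            center = int(round(t0 * fs))
            _add_centered(out[ch],
                          _ripple_waveform(fs, config.ripple_freq_hz, dur,
                                           amp), center)
            fspw = float(ev_rng.uniform(*config.spw_freq_hz))
            _add_centered(out[ch],
                          _spw_waveform(fs, fspw, config.spw_amp_uv,
                                        config.spw_ripple_phase,
                                        config.spw_polarity), center)
            ct.ripple_times.append(float(t0))
            ct.ripple_durations_ms.append(dur * 1000.0)
            ct.ripple_amplitudes_uv.append(float(amp))
            ct.spw_times.append(float(t0))
            ct.spw_freqs_hz.append(fspw)

    _place_ripples(CHANNELS[0], per_channel_times[CHANNELS[0]],
                   config.ripple_amp_uv[0])
    _place_ripples(CHANNELS[1], per_channel_times[CHANNELS[1]],
                   config.ripple_amp_uv[1])
    # spawned co-occurring events on channel 1, paired to their parent
    ct1 = truth.channels[CHANNELS[1]]
    for parent_idx, t1, lag in spawned:
        idx1 = len(ct1.ripple_times)
        _place_ripples(CHANNELS[1], [t1], config.ripple_amp_uv[1])
        truth.pairs.append((parent_idx, idx1))
        truth.pair_lags_s.append(float(lag))

    # spindles (independent per channel)
    for ch in CHANNELS:
        times = _poisson_times(spin_rng, config.spindle_rate_per_min,
                               config.duration_s, config.spindle_dur_s)
        for t0 in times:
            _add_centered(out[ch],
                          _spindle_waveform(fs, config.spindle_freq_hz,
                                            config.spindle_dur_s,
                                            config.spindle_amp_uv),
                          int(round(t0 * fs)))
            truth.channels[ch].spindle_times.append(float(t0))

    # artifacts: alternating high-amplitude spikes and boxcar steps
    for ch in CHANNELS:
        times = _poisson_times(art_rng, config.artifact_rate_per_min,
                               config.duration_s, 2.0)
        for k, t0 in enumerate(times):
            c = int(round(t0 * fs))
            if k % 2 == 0:  # sharp triangular spike, ~5 ms
                w = 2000.0 * np.array([0.2, 0.6, 1.0, 0.6, 0.2])
                _add_centered(out[ch], w, c)
                span = (t0 - 3 / fs, t0 + 3 / fs)
            else:  # 200-ms step with sharp edges
                w = 500.0 * np.ones(int(0.2 * fs))
                _add_centered(out[ch], w, c)
                span = (t0 - 0.1, t0 + 0.1)
            truth.channels[ch].artifact_intervals.append(
                (float(span[0]), float(span[1])))
    return out, truth


def generate_recording(config: SynthConfig
                       ) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Full synthesis: shaped background per channel plus injected events."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg_rngs = rng.spawn(2)
    bg = np.stack([
        generate_background(config.duration_s, config.fs, config.background_a,
                            config.background_b, r) for r in bg_rngs])
    return inject_events(bg, config, rng)
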
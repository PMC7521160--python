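"""Ripple-locked ERP, ERP spectra, time-frequency power, and ITPC.

All event-locked analyses use a 1.5-s window centred on the ripple
envelope maximum and the 1000 surrogate event sets as their null.  The
ERP averages mean-centred snippets; its 95% confidence band is the
pointwise 2.5th-97.5th percentile across surrogate ERPs.  ERP spectra
(Welch, 1.25-s windows, 95% overlap, 0.488-Hz bins) are z-scored per
bin against surrogate ERP spectra.  TF power (z-scored per frequency
over all NREM data first) and ITPC maps are averaged over event-centred
windows and z-scored against the 1000 mean surrogate responses; cluster
outlines are drawn at up to 5 integer z levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .ripples import RippleEvent, SurrogateEventSets
from .stats import Cluster, choose_outline_levels, find_clusters, \
    surrogate_zscore
from .timefreq import TFRun

__all__ = [
    "LockedMaps",
    "locked_erp",
    "erp_spectrum",
    "locked_tf_power",
    "locked_itpc",
    "locked_analyses",
]

HALF_WINDOW_S = 0.75
ERP_WELCH_WINDOW_S = 1.25
ERP_WELCH_OVERLAP = 0.95
#: TF columns on each side of the peak column; 2*188+1 = 377 columns at
#: 250 Hz, i.e. 50 x 377 = 18 850 time-frequency bins per locked map
TF_HALF_COLS = 188
MIN_EVENTS = 10


@dataclass
class LockedMaps:
    """Bundle of event-locked results for one (events, signal) pairing."""

    erp_t: np.ndarray
    erp: np.ndarray
    erp_ci: np.ndarray            # (2, n_time) lower/upper 95% band
    erp_freqs: np.ndarray
    erp_spectrum_raw: np.ndarray
    erp_spectrum_z: np.ndarray
    tf_freqs: np.ndarray
    tf_t: np.ndarray
    power_z: np.ndarray           # (n_freqs, 377)
    itpc_z: np.ndarray
    power_clusters: list[Cluster]
    itpc_clusters: list[Cluster]
    power_levels: list[int]
    itpc_levels: list[int]
    n_events: int
    low_event_warning: bool = False


def _peaks_of(events) -> np.ndarray:
    if len(events) and isinstance(events[0], RippleEvent):
        return np.asarray([ev.peak_sample for ev in events], dtype=int)
    return np.asarray(events, dtype=int)


def _snippets(series: np.ndarray, peaks: np.ndarray, half_n: int
              ) -> np.ndarray:
    """(n_events, 2*half_n+1) windows centred on each peak sample."""
    idx = peaks[:, None] + np.arange(-half_n, half_n + 1)[None, :]
    if idx.min() < 0 or idx.max() >= len(series):
        raise ValueError("event window outside the recording")
    return series[idx]


def _mean_centered_erp(series: np.ndarray, peaks: np.ndarray,
                       half_n: int) -> np.ndarray:
    snips = _snippets(series, peaks, half_n)
    snips = snips - snips.mean(axis=1, keepdims=True)
    return snips.mean(axis=0)


def _surrogate_erps(series: np.ndarray, surrogate_sets: SurrogateEventSets,
                    half_n: int) -> np.ndarray:
    out = np.empty((surrogate_sets.n_sets, 2 * half_n + 1))
    for i in range(surrogate_sets.n_sets):
        out[i] = _mean_centered_erp(
            series, surrogate_sets.peaks[i].astype(int), half_n)
    return out


def locked_erp(series: np.ndarray, events: list[RippleEvent] | np.ndarray,
               surrogate_sets: SurrogateEventSets, fs: float,
               half_window_s: float = HALF_WINDOW_S
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Ripple-locked ERP with surrogate-based 95% confidence band.

    Each snippet is mean-centred before averaging; the same computation
    on every surrogate set yields the pointwise 2.5-97.5 percentile
    band.  Returns (t_axis_s, erp, ci[2, n], low_event_warning).
    """
    peaks = _peaks_of(events)
    half_n = int(round(half_window_s * fs))
    erp = _mean_centered_erp(series, peaks, half_n)
    surr_erps = _surrogate_erps(series, surrogate_sets, half_n)
    ci = np.percentile(surr_erps, [2.5, 97.5], axis=0)
    t = np.arange(-half_n, half_n + 1) / fs
    return t, erp, ci, len(peaks) < MIN_EVENTS


def erp_spectrum(erp: np.ndarray, surrogate_erps: np.ndarray, fs: float,
                 window_s: float = ERP_WELCH_WINDOW_S,
                 overlap: float = ERP_WELCH_OVERLAP
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch spectrum of the ERP, raw and z-scored against surrogates.

    1.25-s Hann windows with 95% overlap, zero-padded to the next power
    of two (2048 at 1 kHz: 0.488-Hz bins).  Returns (freqs, raw, z).
    """
    nperseg = int(round(window_s * fs))
    noverlap = int(overlap * nperseg)
    nfft = 1 << (nperseg - 1).bit_length()

    def spec(x: np.ndarray) -> np.ndarray:
        return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                            noverlap=noverlap, nfft=nfft,
                            detrend="constant")[1]

    freqs = signal.welch(erp, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=noverlap, nfft=nfft)[0]
    raw = spec(erp)
    surr = np.stack([spec(s) for s in surrogate_erps])
    z = surrogate_zscore(raw, surr, axis=0)
    return freqs, raw, z


def _event_columns(run: TFRun, peaks: np.ndarray,
                   half_cols: int) -> np.ndarray:
    """(n_events, 2*half_cols+1) TF column indices per event window."""
    centers = np.array([run.column_of_sample(int(p)) for p in peaks])
    cols = centers[:, None] + np.arange(-half_cols, half_cols + 1)[None, :]
    if cols.min() < 0 or cols.max() >= run.values.shape[1]:
        raise ValueError("event TF window not covered by decomposed data")
    return cols


def _locked_map(data: np.ndarray, run: TFRun, peaks: np.ndarray,
                surrogate_sets: SurrogateEventSets, half_cols: int,
                itpc: bool) -> tuple[np.ndarray, np.ndarray]:
    """Mean event-locked map and its surrogate z-score.

    ``data`` is the per-frequency z-scored power (real) or the unit
    phasors (complex, for ITPC).
    """
    data = data.astype(np.complex64 if itpc else np.float32)

    def mean_map(pk: np.ndarray) -> np.ndarray:
        cols = _event_columns(run, pk, half_cols)
        stacked = data[:, cols]  # (n_freqs, n_events, n_cols)
        m = stacked.mean(axis=1)
        return np.abs(m) if itpc else m

    observed = mean_map(peaks)
    surr = np.empty((surrogate_sets.n_sets, *observed.shape),
                    dtype=np.float32)
    for i in range(surrogate_sets.n_sets):
        surr[i] = mean_map(surrogate_sets.peaks[i])
    z = surrogate_zscore(observed, surr.astype(float), axis=0)
    return observed, z


def locked_tf_power(run: TFRun, events: list[RippleEvent] | np.ndarray,
                    surrogate_sets: SurrogateEventSets,
                    half_cols: int = TF_HALF_COLS
                    ) -> tuple[np.ndarray, np.ndarray, list[int],
                               list[Cluster]]:
    """Ripple-locked TF power z map with multi-level cluster outlines.

    Power is z-scored per frequency over all NREM columns before the
    event averaging; the averaged response is then z-scored against the
    1000 mean surrogate responses.  Returns (t_axis_s, z map, outline
    levels, clusters at the lowest level).
    """
    peaks = _peaks_of(events)
    data = run.power_zscore()
    _, z = _locked_map(data, run, peaks, surrogate_sets, half_cols,
                       itpc=False)
    levels = choose_outline_levels(z)
    clusters = find_clusters(z, levels[0]) if levels else []
    t = np.arange(-half_cols, half_cols + 1) / run.fs_eff
    return t, z, levels, clusters


def locked_itpc(run: TFRun, events: list[RippleEvent] | np.ndarray,
                surrogate_sets: SurrogateEventSets,
                half_cols: int = TF_HALF_COLS
                ) -> tuple[np.ndarray, np.ndarray, list[int],
                           list[Cluster]]:
    """Ripple-locked intertrial phase clustering z map and clusters.

    ITPC(f, t) is the magnitude of the across-event mean unit phasor;
    the surrogate normalization mirrors the power analysis.
    """
    peaks = _peaks_of(events)
    mag = np.abs(run.values)
    mag[mag == 0] = 1.0
    phasors = run.values / mag
    _, z = _locked_map(phasors, run, peaks, surrogate_sets, half_cols,
                       itpc=True)
    levels = choose_outline_levels(z)
    clusters = find_clusters(z, levels[0]) if levels else []
    t = np.arange(-half_cols, half_cols + 1) / run.fs_eff
    return t, z, levels, clusters


def locked_analyses(series: np.ndarray, run: TFRun,
                    events: list[RippleEvent],
                    surrogate_sets: SurrogateEventSets, fs: float
                    ) -> LockedMaps:
    """All four event-locked analyses with one shared surrogate null.

    ``series`` and ``run`` may belong to the events' own channel
    (same-site) or to the other channel (cross-site); the code path is
    identical.
    """
    peaks = np.asarray([ev.peak_sample for ev in events], dtype=int)
    half_n = int(round(HALF_WINDOW_S * fs))
    erp = _mean_centered_erp(series, peaks, half_n)
    surr_erps = _surrogate_erps(series, surrogate_sets, half_n)
    ci = np.percentile(surr_erps, [2.5, 97.5], axis=0)
    t_erp = np.arange(-half_n, half_n + 1) / fs
    low = len(peaks) < MIN_EVENTS
    freqs, raw, zspec = erp_spectrum(erp, surr_erps, fs)
    t_tf, pz, plevels, pclusters = locked_tf_power(run, events,
                                                   surrogate_sets)
    _, iz, ilevels, iclusters = locked_itpc(run, events, surrogate_sets)
    return LockedMaps(
        erp_t=t_erp, erp=erp, erp_ci=ci, erp_freqs=freqs,
        erp_spectrum_raw=raw, erp_spectrum_z=zspec,
        tf_freqs=run.freqs, tf_t=t_tf, power_z=pz, itpc_z=iz,
        power_clusters=pclusters, itpc_clusters=iclusters,
        power_levels=plevels, itpc_levels=ilevels,
        n_events=len(events), low_event_warning=low)
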
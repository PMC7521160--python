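"""Cross-channel ripple co-occurrence rates and timing differences.

A ripple of channel A co-occurs with channel B when its envelope peak
lies within a centred interval (1.5 s, 500 ms, or 100 ms, i.e. +/- half
the window, closed) of any B peak.  Significance comes from the 1000
surrogate event sets of the other channel; precise (100-ms window)
co-occurrences yield signed peak-timing differences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .ripples import RippleEvent, SurrogateEventSets
from .stats import empirical_p

__all__ = [
    "cooccurrence_rate",
    "cooccurrence_significance",
    "timing_differences",
    "cooccurrence_table",
]

WINDOWS_MS = (1500.0, 500.0, 100.0)


def _peaks(events: list[RippleEvent] | np.ndarray) -> np.ndarray:
    if isinstance(events, np.ndarray):
        return np.sort(events.astype(float))
    return np.sort(np.array([ev.peak_sample for ev in events], dtype=float))


def _nearest_distance(a: np.ndarray, b_sorted: np.ndarray) -> np.ndarray:
    """Distance from each element of ``a`` to its nearest element of b."""
    pos = np.searchsorted(b_sorted, a)
    left = np.where(pos > 0, np.abs(a - b_sorted[np.maximum(pos - 1, 0)]),
                    np.inf)
    right = np.where(pos < len(b_sorted),
                     np.abs(a - b_sorted[np.minimum(pos, len(b_sorted) - 1)]),
                     np.inf)
    return np.minimum(left, right)


def cooccurrence_rate(events_a: list[RippleEvent] | np.ndarray,
                      events_b: list[RippleEvent] | np.ndarray,
                      window_ms: float, fs: float) -> float:
    """Percent of A ripples whose peak falls within +/- window/2 of any
    B peak (closed interval)."""
    pa = _peaks(events_a)
    pb = _peaks(events_b)
    if pa.size == 0:
        raise ValueError("events_a is empty: rate undefined")
    if pb.size == 0:
        return 0.0
    half = window_ms / 2000.0 * fs
    d = _nearest_distance(pa, pb)
    return 100.0 * float(np.count_nonzero(d <= half)) / pa.size


def cooccurrence_significance(events_a: list[RippleEvent] | np.ndarray,
                              surrogate_sets_b: SurrogateEventSets,
                              window_ms: float, fs: float,
                              observed_rate: float | None = None,
                              events_b: list[RippleEvent] | np.ndarray
                              | None = None
                              ) -> tuple[float, np.ndarray]:
    """Empirical p of the observed rate against 1000 surrogate rates.

    Surrogate rates pair channel A's true ripples with each surrogate
    set of channel B.  Returns (p, surrogate rates); ties count toward p.
    """
    if observed_rate is None:
        if events_b is None:
            raise ValueError("provide observed_rate or events_b")
        observed_rate = cooccurrence_rate(events_a, events_b, window_ms, fs)
    pa = _peaks(events_a)
    half = window_ms / 2000.0 * fs
    rates = np.empty(surrogate_sets_b.n_sets)
    for i in range(surrogate_sets_b.n_sets):
        pb = np.sort(surrogate_sets_b.peaks[i].astype(float))
        d = _nearest_distance(pa, pb)
        rates[i] = 100.0 * np.count_nonzero(d <= half) / pa.size
    return empirical_p(observed_rate, rates), rates


def timing_differences(events_a: list[RippleEvent] | np.ndarray,
                       events_b: list[RippleEvent] | np.ndarray,
                       fs: float, window_ms: float = 100.0
                       ) -> tuple[np.ndarray, float, float]:
    """Signed lags (ms, A peak minus nearest B peak) of precise pairs.

    Only A events with a partner within +/- window/2 contribute; the
    nearest B peak is used (no one-to-one matching).  Returns
    (lags_ms, t statistic, p) of a one-sample t-test of the lags
    against zero; (empty, nan, nan) without pairs.
    """
    pa = _peaks(events_a)
    pb = _peaks(events_b)
    if pa.size == 0 or pb.size == 0:
        return np.empty(0), np.nan, np.nan
    pos = np.searchsorted(pb, pa)
    cand_lo = pb[np.clip(pos - 1, 0, len(pb) - 1)]
    cand_hi = pb[np.clip(pos, 0, len(pb) - 1)]
    nearest = np.where(np.abs(pa - cand_lo) <= np.abs(pa - cand_hi),
                       cand_lo, cand_hi)
    lags = (pa - nearest) / fs * 1000.0
    lags = lags[np.abs(lags) <= window_ms / 2.0]
    if lags.size == 0:
        return lags, np.nan, np.nan
    if lags.size == 1 or np.ptp(lags) == 0:
        return lags, 0.0 if np.allclose(lags, 0) else np.nan, np.nan
    t, p = sp_stats.ttest_1samp(lags, 0.0)
    return lags, float(t), float(p)


def cooccurrence_table(events_a: list[RippleEvent],
                       events_b: list[RippleEvent],
                       surrogates_a: SurrogateEventSets,
                       surrogates_b: SurrogateEventSets,
                       fs: float, label_a: str = "HPC", label_b: str = "AMY",
                       windows_ms: tuple[float, ...] = WINDOWS_MS
                       ) -> pd.DataFrame:
    """Both directions x all windows, with empirical p-values.

    Direction "A during B" counts the fraction of A's ripples near B
    peaks (and tests against B's surrogate sets), mirroring the usual
    per-patient co-occurrence table layout.
    """
    rows = []
    for direction, ea, eb, surr in (
            (f"{label_a} during {label_b}", events_a, events_b, surrogates_b),
            (f"{label_b} during {label_a}", events_b, events_a, surrogates_a)):
        for w in windows_ms:
            rate = cooccurrence_rate(ea, eb, w, fs)
            p, srates = cooccurrence_significance(
                ea, surr, w, fs, observed_rate=rate)
            rows.append({
                "direction": direction, "window_ms": w,
                "rate_percent": rate, "p": p,
                "p_label": f"<{1 / surr.n_sets:g}"
                if rate > srates.max() else f"{p:.3g}",
            })
    return pd.DataFrame(rows)
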
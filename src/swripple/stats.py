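"""Surrogate-based statistics shared across the pipeline.

z-scoring of an observed statistic against an empirical surrogate null,
z-to-P mapping, empirical (proportion-based) p-values, 4-connected
cluster extraction on z maps with extent rules, multi-level integer
cluster outlines, and the one-sample cluster-based permutation test
(sign-flip scheme) used for PAC significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sp_stats

__all__ = [
    "Cluster",
    "z_to_p_one_sided",
    "surrogate_zscore",
    "empirical_p",
    "find_clusters",
    "choose_outline_levels",
    "cluster_permutation_onesample",
    "cluster_report",
]

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    """A sign-homogeneous 4-connected component of a thresholded map."""

    members: np.ndarray  # (n, 2) array of (row, col) indices
    level: float
    sign: int
    mass: float
    p: float | None = None

    @property
    def row_extent(self) -> int:
        return int(self.members[:, 0].max() - self.members[:, 0].min() + 1)

    @property
    def col_extent(self) -> int:
        return int(self.members[:, 1].max() - self.members[:, 1].min() + 1)

    @property
    def n_bins(self) -> int:
        return len(self.members)


def z_to_p_one_sided(z: float | np.ndarray) -> float | np.ndarray:
    """Upper-tail standard-normal probability (z=2 -> ~0.02, 5 -> ~1e-7)."""
    return sp_stats.norm.sf(z)


def surrogate_zscore(observed: np.ndarray | float,
                     surrogates: np.ndarray,
                     axis: int = 0) -> np.ndarray | float:
    """(observed - mean) / sd of the surrogate distribution (sample sd)."""
    surrogates = np.asarray(surrogates, dtype=float)
    if surrogates.shape[axis] < 2:
        raise ValueError("need at least two surrogate values")
    sd = surrogates.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate surrogate null: zero spread")
    return (observed - surrogates.mean(axis=axis)) / sd


def empirical_p(observed: float, surrogates: np.ndarray) -> float:
    """Proportion of surrogate values >= observed; 0 reported as < 1/n.

    Ties count toward the p-value.  A result smaller than every surrogate
    is reported as 1/n (i.e., "P < 1/n") so p stays in (0, 1].
    """
    surrogates = np.asarray(surrogates, dtype=float)
    n = len(surrogates)
    if n < 1:
        raise ValueError("need at least one surrogate value")
    count = int(np.count_nonzero(surrogates >= observed))
    return max(count, 1) / n


def find_clusters(z_map: np.ndarray, level: float,
                  min_freq_bins: int = 2, min_time_bins: int = 10
                  ) -> list[Cluster]:
    """Sign-homogeneous 4-connected clusters of ``|z| >= level``.

    Rows are frequency, columns time.  A component is kept only if its
    bounding extent spans at least ``min_freq_bins`` rows and
    ``min_time_bins`` columns (10 columns at 250 Hz span 36 ms).
    """
    if level <= 0:
        raise ValueError("level must be positive")
    z_map = np.asarray(z_map, dtype=float)
    clusters: list[Cluster] = []
    for sign in (1, -1):
        above = sign * z_map >= level
        labels, n = ndimage.label(above, structure=FOUR_CONN)
        for obj in range(1, n + 1):
            members = np.argwhere(labels == obj)
            c = Cluster(members=members, level=level, sign=sign,
                        mass=float(z_map[labels == obj].sum()))
            if c.row_extent >= min_freq_bins and c.col_extent >= min_time_bins:
                clusters.append(c)
    return clusters


def choose_outline_levels(z_map: np.ndarray,
                          min_freq_bins: int = 2, min_time_bins: int = 10,
                          z_lo: int = 3, z_hi: int = 25,
                          max_levels: int = 5) -> list[int]:
    """Up to 5 integer outline levels for very-high-z maps.

    The lower bound is the smallest integer >= ``z_lo`` whose clusters do
    not comprise all frequency rows; the upper bound the largest integer
    <= ``z_hi`` still producing a valid cluster.  Levels are evenly
    spaced integers across that range.
    """
    z_map = np.asarray(z_map, dtype=float)
    n_rows = z_map.shape[0]
    zmin = None
    for level in range(z_lo, z_hi + 1):
        cl = find_clusters(z_map, level, min_freq_bins, min_time_bins)
        if not cl:
            continue
        if all(c.row_extent < n_rows for c in cl):
            zmin = level
            break
    if zmin is None:
        return []
    zmax = None
    for level in range(z_hi, zmin - 1, -1):
        if find_clusters(z_map, level, min_freq_bins, min_time_bins):
            zmax = level
            break
    if zmax is None:
        return []
    if zmax - zmin + 1 <= max_levels:
        return list(range(zmin, zmax + 1))
    return sorted({int(v) for v in np.linspace(zmin, zmax, max_levels)})


def cluster_permutation_onesample(values: np.ndarray,
                                  clusteralpha: float = 0.1,
                                  n_perm: int = 1000,
                                  min_extent: tuple[int, int] = (2, 2),
                                  alpha: float = 0.05,
                                  seed: int | np.random.Generator = 0
                                  ) -> list[Cluster]:
    """One-tailed one-sample cluster-based permutation test against zero.

    ``values`` has shape (n_segments, n_rows, n_cols).  Bin-wise t
    statistics (vs 0, positive tail) are thresholded at the t value
    corresponding to ``clusteralpha``; 4-connected supra-threshold
    clusters with bounding extent >= ``min_extent`` get a mass (sum of
    t).  The null is built from ``n_perm`` random sign flips of whole
    segments, recording each permutation's maximum cluster mass; a
    cluster is significant when its mass exceeds the (1 - alpha)
    quantile of that null.
    """
    values = np.asarray(values, dtype=float)
    n_seg = values.shape[0]
    if n_seg < 3:
        raise ValueError("need at least three segments")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    tcrit = sp_stats.t.ppf(1.0 - clusteralpha, n_seg - 1)

    flat = values.reshape(n_seg, -1)
    ss = np.sum(flat ** 2, axis=0)  # invariant under sign flips

    def tmap(signs: np.ndarray) -> np.ndarray:
        s = signs @ flat
        mean = s / n_seg
        var = (ss - n_seg * mean ** 2) / (n_seg - 1)
        var = np.maximum(var, np.finfo(float).tiny)
        return (mean / np.sqrt(var / n_seg)).reshape(values.shape[1:])

    t_obs = tmap(np.ones(n_seg))
    labels, n = ndimage.label(t_obs >= tcrit, structure=FOUR_CONN)
    observed: list[Cluster] = []
    for obj in range(1, n + 1):
        members = np.argwhere(labels == obj)
        c = Cluster(members=members, level=float(tcrit), sign=1,
                    mass=float(t_obs[labels == obj].sum()))
        if c.row_extent >= min_extent[0] and c.col_extent >= min_extent[1]:
            observed.append(c)
    if not observed:
        return []

    null = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_seg)
        t = tmap(signs)
        lab, m = ndimage.label(t >= tcrit, structure=FOUR_CONN)
        best = 0.0
        for obj in range(1, m + 1):
            sel = lab == obj
            # bounding extent via index ranges
            r = np.flatnonzero(np.any(sel, axis=1))
            col = np.flatnonzero(np.any(sel, axis=0))
            if (r[-1] - r[0] + 1 >= min_extent[0]
                    and col[-1] - col[0] + 1 >= min_extent[1]):
                best = max(best, float(t[sel].sum()))
        null[i] = best

    significant = []
    for c in observed:
        c.p = float(np.mean(null >= c.mass))
        if c.p < alpha:
            significant.append(c)
    return significant


def cluster_report(clusters, row_values: np.ndarray,
                   col_values_ms: np.ndarray):
    """Tidy cluster table: one row per cluster with frequency/time spans.

    ``row_values`` maps row indices to Hz; ``col_values_ms`` maps column
    indices to milliseconds.  Columns: level, sign, n_bins, f_min_hz,
    f_max_hz, t_min_ms, t_max_ms, mass, p.
    """
    import pandas as pd

    rows = []
    for c in clusters:
        r = c.members[:, 0]
        col = c.members[:, 1]
        rows.append({
            "level": c.level, "sign": c.sign, "n_bins": c.n_bins,
            "f_min_hz": float(np.min(row_values[r])),
            "f_max_hz": float(np.max(row_values[r])),
            "t_min_ms": float(np.min(col_values_ms[col])),
            "t_max_ms": float(np.max(col_values_ms[col])),
            "mass": c.mass, "p": c.p,
        })
    return pd.DataFrame(rows, columns=["level", "sign", "n_bins",
                                       "f_min_hz", "f_max_hz", "t_min_ms",
                                       "t_max_ms", "mass", "p"])
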
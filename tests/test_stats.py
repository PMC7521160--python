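"""Surrogate z-scoring, empirical p, clusters and permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swripple as sw
from swripple.stats import Cluster


def test_z_to_p_printed_correspondences():
    """z of 2, 3, 5 map to one-sided P of ~0.02, ~0.001, ~1e-7."""
    assert sw.z_to_p_one_sided(2.0) == pytest.approx(0.0228, abs=5e-4)
    assert sw.z_to_p_one_sided(3.0) == pytest.approx(0.00135, abs=5e-5)
    assert sw.z_to_p_one_sided(5.0) == pytest.approx(2.87e-7, rel=0.01)
    assert sw.z_to_p_one_sided(0.0) == pytest.approx(0.5)


def test_surrogate_zscore_hand_examples():
    assert sw.surrogate_zscore(2.0, np.array([1.0, 2.0, 3.0])) == 0.0
    vals = np.array([1.0, 2.0, 3.0])  # mean 2, sample sd 1
    assert sw.surrogate_zscore(5.0, vals) == pytest.approx(3.0)
    assert sw.surrogate_zscore(2.0 + 2 * vals.std(ddof=1), vals) \
        == pytest.approx(2.0)
    with pytest.raises(ValueError):
        sw.surrogate_zscore(1.0, np.array([2.0, 2.0]))
    with pytest.raises(ValueError):
        sw.surrogate_zscore(1.0, np.array([2.0]))


def test_empirical_p_ties_and_floor():
    surr = np.full(1000, 3.0)
    assert sw.empirical_p(3.0, surr) == 1.0  # ties count
    assert sw.empirical_p(4.0, surr) == pytest.approx(1 / 1000)  # "< 1/n"
    odd = np.arange(999.0)
    assert sw.empirical_p(np.median(odd), odd) == pytest.approx(0.5,
                                                                abs=0.01)


@given(st.floats(-5, 5), st.lists(st.floats(-5, 5), min_size=1,
                                  max_size=50))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_empirical_p_bounds_and_monotonicity(obs, vals):
    """p lies in (0, 1]; appending a value >= observed never lowers p."""
    vals = np.asarray(vals)
    p = sw.empirical_p(obs, vals)
    assert 0.0 < p <= 1.0
    bigger = np.append(vals, obs + 1.0)
    n0, n1 = len(vals), len(bigger)
    assert sw.empirical_p(obs, bigger) * n1 >= p * n0


class TestFindClusters:
    def test_all_zero_map(self):
        assert sw.find_clusters(np.zeros((20, 40)), 3.0) == []

    def test_block_cluster_found(self):
        z = np.zeros((20, 40))
        z[5:8, 10:22] = 6.0  # 3 freq x 12 time bins
        (c,) = sw.find_clusters(z, 5.0)
        assert c.n_bins == 36
        assert c.sign == 1
        assert c.mass == pytest.approx(36 * 6.0)

    def test_single_row_rejected(self):
        z = np.zeros((20, 60))
        z[4, 5:55] = 10.0
        assert sw.find_clusters(z, 5.0) == []

    def test_short_cluster_rejected(self):
        z = np.zeros((20, 40))
        z[5:9, 10:19] = 8.0  # 9 time bins < 10
        assert sw.find_clusters(z, 5.0) == []

    def test_negative_clusters_sign_homogeneous(self):
        z = np.zeros((20, 40))
        z[2:6, 5:20] = -7.0
        (c,) = sw.find_clusters(z, 5.0)
        assert c.sign == -1 and c.mass < 0

    def test_monotone_in_level(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 3, (30, 80))
        z[10:16, 20:50] += 8
        sizes = []
        for level in (3.0, 4.0, 5.0):
            cl = sw.find_clusters(z, level)
            sizes.append(max((c.n_bins for c in cl), default=0))
        assert sizes == sorted(sizes, reverse=True)


class TestOutlineLevels:
    def test_low_map_gives_small_levels(self):
        z = np.zeros((20, 40))
        z[5:9, 10:25] = 4.2
        levels = sw.choose_outline_levels(z)
        assert levels and set(levels) <= {3, 4}

    def test_subthreshold_map_empty(self):
        assert sw.choose_outline_levels(np.full((10, 20), 2.5)) == []

    def test_even_spacing_full_range(self):
        z = np.zeros((20, 40))
        z[5:9, 10:25] = 30.0  # clusters survive any level up to 25
        z[0, 0] = 3.0
        assert sw.choose_outline_levels(z) == [3, 8, 14, 19, 25]

    def test_all_rows_cluster_pushes_zmin_up(self):
        z = np.full((10, 40), 3.5)  # level 3 cluster spans every row
        z[4:6, 10:25] = 9.0
        levels = sw.choose_outline_levels(z)
        assert levels[0] == 4


class TestClusterPermutation:
    def test_zero_segments_no_clusters(self):
        vals = np.zeros((10, 8, 8))
        assert sw.cluster_permutation_onesample(vals, seed=0) == []

    def test_block_effect_detected(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (30, 12, 12))
        vals[:, 4:8, 4:8] += 1.0
        clusters = sw.cluster_permutation_onesample(vals, seed=2)
        assert clusters
        best = max(clusters, key=lambda c: c.mass)
        assert best.p < 0.05
        rows = set(best.members[:, 0])
        assert rows & set(range(4, 8))

    def test_single_bin_rejected_by_extent(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.1, (30, 8, 8))
        vals[:, 2, 2] += 5.0  # massive but 1x1
        assert sw.cluster_permutation_onesample(vals, seed=4) == []

    def test_needs_three_segments(self):
        with pytest.raises(ValueError):
            sw.cluster_permutation_onesample(np.zeros((2, 4, 4)), seed=0)

    def test_type_one_error_controlled(self):
        """Across 200 null simulations the family-wise rate stays <=0.08."""
        rng = np.random.default_rng(5)
        false_pos = 0
        for _ in range(200):
            vals = rng.normal(0, 1, (30, 12, 12))
            if sw.cluster_permutation_onesample(vals, n_perm=300,
                                                seed=rng):
                false_pos += 1
        assert false_pos / 200 <= 0.08


def test_cluster_extent_properties():
    members = np.array([[2, 3], [2, 4], [3, 3], [3, 4]])
    c = Cluster(members=members, level=3.0, sign=1, mass=10.0)
    assert c.row_extent == 2 and c.col_extent == 2 and c.n_bins == 4
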
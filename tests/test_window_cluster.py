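import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from nomephase.window_cluster import (
    agglomerative_cluster,
    cluster_means,
    define_windows,
    masked_distance,
    pairwise_masked_distance,
    window_members,
)

from conftest import matrix_from_values

NAN = float("nan")


class TestMaskedDistance:
    def test_identity_zero(self):
        assert masked_distance([1, 0, 1], [1, 0, 1]) == 0.0

    def test_hand_value_half(self):
        assert masked_distance([1, 0, NAN], [0, 0, 1]) == pytest.approx(0.5)

    def test_disjoint_supports_zero(self):
        assert masked_distance([NAN, NAN, 1], [1, 0, NAN]) == 0.0

    def test_disjoint_supports_config_switch(self):
        assert masked_distance([NAN, 1], [1, NAN], disjoint_distance=1.0) == 1.0

    def test_binary_reduces_to_hamming_fraction(self, rng):
        u = rng.integers(0, 2, 40).astype(float)
        v = rng.integers(0, 2, 40).astype(float)
        assert masked_distance(u, v) == pytest.approx(np.mean(u != v))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            masked_distance([1, 0], [1, 0, 1])

    @given(
        hnp.arrays(
            float,
            st.integers(1, 30),
            elements=st.one_of(st.just(np.nan), st.floats(0, 1)),
        ).flatmap(
            lambda u: st.tuples(
                st.just(u),
                hnp.arrays(
                    float,
                    len(u),
                    elements=st.one_of(st.just(np.nan), st.floats(0, 1)),
                ),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_bounds_identity(self, pair):
        u, v = pair
        d = masked_distance(u, v)
        assert d == masked_distance(v, u)
        assert 0.0 <= d <= 1.0
        assert masked_distance(u, u) == 0.0

    def test_pairwise_matches_scalar(self, rng):
        X = rng.random((8, 15))
        X[rng.random((8, 15)) < 0.3] = np.nan
        D = pairwise_masked_distance(X)
        for i in range(8):
            for j in range(8):
                if i != j:
                    assert D[i, j] == pytest.approx(
                        masked_distance(X[i], X[j]), abs=1e-12
                    )
        np.testing.assert_array_equal(np.diag(D), 0.0)


def full_matrix(n_valid_bins, n_reads=1):
    return matrix_from_values(np.ones((n_reads, n_valid_bins)))


class TestDefineWindows:
    def test_100_valid_bins(self):
        windows = define_windows(full_matrix(100), 60, 20)
        spans = [
            (w.valid_bin_indices[0], w.valid_bin_indices[-1] + 1) for w in windows
        ]
        assert spans == [(0, 60), (40, 100)]

    def test_exactly_60_one_window(self):
        windows = define_windows(full_matrix(60), 60, 20)
        assert len(windows) == 1
        assert windows[0].size == 60

    def test_110_valid_bins_right_anchored(self):
        windows = define_windows(full_matrix(110), 60, 20)
        spans = [
            (w.valid_bin_indices[0], w.valid_bin_indices[-1] + 1) for w in windows
        ]
        assert spans == [(0, 60), (40, 100), (50, 110)]
        # final window overlaps its predecessor by >= overlap bins
        assert spans[-2][1] - spans[-1][0] >= 20

    def test_fewer_than_window_size_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            windows = define_windows(full_matrix(30), 60, 20)
        assert len(windows) == 1
        assert windows[0].size == 30

    def test_windows_enumerate_valid_bins_only(self):
        vals = np.ones((1, 100))
        vals[0, 10:30] = np.nan  # 20 invalid bins
        windows = define_windows(matrix_from_values(vals), 60, 20)
        for w in windows:
            assert not np.any((w.valid_bin_indices >= 10) & (w.valid_bin_indices < 30))

    def test_consecutive_windows_share_at_least_overlap(self, rng):
        for nv in (60, 75, 100, 137, 200, 241):
            windows = define_windows(full_matrix(nv), 60, 20)
            for a, b in zip(windows, windows[1:]):
                shared = np.intersect1d(a.valid_bin_indices, b.valid_bin_indices)
                assert len(shared) >= 20

    def test_overlap_ge_size_rejected(self):
        with pytest.raises(ValueError):
            define_windows(full_matrix(100), 60, 60)


class TestWindowMembers:
    def test_min_valid_bins_per_window(self):
        vals = np.full((2, 60), np.nan)
        vals[0, :30] = 1.0  # exactly 30 valid bins -> member
        vals[1, :29] = 1.0  # 29 -> excluded
        m = matrix_from_values(vals)
        w = define_windows(m, 60, 20)[0]
        assert window_members(m, w, 30).tolist() == [0]

    def test_membership_conservation(self, rng):
        vals = rng.random((20, 150))
        vals[rng.random((20, 150)) < 0.4] = np.nan
        m = matrix_from_values(vals)
        windows = define_windows(m, 60, 20)
        member_anywhere = set()
        for w in windows:
            member_anywhere.update(window_members(m, w, 30).tolist())
        for i in range(20):
            qualifies = any(
                m.observed[i, w.valid_bin_indices].sum() >= 30 for w in windows
            )
            assert (i in member_anywhere) == qualifies


def reference_average_linkage(D, t):
    """Step-2 definition recomputed from scratch at every merge (oracle)."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    while len(clusters) > t:
        best = None
        for p in range(len(clusters)):
            for q in range(p + 1, len(clusters)):
                d = np.mean([D[u, v] for u in clusters[p] for v in clusters[q]])
                key = (d, min(clusters[p][0], clusters[q][0]),
                       max(clusters[p][0], clusters[q][0]))
                if best is None or key < best[0]:
                    best = (key, p, q)
        _, p, q = best
        clusters[p] = sorted(clusters[p] + clusters[q])
        del clusters[q]
    clusters.sort(key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for k, c in enumerate(clusters):
        labels[c] = k
    return labels


class TestAgglomerativeCluster:
    def test_n_equals_t_singletons(self, rng):
        X = rng.random((4, 10))
        labels = agglomerative_cluster(X, 4)
        assert sorted(labels) == [0, 1, 2, 3]

    def test_two_identical_pairs(self):
        X = np.array(
            [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=float
        )
        labels = agglomerative_cluster(X, 2)
        assert labels[0] == labels[2]
        assert labels[1] == labels[3]
        assert labels[0] != labels[1]

    def test_matches_scipy_on_complete_data(self, rng):
        X = rng.random((20, 25))
        D = pairwise_masked_distance(X)
        mine = agglomerative_cluster(None, 4, D=D)
        Z = linkage(squareform(D, checks=False), method="average")
        ref = fcluster(Z, 4, criterion="maxclust")
        assert adjusted_rand_score(mine, ref) == 1.0

    def test_matches_step2_recomputation_oracle(self, rng):
        # the Lance-Williams update coincides with the full-pairwise
        # definition exactly on complete data
        for _ in range(5):
            n = int(rng.integers(8, 15))
            X = rng.random((n, 12))
            D = pairwise_masked_distance(X)
            for t in (2, 3):
                mine = agglomerative_cluster(None, t, D=D)
                oracle = reference_average_linkage(D, t)
                np.testing.assert_array_equal(mine, oracle)

    def test_lance_williams_update_equals_recompute_to_1e12(self, rng):
        # merge pairs in an arbitrary order and verify the size-weighted
        # update equals the full pairwise average at every step
        n = 12
        X = rng.random((n, 10))
        D = pairwise_masked_distance(X)
        clusters = [[i] for i in range(n)]
        dist = {
            (p, q): D[p, q] for p in range(n) for q in range(p + 1, n)
        }

        def avg(cp, cq):
            return np.mean([D[u, v] for u in cp for v in cq])

        order = rng.permutation(n - 2)
        for _ in order:
            p, q = sorted(rng.choice(len(clusters), 2, replace=False))
            cp, cq = clusters[p], clusters[q]
            merged = cp + cq
            for r, other in enumerate(clusters):
                if r in (p, q):
                    continue
                lw = (
                    len(cp) * avg(cp, other) + len(cq) * avg(cq, other)
                ) / len(merged)
                assert lw == pytest.approx(avg(merged, other), abs=1e-12)
            clusters[p] = merged
            del clusters[q]

    def test_deterministic_across_runs(self, rng):
        X = rng.integers(0, 2, size=(30, 20)).astype(float)
        l1 = agglomerative_cluster(X, 3)
        l2 = agglomerative_cluster(X.copy(), 3)
        np.testing.assert_array_equal(l1, l2)

    def test_n_below_t_singletons_with_warning(self, rng):
        X = rng.random((2, 5))
        with pytest.warns(UserWarning, match="singleton"):
            labels = agglomerative_cluster(X, 5)
        assert sorted(labels) == [0, 1]

    def test_t_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            agglomerative_cluster(rng.random((3, 4)), 0)


class TestClusterMeans:
    def test_single_read_cluster_is_that_read(self):
        X = np.array([[0.2, NAN, 1.0]])
        mu = cluster_means(X, np.array([0]), 1)
        np.testing.assert_array_equal(mu[0], X[0])

    def test_hand_masked_mean(self):
        X = np.array([[1, NAN], [0, 1]], dtype=float)
        mu = cluster_means(X, np.array([0, 0]), 1)
        np.testing.assert_allclose(mu[0], [0.5, 1.0])

    def test_all_missing_bin_stays_missing(self):
        X = np.array([[NAN, 1], [NAN, 0]], dtype=float)
        mu = cluster_means(X, np.array([0, 0]), 1)
        assert np.isnan(mu[0, 0])

    def test_empty_cluster_all_missing(self):
        X = np.array([[1.0, 0.0]])
        mu = cluster_means(X, np.array([0]), 2)
        assert np.isnan(mu[1]).all()
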
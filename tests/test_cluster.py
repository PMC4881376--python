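"""Clustering algorithms against independent oracles and their invariants.

scikit-learn and scipy serve purely as reference implementations; the
package's own from-scratch code is what is being validated.
"""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.cluster import KMeans as SkKMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

import isophene as ip
from isophene.cluster import (
    DegeneratePartition,
    HIERARCHICAL_METHODS,
    build_features,
    cluster_means,
)


def random_points(n, d, seed):
    return np.random.default_rng(seed).standard_normal((n, d))


# ---------------------------------------------------------------------------
# feature scaling

class TestStandardize:
    def test_zscore_columns(self, day7):
        _, ratios, _ = day7
        f = build_features(ratios)
        assert f.columns == ["r13C", "r15N", "r33S", "rC_CN", "rS_CN"]
        np.testing.assert_allclose(f.data.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(f.data.std(axis=0, ddof=1), 1, rtol=1e-12)

    def test_back_transform_inverts(self, day7):
        _, ratios, _ = day7
        f = build_features(ratios)
        pts = np.array([[0.1, 0.2, 0.3, 0.4, 0.5], [0.0, 0.0, 0.0, 0.0, 0.0]])
        np.testing.assert_allclose(f.to_raw(f.to_scaled(pts)), pts, atol=1e-12)

    def test_constant_column_dropped(self, day7):
        _, ratios, _ = day7
        r = ratios.copy()
        r["r13C"] = 0.5
        f = build_features(r)
        assert "r13C" not in f.columns

    def test_all_constant_rejected(self, day7):
        _, ratios, _ = day7
        r = ratios.copy()
        for c in r.columns:
            r[c] = 1.0
        with pytest.raises(ValueError):
            build_features(r)


# ---------------------------------------------------------------------------
# k-means

class TestKMeans:
    def test_separated_blobs_recovered(self, blobs):
        X, truth, centers = blobs
        sol = ip.kmeans(X, 4, seed=0)
        # each true blob maps to exactly one found cluster
        for t in range(1, 5):
            found = sol.labels[truth == t]
            assert len(np.unique(found)) == 1

    def test_1d_optimum_by_enumeration(self):
        """{0,1,9,10,11} at k=2 must split as {0,1} | {9,10,11}."""
        X = np.array([[0.0], [1.0], [9.0], [10.0], [11.0]])
        sol = ip.kmeans(X, 2, seed=3, restarts=10)
        assert set(map(tuple, [sol.labels[:2], sol.labels[2:]])) == {
            (sol.labels[0],) * 2, (sol.labels[2],) * 3}
        # brute-force oracle: enumerate all 2-partitions, minimize WSS
        best = None
        for assign in itertools.product([0, 1], repeat=5):
            if len(set(assign)) < 2:
                continue
            a = np.array(assign)
            wss = sum(((X[a == j] - X[a == j].mean(axis=0)) ** 2).sum() for j in (0, 1))
            if best is None or wss < best:
                best = wss
        assert sol.objective == pytest.approx(best)

    def test_k_equals_n(self):
        X = random_points(6, 2, 0)
        sol = ip.kmeans(X, 6, seed=0)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(sol.labels)) == 6

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValueError):
            ip.kmeans(random_points(3, 2, 0), 4)

    def test_objective_non_increasing(self):
        X = random_points(60, 3, 1)
        sol = ip.kmeans(X, 4, seed=1, restarts=3)
        h = np.array(sol.objective_history)
        assert (np.diff(h) <= 1e-9).all()

    def test_matches_sklearn_objective(self):
        """Best-of-restarts WSS agrees with scikit-learn on an easy instance."""
        X = random_points(80, 2, 7)
        ours = ip.kmeans(X, 3, seed=0, restarts=30)
        sk = SkKMeans(3, n_init=30, random_state=0).fit(X)
        assert ours.objective == pytest.approx(sk.inertia_, rel=1e-6)


# ---------------------------------------------------------------------------
# fuzzy c-means

class TestFuzzyCMeans:
    def test_equidistant_point_memberships(self):
        """A point midway between two symmetric clusters gets u = (1/2, 1/2)."""
        X = np.array([[-1.0, 0], [-1, 0.1], [1, 0], [1, 0.1], [0, 0.05]])
        sol = ip.fuzzy_cmeans(X, 2, seed=0, restarts=5)
        np.testing.assert_allclose(sol.membership[-1], [0.5, 0.5], atol=1e-3)

    def test_k1_center_is_mean(self):
        X = random_points(20, 2, 3)
        sol = ip.fuzzy_cmeans(X, 1, seed=0, restarts=2)
        np.testing.assert_allclose(sol.membership, 1.0)
        np.testing.assert_allclose(sol.centers[0], X.mean(axis=0), atol=1e-9)

    def test_1d_toy_centers(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        sol = ip.fuzzy_cmeans(X, 2, seed=0, restarts=5)
        got = np.sort(sol.centers.ravel())
        np.testing.assert_allclose(got, [0.05, 10.05], atol=1e-3)

    def test_membership_rows_sum_to_one(self, day7):
        _, ratios, _ = day7
        f = build_features(ratios)
        sol = ip.fuzzy_cmeans(f.data, 5, seed=2, restarts=3)
        np.testing.assert_allclose(sol.membership.sum(axis=1), 1.0, atol=1e-9)
        assert ((sol.membership >= 0) & (sol.membership <= 1)).all()

    def test_objective_non_increasing(self, day7):
        _, ratios, _ = day7
        f = build_features(ratios)
        sol = ip.fuzzy_cmeans(f.data, 5, seed=4, restarts=2)
        h = np.array(sol.objective_history)
        assert (np.diff(h) <= 1e-8).all()

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        sol = ip.fuzzy_cmeans(X, 2, seed=0, restarts=3)
        assert sol.membership.max(axis=1).min() > 0.999

    def test_low_fuzzifier_approaches_hard(self, blobs):
        """As m -> 1+, memberships approach the hard k-means assignment."""
        X, _, _ = blobs
        soft = ip.fuzzy_cmeans(X, 4, m=1.05, seed=0, restarts=5)
        assert soft.membership.max(axis=1).min() > 0.99

    def test_invalid_fuzzifier_rejected(self):
        with pytest.raises(ValueError):
            ip.fuzzy_cmeans(random_points(5, 2, 0), 2, m=1.0)


# ---------------------------------------------------------------------------
# PAM

class TestPAM:
    def test_k_equals_n_cost_zero(self):
        X = random_points(5, 2, 0)
        sol = ip.pam(X, 5)
        assert sol.objective == pytest.approx(0.0)

    def test_1d_medoids_by_enumeration(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        sol = ip.pam(X, 2)
        assert set(X[sol.medoid_ids].ravel()) == {1.0, 11.0}

    def test_matches_exhaustive_search(self):
        """SWAP local optimum equals the global optimum on small instances."""
        for seed in range(4):
            X = random_points(10, 2, seed)
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            best = min(D[:, list(pair)].min(axis=1).sum()
                       for pair in itertools.combinations(range(10), 2))
            sol = ip.pam(X, 2)
            assert sol.objective == pytest.approx(best, rel=1e-9)

    def test_duplicated_data_same_medoid_values(self):
        X = random_points(8, 2, 1)
        X2 = np.vstack([X, X])
        m1 = np.sort(X[ip.pam(X, 2).medoid_ids], axis=0)
        m2 = np.sort(X2[ip.pam(X2, 2).medoid_ids], axis=0)
        np.testing.assert_allclose(m1, m2)


# ---------------------------------------------------------------------------
# hierarchical / Lance-Williams

SCIPY_NAME = {"single": "single", "complete": "complete", "average": "average",
              "mcquitty": "weighted", "centroid": "centroid", "median": "median",
              "ward": "ward"}


class TestLanceWilliams:
    def test_two_points_single_merge(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        for link in HIERARCHICAL_METHODS:
            d = ip.hclust_lance_williams(X, link)
            expected = 25.0 if link in ("centroid", "median", "ward") else 5.0
            assert d.heights[0] == pytest.approx(expected)

    def test_single_linkage_hand_example(self):
        """1-D {0,1,5}: merge (0,1) at distance 1, then at 4."""
        X = np.array([[0.0], [1.0], [5.0]])
        d = ip.hclust_lance_williams(X, "single")
        np.testing.assert_array_equal(d.merges[0], [0, 1])
        assert d.heights[0] == pytest.approx(1.0)
        assert d.heights[1] == pytest.approx(4.0)

    def test_average_matches_naive_recomputation(self):
        """UPGMA heights equal brute-force mean inter-cluster distances."""
        X = random_points(10, 3, 2)
        d = ip.hclust_lance_williams(X, "average")
        # replay merges, recomputing average distances from scratch
        members = {i: [i] for i in range(10)}
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        for t, (a, b) in enumerate(d.merges):
            naive = np.mean([D[i, j] for i in members[a] for j in members[b]])
            assert d.heights[t] == pytest.approx(naive, rel=1e-9)
            members[10 + t] = members.pop(int(a)) + members.pop(int(b))

    @pytest.mark.parametrize("link", ["single", "complete", "average",
                                      "mcquitty", "ward"])
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_partitions_match_scipy(self, link, k):
        """Monotone linkages: k-cluster partitions equal scipy's."""
        X = random_points(40, 4, 9)
        dend = ip.hclust_lance_williams(X, link)
        ours = ip.cut_dendrogram(dend, k)
        Z = scipy_linkage(X, method=SCIPY_NAME[link])
        ref = fcluster(Z, k, criterion="maxclust")
        # compare as partitions (label names are arbitrary)
        pairs_ours = ours[:, None] == ours[None, :]
        pairs_ref = ref[:, None] == ref[None, :]
        assert (pairs_ours == pairs_ref).all()

    @pytest.mark.parametrize("link", ["centroid", "median"])
    def test_merge_sequence_matches_scipy(self, link):
        """Non-monotone linkages (inversions possible): compare the merge
        sequence and heights directly rather than a height-based cut."""
        X = random_points(30, 3, 13)
        dend = ip.hclust_lance_williams(X, link)
        Z = scipy_linkage(X, method=SCIPY_NAME[link])
        ref_merges = np.sort(Z[:, :2].astype(int), axis=1)
        np.testing.assert_array_equal(dend.merges, ref_merges)
        # our heights are squared centroid distances; scipy reports Euclidean
        np.testing.assert_allclose(np.sqrt(dend.heights), Z[:, 2], rtol=1e-9)

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError):
            ip.hclust_lance_williams(random_points(4, 2, 0), "nope")


# ---------------------------------------------------------------------------
# validity indices

class TestCHIndex:
    def test_hand_computed_example(self):
        """1-D {0,1,10,11} split in half: B=100, W=1, CH=200."""
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assert ip.ch_index(X, np.array([1, 1, 2, 2])) == pytest.approx(200.0)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((30, 2)) * 0.2
        lab = np.repeat([1, 2], 15)
        prev = -np.inf
        for gap in (2.0, 4.0, 8.0):
            X = base.copy()
            X[15:, 0] += gap
            ch = ip.ch_index(X, lab)
            assert ch > prev
            prev = ch

    def test_label_permutation_invariant(self, blobs):
        X, lab, _ = blobs
        ch1 = ip.ch_index(X, lab)
        ch2 = ip.ch_index(X, 5 - lab)   # rename clusters
        assert ch1 == pytest.approx(ch2)

    def test_matches_sklearn(self):
        for seed in range(3):
            X = random_points(12, 3, seed)
            lab = np.random.default_rng(seed).integers(1, 4, 12)
            if len(np.unique(lab)) < 2:
                continue
            assert ip.ch_index(X, lab) == pytest.approx(
                calinski_harabasz_score(X, lab), rel=1e-9)

    def test_degenerate_k_rejected(self):
        X = random_points(5, 2, 0)
        with pytest.raises(ValueError):
            ip.ch_index(X, np.ones(5, dtype=int))


class TestSilhouette:
    def test_two_singletons_are_zero(self):
        X = np.array([[0.0, 0], [5.0, 5]])
        res = ip.silhouette_widths(X, np.array([1, 2]))
        np.testing.assert_allclose(res.widths, 0.0)

    def test_duplicate_pairs_approach_one(self):
        X = np.array([[0.0, 0], [0, 0], [9, 9], [9, 9]])
        res = ip.silhouette_widths(X, np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(res.widths, 1.0)

    def test_matches_sklearn(self):
        for seed in range(3):
            X = random_points(12, 2, seed + 20)
            lab = np.random.default_rng(seed).integers(1, 4, 12)
            if len(np.unique(lab)) < 2:
                continue
            ref = silhouette_samples(X, lab)
            res = ip.silhouette_widths(X, lab)
            np.testing.assert_allclose(res.widths, ref, atol=1e-9)
            assert res.overall_mean == pytest.approx(ref.mean())


# ---------------------------------------------------------------------------
# method x k scan

class TestScan:
    def test_grid_shape(self, blobs):
        X, _, _ = blobs
        scan = ip.scan_methods(X, ["kmeans", "average"], range(2, 6), seed=0, restarts=5)
        assert len(scan.grid) == 2 * 4

    def test_two_gaussians_select_k2(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.3, (40, 2)), rng.normal(6, 0.3, (40, 2))])
        scan = ip.scan_methods(X, ["kmeans"], range(2, 8), seed=0, restarts=5)
        assert scan.best == ("kmeans", 2)

    def test_best_is_argmax_of_valid_cells(self, blobs):
        X, _, _ = blobs
        scan = ip.scan_methods(X, ["kmeans", "ward", "pam"], range(2, 7),
                               seed=1, restarts=5)
        valid = scan.grid[scan.grid["valid"]]
        top = valid.loc[valid["ch"].idxmax()]
        assert scan.grid.loc[
            (scan.grid["method"] == scan.best[0]) & (scan.grid["k"] == scan.best[1]),
            "ch"].iloc[0] == pytest.approx(top["ch"])
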
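"""Forest dissimilarity, tuning, stability, classical MDS and UPGMA."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

import corticolimbic as cl
from corticolimbic.forest import _fit_real_vs_contrast

from _oracles import upgma_cophenetic


def blobs(rng, n_per, centers, sd=1.0):
    parts = [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    X = np.vstack(parts)
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestContrastSample:
    def test_constant_column_unchanged(self):
        X = np.column_stack([np.full(50, 3.0), np.random.default_rng(0).normal(size=50)])
        synth = cl.make_contrast_sample(X, seed=1)
        assert (synth[:, 0] == 3.0).all()

    def test_marginals_preserved(self):
        rng = np.random.default_rng(1)
        X = rng.normal([0.0, 5.0, -2.0], [1.0, 2.0, 0.5], size=(500, 3))
        synth = cl.make_contrast_sample(X, seed=2)
        np.testing.assert_allclose(synth.mean(0), X.mean(0), atol=0.3)
        np.testing.assert_allclose(synth.std(0), X.std(0), rtol=0.15)

    def test_between_column_dependence_destroyed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        X = np.column_stack([x, x + rng.normal(scale=0.1, size=500)])
        assert np.corrcoef(X.T)[0, 1] > 0.95
        synth = cl.make_contrast_sample(X, seed=3)
        assert abs(np.corrcoef(synth.T)[0, 1]) < 0.3


class TestDissimilarity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matrix_invariants(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 6))
        D = cl.rf_dissimilarity(X, cl.RfParams(200, 2, 1, seed))
        v = D.values
        np.testing.assert_allclose(v, v.T)
        np.testing.assert_allclose(np.diag(v), 0.0)
        assert (v >= 0.0).all() and (v <= 1.0).all()

    def test_duplicated_row_attains_minimum(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        X[17] = X[4]
        D = cl.rf_dissimilarity(X, cl.RfParams(500, 2, 1, 3)).values
        off = D[np.triu_indices_from(D, k=1)]
        assert D[4, 17] == off.min()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_separated_blobs_within_less_than_between(self, seed):
        rng = np.random.default_rng(seed)
        X, labels = blobs(rng, 30, [np.zeros(5), np.full(5, 6.0)])
        D = cl.rf_dissimilarity(X, cl.RfParams(500, 2, 1, seed)).values
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices_from(D, k=1)
        within = D[iu][same[iu]]
        between = D[iu][~same[iu]]
        assert within.mean() < between.mean()

    def test_sqrt_toggle_monotone(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 4))
        params = cl.RfParams(200, 2, 1, 4)
        d_sqrt = cl.rf_dissimilarity(X, params, sqrt_transform=True).values
        d_lin = cl.rf_dissimilarity(X, params, sqrt_transform=False).values
        np.testing.assert_allclose(d_sqrt ** 2, d_lin, atol=1e-12)

    def test_oob_restricted_proximity_valid(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        D = cl.rf_dissimilarity(X, cl.RfParams(300, 2, 1, 5), oob_only=True).values
        assert (D >= 0).all() and (D <= 1).all()
        np.testing.assert_allclose(np.diag(D), 0.0)


class TestTuning:
    def test_singleton_grid_returned(self):
        X = np.random.default_rng(0).normal(size=(30, 5))
        params = cl.tune_rf(X, [3], [2], n_trees=100, seed=0)
        assert (params.mtry, params.nodesize) == (3, 2)

    def test_duplicate_grid_cells_ignored(self):
        X = np.random.default_rng(1).normal(size=(30, 5))
        a = cl.tune_rf(X, [2, 3], [1, 5], n_trees=100, seed=1)
        b = cl.tune_rf(X, [2, 3, 3, 2], [1, 5, 5], n_trees=100, seed=1)
        assert (a.mtry, a.nodesize) == (b.mtry, b.nodesize)

    def test_selected_params_minimize_reevaluated_oob_error(self):
        rng = np.random.default_rng(2)
        X, _ = blobs(rng, 25, [np.zeros(6), np.full(6, 4.0)])
        grid_m, grid_n = [2, 4], [1, 8]
        chosen = cl.tune_rf(X, grid_m, grid_n, n_trees=300, seed=2)
        contrast = cl.make_contrast_sample(X, seed=3)
        errs = {}
        for m in grid_m:
            for n in grid_n:
                clf = _fit_real_vs_contrast(X, contrast,
                                            cl.RfParams(300, m, n, 2), oob_score=True)
                errs[(m, n)] = 1.0 - clf.oob_score_
        assert errs[(chosen.mtry, chosen.nodesize)] == min(errs.values())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cl.tune_rf(np.ones((10, 2)), [], [1], 50, 0)


class TestStability:
    def test_same_params_deterministic(self):
        X = np.random.default_rng(6).normal(size=(25, 4))
        params = cl.RfParams(200, 2, 1, 6)
        a = cl.rf_dissimilarity(X, params).values
        b = cl.rf_dissimilarity(X, params).values
        np.testing.assert_array_equal(a, b)

    def test_report_bookkeeping(self):
        rng = np.random.default_rng(7)
        X, _ = blobs(rng, 15, [np.zeros(4), np.full(4, 5.0)])
        rep = cl.stability_assessment(X, cl.RfParams(150, 2, 1, 7), n_runs=2, k=2)
        assert rep.n_runs == 2
        assert len(rep.mean_abs_diff) == 2
        assert len(rep.ari_vs_reference) == 2

    def test_more_trees_shrink_run_differences(self):
        rng = np.random.default_rng(8)
        X, _ = blobs(rng, 20, [np.zeros(4), np.full(4, 5.0)])
        small = cl.stability_assessment(X, cl.RfParams(100, 2, 1, 8), n_runs=3, k=2)
        big = cl.stability_assessment(X, cl.RfParams(2000, 2, 1, 8), n_runs=3, k=2)
        assert big.mean_abs_diff.mean() < small.mean_abs_diff.mean()


class TestClassicalMds:
    def test_euclidean_distances_reconstructed_exactly(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(4, 3))
        D = squareform(pdist(pts))
        emb = cl.classical_mds(D, 3)
        np.testing.assert_allclose(squareform(pdist(emb.coords)), D, atol=1e-8)

    def test_equilateral_triangle(self):
        D = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        emb = cl.classical_mds(D, 2)
        np.testing.assert_allclose(pdist(emb.coords), 1.0, atol=1e-10)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        perm = rng.permutation(8)
        emb = cl.classical_mds(D, 3)
        emb_p = cl.classical_mds(D[np.ix_(perm, perm)], 3)
        np.testing.assert_allclose(squareform(pdist(emb_p.coords)),
                                   squareform(pdist(emb.coords))[np.ix_(perm, perm)],
                                   atol=1e-8)

    def test_eigenvalues_sorted_and_truncation_warns(self, caplog):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        emb = cl.classical_mds(D, 5)
        assert emb.coords.shape[1] <= 1
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)


class TestUpgma:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        pts = rng.normal(size=(n, 3))
        sol = cl.average_linkage(pts)
        from scipy.cluster import hierarchy
        coph_impl = squareform(hierarchy.cophenet(sol.linkage))
        coph_oracle, heights_oracle = upgma_cophenetic(squareform(pdist(pts)))
        np.testing.assert_allclose(coph_impl, coph_oracle, atol=1e-10)
        np.testing.assert_allclose(sorted(sol.linkage[:, 2]), heights_oracle, atol=1e-10)

    def test_two_points_single_merge(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        sol = cl.average_linkage(pts)
        assert sol.linkage.shape[0] == 1
        assert sol.linkage[0, 2] == pytest.approx(5.0)

    def test_duplicated_point_merges_at_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
        sol = cl.average_linkage(pts)
        assert sol.linkage[0, 2] == pytest.approx(0.0)


class TestCutTree:
    def test_extreme_cuts(self):
        pts = np.random.default_rng(11).normal(size=(10, 2))
        sol = cl.average_linkage(pts)
        assert len(np.unique(cl.cut_tree(sol, 1))) == 1
        assert len(np.unique(cl.cut_tree(sol, 10))) == 10

    def test_out_of_range_rejected(self):
        pts = np.random.default_rng(12).normal(size=(5, 2))
        sol = cl.average_linkage(pts)
        with pytest.raises(ValueError):
            cl.cut_tree(sol, 0)
        with pytest.raises(ValueError):
            cl.cut_tree(sol, 6)

    def test_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(13)
        X, labels = blobs(rng, 20, [np.zeros(3), np.full(3, 6.0),
                                    np.array([6.0, -6.0, 0.0])])
        sol = cl.average_linkage(X)
        assert adjusted_rand_score(labels, cl.cut_tree(sol, 3)) == 1.0

    def test_labels_ordered_by_cluster_size(self):
        rng = np.random.default_rng(14)
        X, _ = blobs(rng, 5, [np.zeros(2)])
        Y, _ = blobs(rng, 20, [np.full(2, 8.0)])
        sol = cl.average_linkage(np.vstack([X, Y]))
        lab = cl.cut_tree(sol, 2)
        counts = np.bincount(lab)[1:]
        assert counts[0] == 20 and counts[1] == 5
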
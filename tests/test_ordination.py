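"""Hellinger transform, PCA, RDA and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from trammelnet import (
    boat_summary,
    hellinger,
    lag1_autocorrelation_test,
    pca,
    rda,
    rda_permutation_test,
)


class TestHellinger:
    def test_closed_form_rows(self):
        out = hellinger(np.array([[4.0, 0.0], [1.0, 3.0]]))
        np.testing.assert_allclose(out[0], [1.0, 0.0])
        np.testing.assert_allclose(out[1], [0.5, np.sqrt(0.75)], atol=1e-4)

    def test_nonzero_rows_have_unit_norm(self, rng):
        mat = rng.exponential(1.0, (30, 8))
        mat[rng.random((30, 8)) < 0.5] = 0.0
        mat[3] = 0.0
        out = hellinger(mat)
        norms = np.linalg.norm(out, axis=1)
        totals = mat.sum(axis=1)
        np.testing.assert_allclose(norms[totals > 0], 1.0)
        np.testing.assert_allclose(out[3], 0.0)

    def test_not_idempotent_off_sphere(self):
        mat = np.array([[1.0, 3.0]])
        once = hellinger(mat)
        twice = hellinger(once)
        assert not np.allclose(once, twice)

    def test_dataframe_labels_preserved(self):
        df = pd.DataFrame([[1.0, 1.0]], index=["s1"], columns=["a", "b"])
        out = hellinger(df)
        assert list(out.index) == ["s1"] and list(out.columns) == ["a", "b"]

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[1.0, -0.1]]))


class TestPCA:
    def test_identical_rows_zero_eigenvalues(self):
        res = pca(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        mat = rng.normal(size=(4, 3))
        res = pca(mat)
        cov = np.cov(mat, rowvar=False)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1][: len(res.eigenvalues)]
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-10)

    def test_uncorrelated_unit_variance_columns(self, rng):
        n = 4000
        mat = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        mat = (mat - mat.mean(0)) / mat.std(0, ddof=1)
        res = pca(mat)
        np.testing.assert_allclose(res.proportion_explained, [0.5, 0.5], atol=0.05)

    def test_total_variance_decomposition(self, rng):
        mat = rng.normal(size=(20, 6))
        res = pca(mat)
        assert res.eigenvalues.sum() == pytest.approx(
            np.var(mat, axis=0, ddof=1).sum(), abs=1e-10)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_matches_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        mat = rng.normal(size=(15, 5))
        res = pca(mat)
        sk = sklearn.PCA().fit(mat)
        np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_,
                                   atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        mat = rng.normal(size=(10, 4))
        a, b = pca(mat), pca(mat.copy())
        np.testing.assert_array_equal(a.scores, b.scores)
        for k in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, k])), k] > 0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pca(np.array([[1.0, 2.0]]))


class TestBoatSummary:
    def test_single_sample_group(self):
        res = pca(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]))
        out = boat_summary(res, {0: "a", 1: "b", 2: "b"})
        np.testing.assert_allclose(out["a"]["centroid"], res.scores[0, :2])
        assert out["a"]["hull"].shape[0] == 1

    def test_square_hull_and_centroid(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0],
                        [0.5, 0.5]])
        from trammelnet.ordination import OrdinationResult
        res = OrdinationResult(scores=pts, eigenvalues=np.array([1.0, 1.0]),
                               proportion_explained=np.array([0.5, 0.5]),
                               loadings=np.eye(2))
        out = boat_summary(res, {i: "g" for i in range(5)})
        assert out["g"]["hull"].shape[0] == 4  # interior point excluded
        np.testing.assert_allclose(out["g"]["centroid"], [0.5, 0.5])

    def test_centroids_match_group_means(self, rng):
        mat = rng.normal(size=(30, 3))
        res = pca(mat)
        groups = {i: f"g{i % 3}" for i in range(30)}
        out = boat_summary(res, groups)
        for g in ("g0", "g1", "g2"):
            rows = [i for i in range(30) if groups[i] == g]
            np.testing.assert_allclose(out[g]["centroid"],
                                       res.scores[rows, :2].mean(axis=0))

    def test_unmapped_sample_rejected(self):
        res = pca(np.eye(3))
        with pytest.raises(ValueError):
            boat_summary(res, {0: "a", 1: "a"})


class TestRDA:
    def test_hand_computed_toy(self):
        res = rda(np.array([0.0, 1.0, 2.0, 3.0]), ["A", "A", "B", "B"])
        n = 4
        assert res.constrained_variance * (n - 1) == pytest.approx(4.0)
        assert res.residual_variance * (n - 1) == pytest.approx(1.0)
        assert res.F == pytest.approx(8.0)
        assert (res.df1, res.df2) == (1, 2)

    def test_identical_groups_zero_f(self, rng):
        block = rng.normal(size=(3, 4))
        Y = np.vstack([block, block])
        res = rda(Y, ["A"] * 3 + ["B"] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_hat_matrix_oracle(self, rng):
        Y = rng.normal(size=(12, 5))
        labels = list(rng.choice(["a", "b", "c"], 12))
        levels = sorted(set(labels))
        X = np.column_stack([[1.0 if lab == lev else 0.0 for lab in labels]
                             for lev in levels])
        yc = Y - Y.mean(0)
        hat = X @ np.linalg.pinv(X.T @ X) @ X.T
        fitted = hat @ yc
        res = rda(Y, labels)
        assert res.constrained_variance == pytest.approx(
            float((fitted ** 2).sum()) / 11, abs=1e-10)
        assert res.residual_variance == pytest.approx(
            float(((yc - fitted) ** 2).sum()) / 11, abs=1e-10)

    def test_variance_decomposition_matches_pca_total(self, rng):
        Y = hellinger(rng.exponential(1.0, (15, 6)))
        labels = ["a"] * 8 + ["b"] * 7
        res = rda(Y, labels)
        total = pca(Y).eigenvalues.sum()
        assert res.total_variance == pytest.approx(total, abs=1e-8)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            rda(np.eye(3), ["a", "a", "a"])


class TestRDAPermutation:
    def test_minimum_attainable_p(self, rng):
        Y = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])
        labels = ["A"] * 20 + ["B"] * 20
        res = rda_permutation_test(Y, labels, n_perm=999, seed=5)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_type_one_error_calibration(self, rng):
        """Null rejection rate at alpha=0.05 over 200 replicates."""
        rejections = 0
        for rep in range(200):
            Y = rng.normal(size=(16, 3))
            labels = ["A"] * 8 + ["B"] * 8
            res = rda_permutation_test(Y, labels, n_perm=99, seed=rep)
            rejections += res.p_perm <= 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_label_name_invariance(self, rng):
        Y = rng.normal(size=(12, 3))
        labels = ["A"] * 6 + ["B"] * 6
        renamed = ["X" if lab == "A" else "Y" for lab in labels]
        r1 = rda_permutation_test(Y, labels, n_perm=199, seed=3)
        r2 = rda_permutation_test(Y, renamed, n_perm=199, seed=3)
        assert r1.p_perm == r2.p_perm and r1.F == pytest.approx(r2.F)

    def test_n_perm_floor(self, rng):
        with pytest.raises(ValueError):
            rda_permutation_test(rng.normal(size=(8, 2)), ["a"] * 4 + ["b"] * 4,
                                 n_perm=50)

    def test_degenerate_matrix_warns(self):
        Y = np.ones((8, 2))
        with pytest.warns(UserWarning):
            res = rda_permutation_test(Y, ["a"] * 4 + ["b"] * 4, n_perm=99)
        assert res.p_perm == 1.0

    def test_seed_reproducibility(self, rng):
        Y = rng.normal(size=(10, 2))
        labels = ["a"] * 5 + ["b"] * 5
        assert (rda_permutation_test(Y, labels, 199, seed=9).p_perm
                == rda_permutation_test(Y, labels, 199, seed=9).p_perm)


class TestLag1Autocorrelation:
    def test_trend_detected(self):
        stat, p = lag1_autocorrelation_test({"n1": np.arange(10.0)},
                                            n_perm=199, seed=1)
        assert stat > 0.9
        assert p < 0.05

    def test_null_calibration(self, rng):
        rejections = 0
        for rep in range(200):
            series = {f"n{j}": rng.normal(size=8) for j in range(4)}
            _stat, p = lag1_autocorrelation_test(series, n_perm=99, seed=rep)
            rejections += p <= 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_constant_series_flagged(self):
        with pytest.warns(UserWarning):
            stat, p = lag1_autocorrelation_test({"n1": [1.0] * 5}, n_perm=99, seed=0)
        assert np.isnan(stat) and p == 1.0

    def test_short_nets_rejected(self):
        with pytest.raises(ValueError):
            lag1_autocorrelation_test({"n1": [1.0, 2.0]}, n_perm=99, seed=0)
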
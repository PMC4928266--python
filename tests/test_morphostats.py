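"""Multivariate statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paridmorph import morphostats as ms


class TestLogTransform:
    def test_known_values(self):
        df = pd.DataFrame({"a": [np.e, 1.0]})
        out = ms.log_transform(df)
        assert out["a"].tolist() == pytest.approx([1.0, 0.0])

    def test_zero_rejected_with_names(self):
        df = pd.DataFrame({"culmen": [1.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="culmen"):
            ms.log_transform(df)

    def test_missing_propagates(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        assert np.isnan(ms.log_transform(df)["a"].iloc[1])


class TestStandardize:
    def test_unit_variance_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert ms.standardize(df)["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zero_mean(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, (20, 4)))
        out = ms.standardize(df)
        assert np.abs(out.mean()).max() < 1e-12
        assert out.std(ddof=1).to_numpy() == pytest.approx(np.ones(4))

    def test_constant_column_error(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            ms.standardize(df)


class TestSpeciesMeans:
    def test_mean_and_order(self):
        df = pd.DataFrame(
            {"t1": [1.0, 3.0, 5.0], "t2": [3.0, 5.0, 7.0]}, index=["a", "b", "c"]
        )
        out = ms.species_means(df, ["zz", "zz", "aa"])
        assert list(out.index) == ["zz", "aa"]  # first appearance order
        assert out.loc["zz"].tolist() == [2.0, 4.0]
        assert out.loc["aa"].tolist() == [5.0, 7.0]

    def test_incomplete_rows_dropped(self):
        df = pd.DataFrame({"t": [1.0, np.nan, 5.0]})
        out = ms.species_means(df, ["x", "x", "x"])
        assert out.loc["x", "t"] == 3.0

    def test_species_without_complete_rows_errors(self):
        df = pd.DataFrame({"t": [1.0, np.nan]})
        with pytest.raises(ValueError, match="y"):
            ms.species_means(df, ["x", "y"])


class TestPca:
    def test_perfect_line(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [0.0, 1, 2, 3]})
        res = ms.pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 5)))
        res = ms.pca(df)
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.variance_fraction) <= 1e-12).all()

    @pytest.mark.parametrize("mode", ["covariance", "correlation"])
    def test_reconstruction_identity(self, rng, mode):
        """With all components retained, scores x loadings^T reproduce the
        centered (and scaled, in correlation mode) data."""
        df = pd.DataFrame(rng.normal(size=(6, 4)))
        res = ms.pca(df, mode=mode)
        X = df.to_numpy() - df.to_numpy().mean(axis=0)
        if mode == "correlation":
            X = X / df.std(ddof=1).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - X).max() < 1e-9
        # and scores = data x loadings
        assert np.abs(X @ res.loadings.to_numpy() - res.scores.to_numpy()).max() < 1e-9

    def test_sign_convention(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 3)))
        res = ms.pca(df)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestOneWayAnova:
    def test_hand_computed_example(self):
        res = ms.one_way_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(13.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_means_give_zero_F(self):
        res = ms.one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0)

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 8, k)
            vals = [rng.normal(g, 1.0, n) for g, n in enumerate(sizes)]
            groups = np.concatenate([[f"g{i}"] * n for i, n in enumerate(sizes)])
            res = ms.one_way_anova(np.concatenate(vals), groups)
            ref = stats.f_oneway(*vals)
            assert res.F == pytest.approx(ref.statistic, rel=1e-9)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_p_decreases_with_separation(self, rng):
        noise = rng.normal(0, 1.0, 20)
        ps = []
        for delta in (0.5, 1.5, 3.0, 6.0):
            vals = noise + np.repeat([0.0, delta], 10)
            ps.append(ms.one_way_anova(vals, ["a"] * 10 + ["b"] * 10).p)
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_all_singletons_error(self):
        with pytest.raises(ValueError):
            ms.one_way_anova([1.0, 2.0], ["a", "b"])


class TestCva:
    def test_identity_within_covariance_gives_euclidean_mahalanobis(self):
        """Groups built so the pooled within-group covariance is exactly the
        identity; Mahalanobis then equals the Euclidean distance of means."""
        p = 3
        m1 = np.zeros(p)
        m2 = np.array([2.0, 1.0, -1.0])
        rows, groups = [], []
        for m, g in ((m1, "a"), (m2, "b")):
            for i in range(p):
                e = np.zeros(p)
                e[i] = 1.0
                rows.append(m + e)
                rows.append(m - e)
                groups += [g, g]
        # each group: 2p rows as +/- pairs along each axis, so the within SS
        # is 2 per axis per group and the pooled W = 4/(4p-2) x identity
        rows = np.array(rows)
        w_factor = 4.0 / (4 * p - 2)
        res = ms.cva(pd.DataFrame(rows), groups)
        expected = np.linalg.norm(m1 - m2) / np.sqrt(w_factor)
        assert res.mahalanobis.values[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_matrix_properties(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        groups = ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10
        res = ms.cva(df, groups)
        M = res.mahalanobis.values
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)
        assert (res.axis_eigenvalues >= 0).all()

    def test_invariance_under_invertible_linear_transform(self, rng):
        df = pd.DataFrame(rng.normal(size=(24, 4)))
        groups = np.repeat(["a", "b", "c"], 8)
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        res1 = ms.cva(df, groups)
        res2 = ms.cva(pd.DataFrame(df.to_numpy() @ A), groups)
        assert np.abs(res1.mahalanobis.values - res2.mahalanobis.values).max() < 1e-6

    def test_shuffling_labels_reduces_separation(self, rng):
        X = np.vstack([rng.normal(i * 2, 1.0, (8, 3)) for i in range(3)])
        groups = np.repeat(["a", "b", "c"], 8)
        base = ms.cva(pd.DataFrame(X), groups).axis_eigenvalues.sum()
        worse = 0
        for _ in range(100):
            shuffled = rng.permutation(groups)
            if len(set(shuffled[:8])) == 1:
                continue
            s = ms.cva(pd.DataFrame(X), shuffled).axis_eigenvalues.sum()
            worse += s < base
        assert worse >= 95

    def test_singleton_group_errors(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            ms.cva(df, ["a", "a", "a", "a", "b"])


class TestProcrustesAnova:
    def test_univariate_embedding_equals_classical_F(self, rng):
        vals = rng.normal(0, 1, 18) + np.repeat([0.0, 1.0, 2.0], 6)
        groups = np.repeat(["a", "b", "c"], 6)
        classical = ms.one_way_anova(vals, groups)
        shape_res, _ = ms.procrustes_anova(
            vals.reshape(-1, 1), np.ones(18), groups, shape_dim=1
        )
        assert shape_res.F == pytest.approx(classical.F, rel=1e-12)
        assert shape_res.p == pytest.approx(classical.p, rel=1e-9)

    def test_shape_dim_scales_df(self, rng):
        X = rng.normal(size=(12, 10))  # 5 2-D landmarks -> shape dim 6
        groups = np.repeat(["a", "b"], 6)
        shape_res, _ = ms.procrustes_anova(X, np.ones(12), groups)
        assert shape_res.df_between == 1 * 6
        assert shape_res.df_within == 10 * 6

    def test_zero_within_variation_is_infinite_F(self):
        X = np.repeat([[0.0], [1.0]], 3, axis=0)
        with pytest.warns(UserWarning, match="infinite"):
            shape_res, _ = ms.procrustes_anova(
                X, np.ones(6), ["a"] * 3 + ["b"] * 3, shape_dim=1
            )
        assert np.isinf(shape_res.F)
        assert shape_res.p == 0.0

    def test_rotation_invariance_of_shape_F(self, rng):
        """Rotating the whole aligned coordinate frame leaves F unchanged."""
        X = rng.normal(size=(12, 8))
        groups = np.repeat(["a", "b"], 6)
        theta = 0.7
        R2 = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        R = np.kron(np.eye(4), R2)
        f1, _ = ms.procrustes_anova(X, np.ones(12), groups)
        f2, _ = ms.procrustes_anova(X @ R, np.ones(12), groups)
        assert f1.F == pytest.approx(f2.F, rel=1e-9)


class TestOls:
    def test_exact_line(self):
        x = np.arange(5, dtype=float)
        res = ms.ols_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        res = ms.ols_regression(np.ones(5), np.arange(5.0))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 20))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            res = ms.ols_regression(y, x)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert res.intercept == pytest.approx(beta[0], abs=1e-9)
            assert res.slope == pytest.approx(beta[1], abs=1e-9)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            ms.ols_regression(np.arange(5.0), np.ones(5))


class TestSizeCorrect:
    def test_proportional_trait_gives_zero_residuals(self, rng):
        w = rng.normal(3, 0.4, 12)
        df = pd.DataFrame({"t": 0.33 * w + 1.2})
        out = ms.size_correct(df, w)
        assert np.abs(out["t"]).max() < 1e-12

    def test_residual_orthogonality(self, rng):
        w = rng.normal(3, 0.4, 30)
        df = pd.DataFrame({"t": 0.3 * w + rng.normal(0, 0.1, 30)})
        out = ms.size_correct(df, w)
        assert out["t"].mean() == pytest.approx(0.0, abs=1e-12)
        assert abs(np.corrcoef(out["t"], w)[0, 1]) < 1e-9
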
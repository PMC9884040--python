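import numpy as np
import pandas as pd
import pytest

from phyloshape.pgls import (
    CollinearityError,
    ModelSpec,
    bootstrap_cis,
    classify_allometry,
    compare_group_slopes,
    fit_pgls,
    group_mean_comparison,
    identity_family,
    per_group_slopes,
    size_correct,
    type2_anova,
)
from phyloshape.phylo import CovarianceFamily
from phyloshape.simulate import simulate_tree


def dense_gls_oracle(X, y, V):
    """Closed-form GLS via explicit matrix inversion (independent route)."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    rss = float(resid @ Vi @ resid)
    n, p = X.shape
    se = np.sqrt(np.diag(np.linalg.inv(XtVi @ X)) * rss / (n - p))
    sign, logdet = np.linalg.slogdet(V)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(rss / n) + n + logdet)
    return beta, se, ll


class TestModelSpec:
    def test_formula_expansion(self):
        spec = ModelSpec.from_formula("y ~ x * g")
        assert spec.terms == ["x", "g", "x:g"]

    def test_response_not_predictor(self):
        with pytest.raises(ValueError):
            ModelSpec(response="y", terms=["y"])


class TestFitPGLS:
    def test_star_tree_equals_ols(self, regression_data):
        fam = identity_family(regression_data.index)
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, fam, lam=1.0)
        import statsmodels.api as sm

        ols = sm.OLS(regression_data["y"], sm.add_constant(regression_data["x"])).fit()
        assert fit.coefficients["(Intercept)"] == pytest.approx(ols.params["const"], rel=1e-8)
        assert fit.coefficients["x"] == pytest.approx(ols.params["x"], rel=1e-8)

    @pytest.mark.parametrize("seed,lam", [(0, 1.0), (1, 0.5), (2, 0.1)])
    def test_matches_dense_oracle_fixed_lambda(self, seed, lam):
        tree = simulate_tree(5, seed=seed)
        fam = CovarianceFamily.from_tree(tree)
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {"x": rng.standard_normal(5), "y": rng.standard_normal(5)}, index=fam.taxa
        )
        fit = fit_pgls(ModelSpec("y", ["x"]), df, fam, lam=lam)
        X = np.column_stack([np.ones(5), df["x"]])
        beta, se, ll = dense_gls_oracle(X, df["y"].to_numpy(), fam.matrix(lam).V)
        np.testing.assert_allclose(fit.beta, beta, rtol=1e-8)
        np.testing.assert_allclose(fit.se, se, rtol=1e-8)
        assert fit.log_likelihood == pytest.approx(ll, rel=1e-8)

    def test_residual_gls_normal_equations(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        Vi = np.linalg.inv(small_family.matrix(fit.lambda_hat).V)
        score = fit.X.T @ Vi @ fit.residuals.to_numpy()
        np.testing.assert_allclose(score, 0.0, atol=1e-8)

    def test_lambda_beats_grid(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        from phyloshape.pgls import _GLSData

        data = _GLSData(small_family, fit.X, fit.y)
        grid_best = max(float(data.loglik(l)[0]) for l in np.linspace(0, 1, 101))
        assert fit.log_likelihood >= grid_best - 1e-6

    def test_collinear_design_rejected(self, small_family):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        df = pd.DataFrame(
            {"x": x, "x2": 2 * x, "y": rng.standard_normal(12)}, index=small_family.taxa
        )
        with pytest.raises(CollinearityError, match="x2"):
            fit_pgls(ModelSpec("y", ["x", "x2"]), df, small_family)

    def test_missing_species_rejected(self, regression_data, small_family):
        with pytest.raises(KeyError):
            fit_pgls(ModelSpec("y", ["x"]), regression_data.iloc[:-1], small_family)

    def test_adjusted_r2_upper_bound(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        assert fit.adjusted_r2 <= 1.0


class TestType2Anova:
    def test_orthogonal_balanced_equals_sequential(self):
        # balanced 2-level factor, continuous predictor orthogonal to it
        n = 16
        g = np.repeat(["a", "b"], n // 2)
        x = np.tile([-1.5, -0.5, 0.5, 1.5], 4)
        rng = np.random.default_rng(5)
        y = 0.3 * x + (g == "b") * 0.4 + rng.standard_normal(n) * 0.3
        taxa = [f"t{i}" for i in range(n)]
        df = pd.DataFrame({"x": x, "g": g, "y": y}, index=taxa)
        fam = identity_family(taxa)
        fit = fit_pgls(ModelSpec("y", ["x", "g"]), df, fam, lam=1.0)
        tab = type2_anova(fit)
        # sequential oracle by nested OLS refits
        X0 = np.ones((n, 1))
        X1 = np.column_stack([X0, x])
        X2 = np.column_stack([X1, (g == "b").astype(float)])

        def rss(X):
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return float(r @ r)

        assert tab.loc["x", "ss"] == pytest.approx(rss(X0) - rss(X1), rel=1e-8)
        assert tab.loc["g", "ss"] == pytest.approx(rss(X1) - rss(X2), rel=1e-8)

    def test_unbalanced_matches_nested_refit_oracle(self):
        n = 14
        rng = np.random.default_rng(6)
        g = np.array(["a"] * 4 + ["b"] * 10)
        x = rng.standard_normal(n) + (g == "b") * 0.8  # correlated with g
        y = 0.5 * x + (g == "b") * 0.3 + rng.standard_normal(n) * 0.4
        taxa = [f"t{i}" for i in range(n)]
        df = pd.DataFrame({"x": x, "g": g, "y": y}, index=taxa)
        fam = identity_family(taxa)
        fit = fit_pgls(ModelSpec("y", ["x", "g"]), df, fam, lam=1.0)
        tab = type2_anova(fit)

        d = (g == "b").astype(float)

        def rss(*cols):
            X = np.column_stack([np.ones(n), *cols])
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ b
            return float(r @ r)

        # Type II: each term against the model with the other main effect
        assert tab.loc["x", "ss"] == pytest.approx(rss(d) - rss(d, x), rel=1e-8)
        assert tab.loc["g", "ss"] == pytest.approx(rss(x) - rss(x, d), rel=1e-8)

    def test_marginality_violation(self, small_family):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(12),
                "g": ["a", "b"] * 6,
                "y": rng.standard_normal(12),
            },
            index=small_family.taxa,
        )
        fit = fit_pgls(ModelSpec("y", ["x", "x:g"]), df, small_family, lam=0.5)
        with pytest.raises(ValueError, match="marginality"):
            type2_anova(fit)


class TestBootstrap:
    def test_zero_noise_degenerate(self, small_family):
        x = np.linspace(-1, 1, 12)
        df = pd.DataFrame({"x": x, "y": 2.0 + 0.7 * x}, index=small_family.taxa)
        fit = fit_pgls(ModelSpec("y", ["x"]), df, small_family, lam=0.5)
        boot = bootstrap_cis(fit, n_reps=50, seed=0)
        lo, hi = boot.ci["x"]
        assert lo == pytest.approx(0.7, abs=1e-8)
        assert hi == pytest.approx(0.7, abs=1e-8)

    def test_seed_determinism(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        b1 = bootstrap_cis(fit, n_reps=100, seed=42)
        b2 = bootstrap_cis(fit, n_reps=100, seed=42)
        np.testing.assert_array_equal(b1.replicates, b2.replicates)
        assert b1.ci == b2.ci

    def test_different_seeds_differ(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        b1 = bootstrap_cis(fit, n_reps=100, seed=1)
        b2 = bootstrap_cis(fit, n_reps=100, seed=2)
        assert not np.array_equal(b1.replicates, b2.replicates)

    def test_residual_method_runs(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family)
        boot = bootstrap_cis(fit, n_reps=100, seed=3, method="residual")
        assert boot.replicates.shape[1] == 100


class TestAllometryCall:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.06, 0.19), "positive"),
            ((-0.15, -0.06), "negative"),
            ((-0.08, 0.03), "not_significant"),
        ],
    )
    def test_calls(self, ci, expected):
        assert classify_allometry(sum(ci) / 2, ci).call == expected

    def test_zero_width_ci_at_isometry(self):
        assert classify_allometry(0.0, (0.0, 0.0)).call == "not_significant"

    def test_nonzero_isometric_slope(self):
        assert classify_allometry(0.5, (0.2, 0.8), isometric_slope=1.0).call == "negative"

    def test_invalid_ci(self):
        with pytest.raises(ValueError):
            classify_allometry(0.0, (1.0, -1.0))


class TestPerGroupSlopes:
    def _interaction_fit(self, slopes_by_group, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        groups = list(slopes_by_group)
        n_per = 10
        rows = []
        for g in groups:
            x = rng.standard_normal(n_per)
            y = slopes_by_group[g] * x + rng.standard_normal(n_per) * noise
            for xi, yi in zip(x, y):
                rows.append({"g": g, "x": xi, "y": yi})
        df = pd.DataFrame(rows, index=[f"t{i}" for i in range(n_per * len(groups))])
        fam = identity_family(df.index)
        fit = fit_pgls(ModelSpec.from_formula("y ~ x * g"), df, fam, lam=1.0)
        return fit, df

    def test_zero_interaction_common_slope(self):
        fit, _ = self._interaction_fit({"a": 0.5, "b": 0.5})
        slopes = per_group_slopes(fit)
        assert slopes["a"] == pytest.approx(slopes["b"], abs=1e-8)

    def test_matches_within_group_ols(self):
        fit, df = self._interaction_fit({"a": 0.3, "b": -0.4, "c": 1.1}, noise=0.2)
        slopes = per_group_slopes(fit)
        for g, sub in df.groupby("g"):
            ols_slope = np.polyfit(sub["x"], sub["y"], 1)[0]
            assert slopes[g] == pytest.approx(ols_slope, rel=1e-6)

    def test_requires_interaction(self, regression_data, small_family):
        fit = fit_pgls(ModelSpec("y", ["x"]), regression_data, small_family, lam=1.0)
        with pytest.raises(ValueError, match="interaction"):
            per_group_slopes(fit)


class TestCompareGroupSlopes:
    def test_identical_groups_not_flagged(self):
        out = compare_group_slopes(
            {"a": 0.1, "b": 0.1}, {"a": (0.0, 0.2), "b": (0.0, 0.2)}
        )
        assert not out["different_two_way"].any()

    def test_separated_groups_flagged(self):
        out = compare_group_slopes(
            {"a": 0.3, "b": -0.3}, {"a": (0.25, 0.35), "b": (-0.35, -0.25)}
        )
        assert out["different_two_way"].all()

    def test_one_sided_exclusion_not_two_way(self):
        out = compare_group_slopes(
            {"a": 0.1, "b": 0.3}, {"a": (0.0, 0.2), "b": (-0.5, 0.5)}
        )
        row = out.iloc[0]
        assert not row["different_two_way"]
        assert row["different_one_way"]


class TestSizeCorrect:
    def test_exact_linear_zero_residuals(self, small_family):
        size = np.linspace(1, 2, 12)
        df = pd.DataFrame({"size": size, "trait": 3.0 + 2.0 * size}, index=small_family.taxa)
        resid, fit = size_correct(df, "trait", "size", small_family)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)

    def test_residual_orthogonality(self, small_family):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {"size": rng.standard_normal(12), "trait": rng.standard_normal(12)},
            index=small_family.taxa,
        )
        resid, fit = size_correct(df, "trait", "size", small_family)
        Vi = np.linalg.inv(small_family.matrix(fit.lambda_hat).V)
        np.testing.assert_allclose(fit.X.T @ Vi @ resid.to_numpy(), 0.0, atol=1e-8)


class TestGroupMeanComparison:
    def test_identical_constant_no_flags(self, small_family):
        vals = pd.Series(1.0, index=small_family.taxa)
        groups = pd.Series(["a", "b"] * 6, index=small_family.taxa)
        out = group_mean_comparison(vals, groups, small_family, n_reps=50, seed=0)
        assert out.means["a"] == pytest.approx(out.means["b"], abs=1e-10)
        assert not out.flags["different_two_way"].any()

    def test_shifted_group_flagged(self):
        tree = simulate_tree(20, seed=13)
        fam = CovarianceFamily.from_tree(tree)
        rng = np.random.default_rng(13)
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=fam.taxa)
        vals = pd.Series(rng.standard_normal(20) * 0.1, index=fam.taxa)
        vals[groups == "b"] += 10.0
        out = group_mean_comparison(vals, groups, fam, n_reps=200, seed=1)
        assert out.flags["different_two_way"].all()

    def test_singleton_group_warns(self, small_family):
        vals = pd.Series(np.arange(12, dtype=float), index=small_family.taxa)
        groups = pd.Series(["a"] * 11 + ["b"], index=small_family.taxa)
        out = group_mean_comparison(vals, groups, small_family, n_reps=50, seed=2)
        assert out.warning is not None and "b" in out.warning
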
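import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oxiscan as ox
from oxiscan.errors import (
    CohortSizeError,
    DegenerateDataError,
    NestingError,
    RankError,
    ValidationError,
)
from oxiscan.lmm import build_design

SPEC = ox.ModelSpec(response="y", terms=("x", "purity"), group="g")

# Reference values computed with R 4.3.3 / lme4 1.1-37 on the exact
# dataset produced by the grouped_frame fixture (seed 42).
LME4_ML = {
    "beta": [0.583268, 0.494475, -0.066371],
    "s2_group": 1.172701, "s2_resid": 0.8904082, "loglik": -286.1954,
    "bse": [0.452352, 0.067808, 0.346219],
}
LME4_REML = {
    "beta": [0.582512, 0.494181, -0.065693],
    "s2_group": 1.347573, "s2_resid": 0.8997195, "loglik": -288.0988,
    "bse": [0.476551, 0.068163, 0.348054],
}


class TestFit:
    @pytest.mark.parametrize("method,ref", [("ML", LME4_ML),
                                            ("REML", LME4_REML)])
    def test_matches_lme4_reference(self, grouped_frame, method, ref):
        fit = ox.fit_lmm(grouped_frame, SPEC, method=method)
        np.testing.assert_allclose(fit.params.to_numpy(), ref["beta"],
                                   atol=2e-5)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref["bse"], atol=2e-5)
        assert fit.sigma2_group == pytest.approx(ref["s2_group"], abs=1e-4)
        assert fit.sigma2_resid == pytest.approx(ref["s2_resid"], abs=1e-4)
        assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-3)
        assert fit.converged and not fit.boundary

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [0.0, 1, 0, 1],
                           "purity": [0.5] * 4, "g": ["a"] * 4})
        with pytest.raises(CohortSizeError):
            ox.fit_lmm(df, SPEC)

    @pytest.mark.parametrize("seed", range(20))
    def test_zero_group_variance_matches_ols(self, seed):
        # no planted group effect and no accidental between-group noise
        # (group means of the errors are centered): the fit must land on
        # the theta = 0 boundary, where slopes equal the OLS closed form
        rng = np.random.default_rng(seed)
        n, q = 120, 6
        g = np.arange(n) % q
        x = rng.normal(size=n)
        eps = rng.normal(0, 1.0, n)
        for k in range(q):
            eps[g == k] -= eps[g == k].mean()
        y = 2.0 + 0.7 * x + eps
        df = pd.DataFrame({"y": y, "x": x, "g": [f"g{i}" for i in g]})
        spec = ox.ModelSpec(response="y", terms=("x",), group="g")
        fit = ox.fit_lmm(df, spec, method="ML")
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.boundary
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols,
                                   atol=1e-6)

    def test_sampling_noise_variance_stays_near_ols(self):
        # uncentered errors under a true zero group variance: the fitted
        # variance may be small but positive; slopes stay near OLS
        rng = np.random.default_rng(1)
        n = 120
        x = rng.normal(size=n)
        y = 2.0 + 0.7 * x + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"y": y, "x": x,
                           "g": [f"g{i % 6}" for i in range(n)]})
        spec = ox.ModelSpec(response="y", terms=("x",), group="g")
        fit = ox.fit_lmm(df, spec, method="ML")
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ols,
                                   atol=0.05)

    def test_group_relabel_invariance(self, grouped_frame):
        fit1 = ox.fit_lmm(grouped_frame, SPEC)
        relabeled = grouped_frame.copy()
        relabeled["g"] = relabeled["g"].map(
            lambda s: f"zz_{9 - int(s[1:])}")
        fit2 = ox.fit_lmm(relabeled, SPEC)
        np.testing.assert_allclose(fit1.params.to_numpy(),
                                   fit2.params.to_numpy(), atol=1e-8)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_row_permutation_invariance(self, grouped_frame):
        fit1 = ox.fit_lmm(grouped_frame, SPEC)
        shuffled = grouped_frame.sample(frac=1.0, random_state=3)
        fit2 = ox.fit_lmm(shuffled, SPEC)
        np.testing.assert_allclose(fit1.params.to_numpy(),
                                   fit2.params.to_numpy(), atol=1e-8)

    def test_collinear_design_rejected(self, grouped_frame):
        df = grouped_frame.copy()
        df["x2"] = 2.0 * df["x"]
        spec = ox.ModelSpec(response="y", terms=("x", "x2"), group="g")
        with pytest.raises(RankError):
            ox.fit_lmm(df, spec)

    def test_interaction_column_built(self, grouped_frame):
        df = grouped_frame.copy()
        df["z"] = (df["x"] > 0).astype(int)
        spec = ox.ModelSpec(response="y", terms=("x", "z"), group="g",
                            interactions=(("x", "z"),))
        fit = ox.fit_lmm(df, spec)
        assert "x:z" in fit.exog_names

    def test_recovery_coverage(self):
        # planted slope 0.5, tau = 1: the 95% Wald interval should cover
        # the truth in >= 90% of replicates
        covered = 0
        reps = 100
        spec = ox.ModelSpec(response="y", terms=("x",), group="g")
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n, q = 300, 10
            g = rng.integers(0, q, n)
            x = rng.normal(size=n)
            u = rng.normal(0, 1.0, q)
            y = u[g] + 0.5 * x + rng.normal(0, 1.0, n)
            df = pd.DataFrame({"y": y, "x": x,
                               "g": [f"g{i}" for i in g]})
            ci = ox.fit_lmm(df, spec).conf_int().loc["x"]
            covered += ci["lower"] <= 0.5 <= ci["upper"]
        assert covered >= 0.90 * reps


class TestLrt:
    def test_identical_models_p_one(self, grouped_frame):
        full = ox.fit_lmm(grouped_frame, SPEC)
        null = ox.fit_lmm(grouped_frame, SPEC.drop_terms("purity"))
        # statistic floored at zero when the null fits as well
        p = ox.lrt_compare(full, null)
        assert 0.0 <= p <= 1.0

    def test_zero_statistic_gives_one(self, grouped_frame):
        full = ox.fit_lmm(grouped_frame, SPEC)
        clone = ox.fit_lmm(grouped_frame, SPEC.drop_terms("x"))
        clone.loglik = full.loglik  # forces statistic 0, df 1
        assert ox.lrt_compare(full, clone) == pytest.approx(1.0)

    def test_reml_fits_rejected(self, grouped_frame):
        full = ox.fit_lmm(grouped_frame, SPEC, method="REML")
        null = ox.fit_lmm(grouped_frame, SPEC.drop_terms("x"),
                          method="REML")
        with pytest.raises(NestingError):
            ox.lrt_compare(full, null)

    def test_non_nested_rejected(self, grouped_frame):
        df = grouped_frame.copy()
        df["w"] = np.random.default_rng(0).normal(size=len(df))
        a = ox.fit_lmm(df, ox.ModelSpec("y", ("x",), "g"))
        b = ox.fit_lmm(df, ox.ModelSpec("y", ("w",), "g"))
        with pytest.raises(NestingError):
            ox.lrt_compare(a, b)

    def test_different_rows_rejected(self, grouped_frame):
        full = ox.fit_lmm(grouped_frame, SPEC)
        null = ox.fit_lmm(grouped_frame.iloc[:150],
                          SPEC.drop_terms("x"))
        with pytest.raises(NestingError):
            ox.lrt_compare(full, null)

    def test_strong_effect_tiny_p(self):
        rng = np.random.default_rng(7)
        n, q = 500, 10
        g = rng.integers(0, q, n)
        x = rng.normal(size=n)
        y = 5.0 * x + rng.normal(0, 1.0, n) + rng.normal(0, 1, q)[g]
        df = pd.DataFrame({"y": y, "x": x, "g": [f"g{i}" for i in g]})
        spec = ox.ModelSpec("y", ("x",), "g")
        full = ox.fit_lmm(df, spec)
        null = ox.fit_lmm(df, spec.drop_terms("x"))
        assert ox.lrt_compare(full, null) < 1e-6


class TestR2:
    def test_closed_form_triple(self):
        r2 = ox.nakagawa_r2((2.0, 1.0, 1.0))
        assert r2.marginal == pytest.approx(0.5)
        assert r2.conditional == pytest.approx(0.75)

    def test_zero_fixed_variance(self):
        assert ox.nakagawa_r2((0.0, 1.0, 1.0)).marginal == pytest.approx(0.0)

    def test_zero_group_variance_marginal_equals_conditional(self):
        r2 = ox.nakagawa_r2((1.3, 0.0, 0.7))
        assert r2.marginal == pytest.approx(r2.conditional)

    def test_zero_total_variance(self):
        with pytest.raises(DegenerateDataError):
            ox.nakagawa_r2((0.0, 0.0, 0.0))

    @given(st.tuples(st.floats(0, 1e3), st.floats(0, 1e3),
                     st.floats(1e-6, 1e3)))
    @settings(max_examples=200, deadline=None)
    def test_identities_on_arbitrary_components(self, comps):
        r2 = ox.nakagawa_r2(comps)
        assert 0.0 <= r2.marginal <= 1.0
        assert 0.0 <= r2.conditional <= 1.0
        assert r2.conditional >= r2.marginal - 1e-12

    def test_from_fit_matches_components(self, grouped_frame):
        fit = ox.fit_lmm(grouped_frame, SPEC)
        var_f = float(np.var(fit.fitted_fixed, ddof=1))
        direct = ox.nakagawa_r2((var_f, fit.sigma2_group, fit.sigma2_resid))
        assert ox.nakagawa_r2(fit) == direct


class TestResiduals:
    def test_values_in_unit_interval(self, grouped_frame):
        fit = ox.fit_lmm(grouped_frame, SPEC)
        diag = ox.simulated_residuals(fit, n_sim=150, seed=1)
        r = diag.residuals.to_numpy()
        assert ((r >= 0) & (r <= 1)).all()

    def test_extreme_low_observation(self, grouped_frame):
        df = grouped_frame.copy()
        df.loc[df.index[0], "y"] = -1e6  # far below anything simulated
        fit = ox.fit_lmm(df, SPEC)
        diag = ox.simulated_residuals(fit, n_sim=200, seed=0)
        assert diag.residuals.iloc[0] < 1.0 / 200

    def test_permutation_equivariance(self, grouped_frame):
        fit = ox.fit_lmm(grouped_frame, SPEC)
        diag = ox.simulated_residuals(fit, n_sim=120, seed=5)
        shuffled = grouped_frame.sample(frac=1.0, random_state=8)
        fit2 = ox.fit_lmm(shuffled, SPEC)
        diag2 = ox.simulated_residuals(fit2, n_sim=120, seed=5)
        aligned = diag2.residuals.loc[diag.residuals.index]
        np.testing.assert_allclose(diag.residuals.to_numpy(),
                                   aligned.to_numpy(), atol=1e-9)

    def test_n_sim_floor(self, grouped_frame):
        fit = ox.fit_lmm(grouped_frame, SPEC)
        with pytest.raises(ValidationError):
            ox.simulated_residuals(fit, n_sim=50)

    def test_well_specified_uniform(self, grouped_frame):
        fit = ox.fit_lmm(grouped_frame, SPEC)
        diag = ox.simulated_residuals(fit, n_sim=400, seed=2)
        assert diag.ks_pvalue > 0.05


class TestAdjustPvalues:
    def test_bonferroni_single(self):
        np.testing.assert_allclose(
            ox.adjust_pvalues([0.01], "bonferroni"), [0.01])

    def test_bonferroni_capped(self):
        np.testing.assert_allclose(
            ox.adjust_pvalues([0.3, 0.3, 0.3, 0.3], "bonferroni"), [1.0] * 4)

    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            ox.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh_fdr"),
            [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ox.adjust_pvalues([0.5, 1.5], "bonferroni")

    def test_unknown_method(self):
        with pytest.raises(ValidationError):
            ox.adjust_pvalues([0.5], "holm")

    @staticmethod
    def bh_oracle(p):
        """Independent exhaustive step-up definition of BH adjustment."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        out = np.empty(m)
        for i in range(m):
            # adj_i = min over all j with p_j >= p_i of m*p_j/rank_j
            candidates = []
            for j in range(m):
                if p[j] >= p[i] - 1e-15:
                    rank = np.sum(p <= p[j] + 1e-15)
                    candidates.append(m * p[j] / rank)
            out[i] = min(1.0, min(candidates))
        return out

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=6))
    @settings(max_examples=300, deadline=None)
    def test_bh_matches_oracle_on_grid(self, grid_values):
        p = np.array(grid_values) / 100.0
        np.testing.assert_allclose(ox.adjust_pvalues(p, "bh_fdr"),
                                   self.bh_oracle(p), atol=1e-12)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.5]
        adj = ox.adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(adj, [0.12, 0.03, 1.0])


def test_build_design_complete_cases(grouped_frame):
    df = grouped_frame.copy()
    df.loc[df.index[:5], "x"] = np.nan
    X, y, names, codes, labels, row_ids = build_design(df, SPEC)
    assert X.shape[0] == len(df) - 5
    assert names[0] == "(Intercept)"
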
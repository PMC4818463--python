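import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fptrack.models import (
    aicc,
    candidate_set,
    collinearity_diagnostics,
    fit_candidates,
    fit_mixed_model,
    generalized_vif,
    prepare_inputs,
    r2_glmm,
    rank_models,
    residual_semivariogram,
)
from fptrack.synthetic import simulate_covariate_table


def simple_table(seed=0, n_birds=8, n_per=12, sigma_bird=0.3, sigma_e=0.2, beta=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_birds):
        u = rng.normal(0, sigma_bird)
        for _ in range(n_per):
            x = {c: rng.normal() for c in (
                "ndvi_t", "d_ndvi_16", "d_ndvi_32", "mndwi_t", "d_mndwi_16", "d_mndwi_32",
                "precip_t", "d_precip_16", "d_precip_32", "temp", "elev")}
            eta = 2.0 + beta * x["d_precip_32"] + u + rng.normal(0, sigma_e)
            rows.append({"bird_id": f"b{b}", "site": ["BAR", "STR"][b % 2],
                         "mfpt_rmax_h": float(np.exp(eta)), **x})
    return pd.DataFrame(rows)


class TestPrepareInputs:
    def test_log_response(self):
        df = simple_table()
        df.loc[0, "mfpt_rmax_h"] = np.e**2
        df.loc[1, "mfpt_rmax_h"] = np.e**4
        out = prepare_inputs(df, outlier_z=np.inf)
        assert out["log_mfpt"].iloc[0] == pytest.approx(2.0)
        assert out["log_mfpt"].iloc[1] == pytest.approx(4.0)

    def test_predictors_standardised(self):
        out = prepare_inputs(simple_table())
        for col in ("ndvi_t", "d_precip_32", "temp"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_outlier_threshold(self):
        df = simple_table(seed=1)
        logs = np.log(df["mfpt_rmax_h"])
        m, s = logs.mean(), logs.std(ddof=1)
        df.loc[0, "mfpt_rmax_h"] = np.exp(m + 5 * s)   # removed
        df.loc[1, "mfpt_rmax_h"] = np.exp(m + 2.5 * s)  # retained
        out = prepare_inputs(df)
        assert len(out) <= len(df) - 1
        assert np.exp(out["log_mfpt"]).max() >= np.exp(m + 2.0 * s)

    def test_zero_variance_predictor_named(self):
        df = simple_table()
        df["elev"] = 880.0
        with pytest.raises(ValueError, match="elev"):
            prepare_inputs(df)

    def test_reference_site_reordering(self):
        out = prepare_inputs(simple_table(), reference_site="STR")
        assert out["site"].cat.categories[0] == "STR"


class TestCandidateSet:
    def test_exactly_36_specs(self):
        specs = candidate_set()
        assert len(specs) == 36
        assert [s.model_id for s in specs] == list(range(1, 37))

    def test_model_34_terms(self):
        spec = next(s for s in candidate_set() if s.model_id == 34)
        assert set(spec.terms) == {"d_ndvi_32", "d_precip_32", "site"}
        assert spec.hypothesis == "PM32"

    def test_null_model_is_intercept_only(self):
        spec = candidate_set()[-1]
        assert spec.model_id == 36 and spec.terms == ()
        assert spec.formula() == "log_mfpt ~ 1"

    def test_rm_extensions_add_site_temp_elev(self):
        by_id = {s.model_id: s for s in candidate_set()}
        for base, ext in ((12, 16), (13, 17), (14, 18), (15, 19)):
            assert set(by_id[ext].terms) == set(by_id[base].terms) | {"site", "temp", "elev"}
        for base, ext in ((20, 24), (21, 25), (22, 26), (23, 27), (28, 32), (29, 33), (30, 34), (31, 35)):
            assert set(by_id[ext].terms) == set(by_id[base].terms) | {"site"}

    def test_every_spec_unique(self):
        terms = [tuple(sorted(s.terms)) for s in candidate_set()]
        assert len(set(terms)) == 36


class TestAICc:
    def test_closed_form(self):
        assert aicc(-100.0, 5, 50) == pytest.approx(211.364, abs=5e-4)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 5, 10**9) == pytest.approx(210.0, abs=1e-6)

    def test_domain_boundary(self):
        assert np.isfinite(aicc(-10.0, 4, 6))
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestFitMixedModel:
    def test_zero_group_variance_matches_ols(self):
        # residuals demeaned within bird: the between-bird variance MLE sits
        # on the zero boundary and the mixed estimate collapses to OLS
        rng = np.random.default_rng(0)
        g, m = 10, 12
        x = rng.normal(size=g * m)
        e = rng.normal(0, 0.3, size=(g, m))
        e -= e.mean(axis=1, keepdims=True)
        y = 2.0 + 0.4 * x + e.ravel()
        data = pd.DataFrame({"bird_id": np.repeat([f"b{i}" for i in range(g)], m),
                             "log_mfpt": y, "d_precip_32": x, "site": "BAR"})
        spec = next(s for s in candidate_set() if s.model_id == 9)  # d_precip_32 single
        fit = fit_mixed_model(spec, data)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.boundary_fit
        assert fit.params["d_precip_32"] == pytest.approx(ols.params[1], abs=1e-6)

    def test_balanced_anova_method_of_moments(self):
        # balanced one-way layout: ML variance components have closed forms
        rng = np.random.default_rng(3)
        g, m = 12, 10
        u = rng.normal(0, 0.5, g)
        y = (2.0 + np.repeat(u, m) + rng.normal(0, 0.3, g * m))
        df = pd.DataFrame({"bird_id": np.repeat([f"b{i}" for i in range(g)], m),
                           "log_mfpt": y, "site": "BAR"})
        spec = next(s for s in candidate_set() if s.model_id == 36)
        fit = fit_mixed_model(spec, df)
        gm = y.reshape(g, m).mean(axis=1)
        ssw = ((y.reshape(g, m) - gm[:, None]) ** 2).sum()
        sigma_e_hat = ssw / (g * (m - 1))
        # ML between-group: var of group means (ddof=0) minus sigma_e/m
        sigma_b_ml = ((gm - gm.mean()) ** 2).mean() - sigma_e_hat / m
        assert fit.sigma2_resid == pytest.approx(sigma_e_hat, rel=5e-3)
        assert fit.sigma2_id == pytest.approx(sigma_b_ml, rel=5e-2)

    def test_matches_lme4_ml_loglik(self):
        """Independent oracle: the same ML fit in lme4 via Rscript."""
        df = simple_table(seed=4, n_birds=6, n_per=8, beta=0.5)
        data = prepare_inputs(df)
        spec = next(s for s in candidate_set() if s.model_id == 9)
        fit = fit_mixed_model(spec, data)
        csv = "/tmp/fptrack_lmm_check.csv"
        data[["log_mfpt", "d_precip_32", "bird_id"]].to_csv(csv, index=False)
        r_code = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(log_mfpt ~ d_precip_32 + (1|bird_id), data=d, REML=FALSE)
            cat(as.numeric(logLik(m)), fixef(m)["d_precip_32"], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        llf_r, beta_r = (float(v) for v in out.stdout.strip().split("\n"))
        assert fit.loglik == pytest.approx(llf_r, abs=1e-3)
        assert fit.params["d_precip_32"] == pytest.approx(beta_r, abs=1e-4)

    def test_boundary_fit_flagged_not_raised(self):
        df = simple_table(seed=5, sigma_bird=0.0)
        fit = fit_mixed_model(candidate_set()[-1], prepare_inputs(df))
        assert fit.sigma2_id >= 0.0
        assert isinstance(fit.boundary_fit, bool)

    def test_k_counts_fixed_effects_plus_two_variances(self):
        data = prepare_inputs(simple_table(seed=6))
        by_id = {s.model_id: s for s in candidate_set()}
        # model 34 with 2 sites: intercept + 2 slopes + 1 dummy + 2 variances = 6
        assert fit_mixed_model(by_id[34], data).k == 6
        assert fit_mixed_model(by_id[36], data).k == 3

    def test_irrelevant_predictor_never_lowers_loglik(self):
        data = prepare_inputs(simple_table(seed=7, beta=0.5))
        by_id = {s.model_id: s for s in candidate_set()}
        nested_pairs = [(9, 31), (36, 9), (30, 28)]
        for small, big in nested_pairs:
            f_small = fit_mixed_model(by_id[small], data)
            f_big = fit_mixed_model(by_id[big], data)
            assert f_big.loglik >= f_small.loglik - 1e-4


class TestRankingAndR2:
    def test_selection_table_invariants(self):
        data = prepare_inputs(simple_table(seed=8, beta=0.6))
        fits = fit_candidates(data)
        table = rank_models(fits)
        assert len(table) == 36
        assert table["dAICc"].iloc[0] == 0.0
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table["weight"].iloc[0] == table["weight"].max()
        assert (np.diff(table["cum_weight"]) >= -1e-12).all()

    def test_differing_nobs_rejected(self):
        data = prepare_inputs(simple_table(seed=9))
        spec = candidate_set()[-1]
        f1 = fit_mixed_model(spec, data)
        f2 = fit_mixed_model(spec, data.iloc[:-3])
        with pytest.raises(ValueError, match="n_obs"):
            rank_models([f1, f2])

    def test_scaling_invariance_of_selection(self):
        raw = simple_table(seed=10, beta=0.5)
        t1 = rank_models(fit_candidates(prepare_inputs(raw)))
        raw2 = raw.copy()
        raw2["d_precip_32"] = raw2["d_precip_32"] * 37.5 + 4.2  # affine rescale pre-z-scoring
        t2 = rank_models(fit_candidates(prepare_inputs(raw2)))
        assert t1["model_id"].tolist() == t2["model_id"].tolist()
        np.testing.assert_allclose(t1["weight"], t2["weight"], atol=1e-9)

    def test_r2_closed_form(self):
        from fptrack.models import FitResult, ModelSpec

        f = FitResult(model_id=1, spec=ModelSpec(1, ("x",), "single"), params=None, bse=None,
                      conf_int=None, sigma2_id=1.0, sigma2_resid=2.0, loglik=0.0, n_obs=10,
                      k=3, aicc=0.0, r2_marginal=1.0 / 4.0, r2_conditional=2.0 / 4.0)
        assert r2_glmm(f) == (0.25, 0.5)

    def test_null_model_marginal_zero_and_degenerate_equality(self):
        data = prepare_inputs(simple_table(seed=11, sigma_bird=0.4))
        null = fit_mixed_model(candidate_set()[-1], data)
        assert null.r2_marginal == pytest.approx(0.0, abs=1e-10)
        ols_like = fit_mixed_model(candidate_set()[8], prepare_inputs(simple_table(seed=12, sigma_bird=0.0)))
        if ols_like.sigma2_id < 1e-8:
            assert ols_like.r2_marginal == pytest.approx(ols_like.r2_conditional, abs=1e-6)


class TestDiagnostics:
    def test_orthonormal_columns_unit_kappa_and_vif(self):
        # zero-mean, mutually orthogonal harmonic columns stay orthogonal
        # after per-column standardisation: the identity case is exact
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({
            "a": np.cos(2 * np.pi * t / n),
            "b": np.sin(2 * np.pi * t / n),
            "c": np.cos(4 * np.pi * t / n),
        })
        kappa, vif = collinearity_diagnostics(X)
        assert kappa == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(vif, 1.0, atol=1e-9)

    def test_vif_closed_form_at_correlation_09(self):
        rng = np.random.default_rng(1)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        X = pd.DataFrame({"a": a, "b": b})
        _, vif = collinearity_diagnostics(X)
        assert vif["a"] == pytest.approx(1 / (1 - 0.81), abs=0.05)

    def test_duplicated_column_flags_infinite(self):
        x = np.random.default_rng(2).normal(size=50)
        kappa, _ = collinearity_diagnostics(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(kappa)

    def test_generalized_vif_groups(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=["x", "d1", "d2", "z"])
        gvif = generalized_vif(X, {"x": ["x"], "cat": ["d1", "d2"], "z": ["z"]})
        assert (gvif > 0.9).all() and (gvif < 1.2).all()

    def test_semivariogram_constant_residuals(self):
        rng = np.random.default_rng(4)
        sv = residual_semivariogram(np.full(30, 1.7), rng.uniform(0, 1000, (30, 2)), n_bins=5)
        assert np.nanmax(sv.gamma) == 0.0
        assert sv.pair_counts.sum() == 30 * 29 // 2

    def test_semivariogram_iid_flat_at_sigma2(self):
        rng = np.random.default_rng(5)
        n, sigma = 500, 1.3
        resid = rng.normal(0, sigma, n)
        sv = residual_semivariogram(resid, rng.uniform(0, 10_000, (n, 2)), n_bins=8)
        # judge only bins carrying a meaningful share of pairs (the farthest
        # corner-to-corner bins of a uniform square hold a handful of pairs)
        good = sv.pair_counts > 0.05 * sv.pair_counts.sum()
        assert good.sum() >= 4
        assert np.all(np.abs(sv.gamma[good] - sigma**2) < 0.2 * sigma**2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            residual_semivariogram(np.array([1.0]), np.array([[0.0, 0.0]]))
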
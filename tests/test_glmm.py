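"""Mixed-model engine: oracles, invariances and inference helpers."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from stressborn.glmm import (
    GlmmError,
    ModelSpec,
    brute_force_loglik,
    fit_glmm,
    laplace_loglik,
    likelihood_ratio_test,
    marginal_predict,
    wald_test,
)

from conftest import make_binomial_instance


@pytest.mark.parametrize("family", ["binomial", "poisson"])
def test_pinned_zero_variance_matches_glm(family, rng):
    """With both variance components pinned to 0 the fit collapses to an
    ordinary GLM; statsmodels is the independent IRLS oracle."""
    n = 300
    ids = rng.integers(0, 40, n)
    reg = rng.integers(0, 4, n)
    x = rng.normal(size=n)
    if family == "binomial":
        y = (rng.random(n) < expit(-0.3 + 0.7 * x)).astype(int)
        sm_fam = sm.families.Binomial()
    else:
        y = rng.poisson(np.exp(0.1 + 0.4 * x))
        sm_fam = sm.families.Poisson()
    df = pd.DataFrame({"y": y, "x": x, "id": ids, "region": reg})
    spec = ModelSpec("y ~ x", ("id", "region"), family)
    fit = fit_glmm(spec, df, var_fixed={"id": 0.0, "region": 0.0})
    oracle = sm.GLM(df["y"], sm.add_constant(df["x"]), family=sm_fam).fit()
    np.testing.assert_allclose(fit.params, oracle.params.values, atol=1e-3)
    assert abs(fit.loglik - oracle.llf) < 1e-4


def test_gaussian_balanced_oneway_closed_form(rng):
    """Balanced one-way Gaussian design: ML variance components have a closed
    form (within part SSW/(N-k); group-mean variance Sum(gbar-gbar..)^2/k)."""
    k, m = 15, 8
    ids = np.repeat(np.arange(k), m)
    y = 2.0 + rng.normal(0, 0.8, k)[ids] + rng.normal(0, 1.1, k * m)
    df = pd.DataFrame({"y": y, "id": ids})
    fit = fit_glmm(ModelSpec("y ~ 1", ("id",), "gaussian"), df)
    gmeans = df.groupby("id")["y"].mean().to_numpy()
    ssw = float(((y - gmeans[ids]) ** 2).sum())
    s2e = ssw / (k * m - k)
    v_between = float(((gmeans - gmeans.mean()) ** 2).mean())
    s2b = v_between - s2e / m
    assert abs(fit.scale - s2e) < 1e-6
    assert abs(fit.vcomp["id"] - s2b) < 1e-6


def test_gaussian_matches_mixedlm_ml(rng):
    ids = np.repeat(np.arange(12), 6)
    x = rng.normal(size=len(ids))
    y = 1.5 + 0.4 * x + rng.normal(0, 0.7, 12)[ids] + rng.normal(0, 1.0, len(ids))
    df = pd.DataFrame({"y": y, "x": x, "id": ids})
    fit = fit_glmm(ModelSpec("y ~ x", ("id",), "gaussian"), df)
    oracle = sm.MixedLM.from_formula("y ~ x", groups="id", data=df).fit(reml=False)
    np.testing.assert_allclose(fit.params, oracle.fe_params.values, atol=1e-5)
    assert abs(fit.loglik - oracle.llf) < 1e-5


def test_laplace_vs_brute_force_at_fixed_params(rng):
    """The Laplace approximation tracks dense quadrature on small instances."""
    for _ in range(10):
        sd = rng.uniform(0.3, 0.8)
        df = make_binomial_instance(rng, 6, 5, sd=sd)
        spec = ModelSpec("y ~ x", ("id",), "binomial")
        params = {"beta": np.array([0.2, 0.5]), "variances": {"id": sd ** 2}}
        lap = laplace_loglik(spec, df, params)
        brute = brute_force_loglik(spec, df, params)
        assert abs(lap - brute) <= 0.05


def test_brute_force_sigma_zero_is_exact_glm_loglik(rng):
    df = make_binomial_instance(rng, 5, 4)
    spec = ModelSpec("y ~ x", ("id",), "binomial")
    beta = np.array([0.1, 0.4])
    brute = brute_force_loglik(spec, df, {"beta": beta, "variances": {"id": 0.0}})
    eta = beta[0] + beta[1] * df["x"].to_numpy()
    ll = float(np.sum(df["y"] * eta - np.log1p(np.exp(eta))))
    assert abs(brute - ll) < 1e-10


def test_brute_force_gaussian_matches_closed_form(rng):
    ids = np.repeat(np.arange(4), 3)
    y = rng.normal(2.0, 1.0, len(ids))
    df = pd.DataFrame({"y": y, "id": ids})
    spec = ModelSpec("y ~ 1", ("id",), "gaussian")
    params = {"beta": np.array([2.0]), "variances": {"id": 0.5}, "scale": 1.2}
    brute = brute_force_loglik(spec, df, params)
    from scipy.stats import multivariate_normal

    Z = np.zeros((len(ids), 4))
    Z[np.arange(len(ids)), ids] = 1.0
    cov = 1.2 * np.eye(len(ids)) + 0.5 * Z @ Z.T
    ref = multivariate_normal.logpdf(y, mean=np.full(len(ids), 2.0), cov=cov)
    assert abs(brute - ref) < 1e-8


def test_brute_force_two_factor_guard(rng):
    ids = np.repeat(np.arange(5), 4)
    reg = np.tile(np.arange(4), 5)
    df = pd.DataFrame({"y": (rng.random(20) < 0.5).astype(int), "id": ids, "region": reg})
    spec = ModelSpec("y ~ 1", ("id", "region"), "binomial")
    with pytest.raises(GlmmError, match="too large"):
        brute_force_loglik(
            spec, df, {"beta": np.zeros(1), "variances": {"id": 0.3, "region": 0.3}}
        )


def test_lrt_identical_models_is_zero(rng):
    df = make_binomial_instance(rng, 8, 6)
    spec = ModelSpec("y ~ x", ("id",), "binomial")
    fit = fit_glmm(spec, df)
    with pytest.raises(GlmmError):
        likelihood_ratio_test(fit, fit)  # df = 0 is not a valid test
    red = fit_glmm(ModelSpec("y ~ 1", ("id",), "binomial"), df)
    lrt = likelihood_ratio_test(fit, red)
    assert lrt.chi_square >= 0.0
    assert lrt.df == 1
    assert 0.0 <= lrt.p_value <= 1.0


def test_lrt_validates_rows_and_nesting(rng):
    df = make_binomial_instance(rng, 8, 6)
    spec = ModelSpec("y ~ x", ("id",), "binomial")
    fit = fit_glmm(spec, df)
    short = fit_glmm(spec, df.iloc[:-3])
    with pytest.raises(GlmmError, match="row-count"):
        likelihood_ratio_test(fit, short)
    df2 = df.assign(z=np.arange(len(df)) % 2)
    other = fit_glmm(ModelSpec("y ~ z", ("id",), "binomial"), df2)
    with pytest.raises(GlmmError, match="subset"):
        likelihood_ratio_test(fit, other)


def test_lrt_negative_statistic_clipped(rng):
    df = make_binomial_instance(rng, 8, 6)
    spec = ModelSpec("y ~ x", ("id",), "binomial")
    full = fit_glmm(spec, df)
    red = fit_glmm(ModelSpec("y ~ 1", ("id",), "binomial"), df)
    # simulate convergence noise: reduced apparently above full
    red.loglik = full.loglik + 1e-8
    lrt = likelihood_ratio_test(full, red)
    assert lrt.chi_square == 0.0
    assert lrt.p_value == 1.0


def test_marginal_predict_inverse_link(rng):
    df = make_binomial_instance(rng, 6, 5)
    fit = fit_glmm(ModelSpec("y ~ x", ("id",), "binomial"), df)
    fit.params = np.array([-2.122, 0.0])
    p = marginal_predict(fit, pd.DataFrame({"x": [0.0]}))
    assert abs(p[0] - expit(-2.122)) < 1e-12
    assert abs(p[0] - 0.10706) < 5e-4
    fit.params = np.array([0.0, 0.0])
    assert marginal_predict(fit, pd.DataFrame({"x": [1.3]}))[0] == pytest.approx(0.5)
    dfp = df.assign(y=rng.poisson(1.0, len(df)))
    fitp = fit_glmm(ModelSpec("y ~ x", ("id",), "poisson"), dfp)
    fitp.params = np.array([0.0, 0.0])
    assert marginal_predict(fitp, pd.DataFrame({"x": [0.7]}))[0] == pytest.approx(1.0)


def test_marginal_predict_unseen_level_raises(small_senescent):
    from stressborn.senescence import fit_senescence_models

    fits = fit_senescence_models(small_senescent)
    with pytest.raises(GlmmError):
        marginal_predict(
            fits.full,
            pd.DataFrame(
                {
                    "high_stress_born": [0],
                    "age_c": [0.0],
                    "last_age_scaled": [0.3],
                    "last_age_scaled_sq": [0.09],
                    "censored": [0],
                    "birth_decade": ["1890s"],
                }
            ),
        )


def test_fit_invariant_to_row_order_and_level_labels(rng):
    df = make_binomial_instance(rng, 10, 6)
    spec = ModelSpec("y ~ x", ("id",), "binomial")
    fit1 = fit_glmm(spec, df)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    shuffled["id"] = shuffled["id"].map(lambda g: f"grp_{chr(122 - g)}")
    fit2 = fit_glmm(spec, shuffled)
    np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-6)
    assert abs(fit1.loglik - fit2.loglik) < 1e-6
    assert abs(fit1.vcomp["id"] - fit2.vcomp["id"]) < 1e-5


def test_loglik_never_decreases_with_added_terms(rng):
    df = make_binomial_instance(rng, 12, 6)
    df["z"] = rng.normal(size=len(df))
    lls = []
    for rhs in ("1", "x", "x + z", "x * z"):
        fit = fit_glmm(ModelSpec(f"y ~ {rhs}", ("id",), "binomial"), df)
        lls.append(fit.loglik)
    assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))


def test_aliased_columns_dropped_with_warning(rng):
    df = make_binomial_instance(rng, 6, 5)
    df["x2"] = 2.0 * df["x"]
    with pytest.warns(UserWarning, match="aliased"):
        fit = fit_glmm(ModelSpec("y ~ x + x2", ("id",), "binomial"), df)
    assert "x2" in fit.dropped_columns


def test_wald_test_matches_single_coef_z(rng):
    df = make_binomial_instance(rng, 10, 6)
    fit = fit_glmm(ModelSpec("y ~ x", ("id",), "binomial"), df)
    w = wald_test(fit, ["x"])
    z = fit.z_values[fit.param_names.index("x")]
    assert w["chi_square"] == pytest.approx(z ** 2, rel=1e-8)


def test_wald_coverage_at_study_scale_variance(rng):
    """Interval coverage sanity for the logistic fit with an individual-level
    SD of 0.438 (the scale reported for repeated measures in this system)."""
    hits = 0
    reps = 60
    beta_true = np.array([-0.5, 0.6])
    for r in range(reps):
        ids = np.repeat(np.arange(150), 6)
        x = rng.normal(size=len(ids))
        u = rng.normal(0, 0.438, 150)
        eta = beta_true[0] + beta_true[1] * x + u[ids]
        y = (rng.random(len(ids)) < expit(eta)).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "id": ids})
        fit = fit_glmm(ModelSpec("y ~ x", ("id",), "binomial"), df)
        j = fit.param_names.index("x")
        lo = fit.params[j] - 1.96 * fit.se[j]
        hi = fit.params[j] + 1.96 * fit.se[j]
        hits += lo <= beta_true[1] <= hi
    assert 0.85 <= hits / reps <= 1.0


def test_binomial_fit_agrees_with_lme4(tmp_path, rng):
    """Cross-check the Laplace fit against lme4::glmer on one dataset."""
    df = make_binomial_instance(rng, 40, 8, sd=0.7)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1|id), family=binomial, data=d)
        cat(sprintf("%.6f %.6f %.6f %.6f\\n",
            fixef(m)[1], fixef(m)[2], as.numeric(logLik(m)),
            as.numeric(VarCorr(m)$id[1])))
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    b0, b1, ll, vid = map(float, out.stdout.split())
    fit = fit_glmm(ModelSpec("y ~ x", ("id",), "binomial"), df)
    assert abs(fit.params[0] - b0) < 0.02
    assert abs(fit.params[1] - b1) < 0.02
    assert abs(fit.loglik - ll) < 0.05
    assert abs(fit.vcomp["id"] - vid) < 0.05


def test_fitresult_aic_counts_variance_components(rng):
    df = make_binomial_instance(rng, 8, 6)
    fit = fit_glmm(ModelSpec("y ~ x", ("id",), "binomial"), df)
    assert fit.k_params == 3  # intercept, slope, sigma2_id
    assert fit.aic == pytest.approx(-2 * fit.loglik + 6.0)


def test_empty_data_raises():
    with pytest.raises(GlmmError, match="empty"):
        fit_glmm(ModelSpec("y ~ x", (), "binomial"), pd.DataFrame({"y": [], "x": []}))
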
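"""Trend ANOVA, abundance GLM, attraction covariate, and the Poisson GLMM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import steppefav as sf
from steppefav.population import glmm_loglik_bruteforce, lr_term_test


# ---------------------------------------------------------------------------
# favourability trend GLM


def _trend_panel(rng, n_cells=24, years=(2011, 2013, 2015, 2017),
                 slope=-0.05, prot_effects=(0.1, 0.0, -0.1), noise=0.03):
    levels = ("reserve", "spa", "unprotected")
    rows = []
    for i in range(n_cells):
        lev = levels[i % 3]
        eff = prot_effects[i % 3]
        for year in years:
            rows.append({"cell_x": i, "cell_y": 0, "year": year,
                         "protection": lev, "effect": eff})
    panel = pd.DataFrame(rows)
    # standardize year exactly as the model does: over all panel rows
    yrs = panel["year"].astype(float)
    zy = (yrs - yrs.mean()) / yrs.std(ddof=1)
    panel["favourability"] = (0.4 + panel["effect"] + slope * zy
                              + rng.normal(0, noise, len(panel)))
    return panel.drop(columns=["effect"])


def test_trend_glm_recovers_noiseless_coefficients():
    rng = np.random.default_rng(0)
    panel = _trend_panel(rng, noise=0.0)
    # add minuscule noise so the residual df is meaningful but estimates are
    # unchanged to 6 decimals
    panel["favourability"] += np.random.default_rng(1).normal(0, 1e-7, len(panel))
    est, anova = sf.favourability_trend_glm(panel)
    assert est["intercept"] == pytest.approx(0.4, abs=1e-5)
    assert est["year"] == pytest.approx(-0.05, abs=1e-5)
    # sum-to-zero contrasts: coefficient = level effect minus the mean effect
    assert est["protection[reserve]"] == pytest.approx(0.1, abs=1e-5)
    assert est["protection[spa]"] == pytest.approx(0.0, abs=1e-5)
    assert anova.loc["year", "p"] < 1e-10
    assert anova.loc["protection", "p"] < 1e-10
    assert anova.loc["year:protection", "p"] > 0.5


def test_trend_glm_matches_statsmodels_type3():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(2)
    panel = _trend_panel(rng)
    est, anova = sf.favourability_trend_glm(panel)

    df = panel.copy()
    years = df["year"].astype(float)
    df["zyear"] = (years - years.mean()) / years.std(ddof=1)
    res = smf.ols(
        "favourability ~ zyear * C(protection, Sum)", data=df
    ).fit()
    ref = anova_lm(res, typ=3)
    assert anova.loc["year", "sum_sq"] == pytest.approx(
        ref.loc["zyear", "sum_sq"], rel=1e-8)
    assert anova.loc["protection", "sum_sq"] == pytest.approx(
        ref.loc["C(protection, Sum)", "sum_sq"], rel=1e-8)
    assert anova.loc["year:protection", "sum_sq"] == pytest.approx(
        ref.loc["zyear:C(protection, Sum)", "sum_sq"], rel=1e-8)
    assert anova.loc["residual", "sum_sq"] == pytest.approx(
        ref.loc["Residual", "sum_sq"], rel=1e-8)
    assert anova.loc["year", "p"] == pytest.approx(ref.loc["zyear", "PR(>F)"],
                                                   rel=1e-6)


def test_trend_glm_partial_r2_definition(rng):
    panel = _trend_panel(rng)
    _, anova = sf.favourability_trend_glm(panel)
    for term in ("year", "protection", "year:protection"):
        ss = anova.loc[term, "sum_sq"]
        rss = anova.loc["residual", "sum_sq"]
        assert anova.loc[term, "partial_r2"] == pytest.approx(ss / (ss + rss))


def test_trend_glm_needs_two_levels_and_years(rng):
    panel = _trend_panel(rng)
    with pytest.raises(sf.SchemaError):
        sf.favourability_trend_glm(panel[panel["protection"] == "reserve"])
    with pytest.raises(sf.SchemaError):
        sf.favourability_trend_glm(panel[panel["year"] == 2011])


# ---------------------------------------------------------------------------
# abundance GLM


def test_abundance_glm_closed_form_means_and_lr():
    counts = np.r_[np.full(10, 2), np.zeros(10), np.full(10, 1), np.zeros(30)]
    protection = ["reserve"] * 20 + ["spa"] * 20 + ["unprotected"] * 20
    fit = sf.abundance_glm(counts, protection)
    assert fit.group_means["reserve"] == pytest.approx(1.0)
    assert fit.group_means["spa"] == pytest.approx(0.5)
    assert fit.group_means["unprotected"] == pytest.approx(0.0)
    # canonical link: intercept = log mean of the first (alphabetical) level
    assert fit.params["log_mean[reserve]"] == pytest.approx(0.0, abs=1e-6)
    assert fit.params["log_ratio[spa]"] == pytest.approx(np.log(0.5), abs=1e-5)

    # brute-force LR: Poisson log-likelihood at level means vs overall mean
    def pois_llf(y, mu):
        mu = np.maximum(mu, 1e-300)
        return float((y * np.log(mu) - mu - gammaln(y + 1)).sum())

    mu_full = pd.Series(protection).map(fit.group_means).to_numpy()
    lr_expected = 2 * (pois_llf(counts, mu_full) - pois_llf(counts, counts.mean()))
    assert fit.lr_chi2 == pytest.approx(lr_expected, abs=1e-5)
    assert fit.lr_df == 2
    assert fit.lr_p == pytest.approx(stats.chi2.sf(lr_expected, 2), abs=1e-8)


def test_abundance_glm_zero_level_boundary_warns():
    counts = np.r_[np.full(5, 3), np.zeros(5)]
    with pytest.warns(UserWarning, match="zero counts"):
        sf.abundance_glm(counts, ["reserve"] * 5 + ["spa"] * 5)


def test_abundance_glm_rejects_bad_counts():
    with pytest.raises(sf.SchemaError):
        sf.abundance_glm([1.5, 2], ["a", "b"])
    with pytest.raises(sf.SchemaError):
        sf.abundance_glm([1, 2], ["a", "a"])


# ---------------------------------------------------------------------------
# conspecific attraction covariate


def test_neighbouring_males_hand_example():
    census = pd.DataFrame({
        "point_id": [1, 2, 3, 1, 2, 3],
        "x": [0.0, 1000.0, 5000.0] * 2,
        "y": [0.0, 0.0, 0.0] * 2,
        "year": [2011] * 3 + [2012] * 3,
        "males": [2, 3, 7, 1, 0, 4],
    })
    out = sf.neighbouring_males(census, radius=1700.0)
    # 2011: points 1 and 2 are 1 km apart, point 3 is isolated
    assert list(out[:3]) == [3.0, 2.0, 0.0]
    assert list(out[3:]) == [0.0, 1.0, 0.0]


def test_neighbouring_males_radius_inclusive():
    census = pd.DataFrame({
        "point_id": [1, 2], "x": [0.0, 1700.0], "y": [0.0, 0.0],
        "year": [2011, 2011], "males": [5, 2],
    })
    out = sf.neighbouring_males(census, radius=1700.0)
    assert list(out) == [2.0, 5.0]


def test_neighbouring_males_matches_python_loop(rng):
    n = 40
    census = pd.DataFrame({
        "point_id": np.r_[np.arange(n), np.arange(n)],
        "x": np.r_[(x := rng.uniform(0, 6000, n)), x],
        "y": np.r_[(y := rng.uniform(0, 6000, n)), y],
        "year": np.r_[np.full(n, 2011), np.full(n, 2012)],
        "males": rng.poisson(1.0, 2 * n),
    })
    out = sf.neighbouring_males(census, radius=1700.0)
    for i, row in census.iterrows():
        total = 0.0
        for j, other in census.iterrows():
            if i == j or other["year"] != row["year"]:
                continue
            d = np.hypot(row["x"] - other["x"], row["y"] - other["y"])
            if d <= 1700.0:
                total += other["males"]
        assert out[i] == total


def test_neighbouring_males_duplicate_raises():
    census = pd.DataFrame({
        "point_id": [1, 1], "x": [0.0, 10.0], "y": [0.0, 0.0],
        "year": [2011, 2011], "males": [1, 2],
    })
    with pytest.raises(sf.SchemaError):
        sf.neighbouring_males(census)


# ---------------------------------------------------------------------------
# Poisson GLMM


def _toy_glmm(rng, n_groups=30, n_per=6, sigma=0.5, beta=(0.2, 0.4)):
    groups = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=n_groups * n_per)
    u = rng.normal(0, sigma, n_groups)
    mu = np.exp(beta[0] + beta[1] * x + u[groups])
    y = rng.poisson(mu)
    return y, pd.DataFrame({"x": x}), groups


def test_glmm_loglik_matches_bruteforce_oracle():
    rng = np.random.default_rng(10)
    y, X, groups = _toy_glmm(rng, n_groups=3, n_per=4)
    from steppefav.population import _GroupData, _glmm_loglik
    from numpy.polynomial.hermite import hermgauss

    Xmat = np.column_stack([np.ones(len(y)), X["x"].to_numpy()])
    data = _GroupData(np.asarray(y, float), Xmat, groups)
    for params, sigma in [((0.2, 0.4), 0.5), ((0.0, 0.0), 1.2), ((0.3, -0.2), 0.05)]:
        slow = glmm_loglik_bruteforce(y, X, groups, params, sigma,
                                      n_grid=400_000)
        errors = []
        for nq in (15, 25):
            nodes, weights = hermgauss(nq)
            fast = _glmm_loglik(np.r_[params, sigma], data, nodes, weights)
            errors.append(abs(fast - slow))
        assert errors[1] < 1e-6  # 25 nodes nails the marginal likelihood
        assert errors[0] < 1e-5  # the default 15 nodes is already close
        assert errors[1] <= errors[0] + 1e-12  # more nodes never hurts


def test_glmm_sigma_zero_reduces_to_poisson_glm():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    y, X, groups = _toy_glmm(rng, sigma=0.0)
    from steppefav.population import _GroupData, _glmm_loglik
    from numpy.polynomial.hermite import hermgauss

    Xmat = np.column_stack([np.ones(len(y)), X["x"].to_numpy()])
    glm = sm.GLM(np.asarray(y, float), Xmat, family=sm.families.Poisson()).fit()
    data = _GroupData(np.asarray(y, float), Xmat, groups)
    nodes, weights = hermgauss(15)
    ll = _glmm_loglik(np.r_[np.asarray(glm.params), 0.0], data, nodes, weights)
    assert ll == pytest.approx(glm.llf, abs=1e-4)


def test_glmm_fit_recovers_toy_parameters():
    rng = np.random.default_rng(12)
    y, X, groups = _toy_glmm(rng, n_groups=80, n_per=8, sigma=0.6,
                             beta=(0.3, 0.5))
    fit = sf.fit_poisson_glmm(y, X, groups, term_tests=False)
    assert fit.params["intercept"] == pytest.approx(0.3, abs=0.2)
    assert fit.params["x"] == pytest.approx(0.5, abs=0.1)
    assert fit.sigma == pytest.approx(0.6, abs=0.15)
    assert not fit.boundary
    ci = fit.conf_int()
    assert (ci["lower"] < fit.params).all() and (fit.params < ci["upper"]).all()


def test_glmm_quadrature_node_convergence():
    rng = np.random.default_rng(13)
    y, X, groups = _toy_glmm(rng, n_groups=40, n_per=6, sigma=0.8)
    f9 = sf.fit_poisson_glmm(y, X, groups, n_quad=9, term_tests=False)
    f25 = sf.fit_poisson_glmm(y, X, groups, n_quad=25, term_tests=False)
    assert f9.llf == pytest.approx(f25.llf, abs=1e-3)
    assert np.allclose(f9.params, f25.params, atol=1e-3)
    assert f9.sigma == pytest.approx(f25.sigma, abs=1e-3)


def test_glmm_group_relabelling_invariance():
    rng = np.random.default_rng(14)
    y, X, groups = _toy_glmm(rng, n_groups=25, n_per=5, sigma=0.5)
    f1 = sf.fit_poisson_glmm(y, X, groups, term_tests=False)
    relabel = {g: f"site-{g:03d}" for g in np.unique(groups)}
    f2 = sf.fit_poisson_glmm(y, X, np.array([relabel[g] for g in groups]),
                             term_tests=False)
    assert f1.llf == pytest.approx(f2.llf, abs=1e-8)
    assert np.allclose(f1.params, f2.params, atol=1e-7)


def test_glmm_boundary_flag_when_no_group_variance():
    rng = np.random.default_rng(15)
    y, X, groups = _toy_glmm(rng, n_groups=40, n_per=8, sigma=0.0)
    fit = sf.fit_poisson_glmm(y, X, groups, term_tests=False)
    assert fit.sigma < 0.15
    # sigma variance column is NaN only when the estimate hits the boundary
    if fit.boundary:
        assert np.isnan(fit.cov_params.loc["sigma", "sigma"])


def test_glmm_term_tests_match_manual_refit():
    rng = np.random.default_rng(16)
    y, X, groups = _toy_glmm(rng, n_groups=30, n_per=6, sigma=0.5)
    full = sf.fit_poisson_glmm(y, X, groups, term_tests=True)
    reduced = sf.fit_poisson_glmm(y, X.drop(columns=["x"]), groups,
                                  term_tests=False)
    chi2, df, p = lr_term_test(full, reduced)
    assert full.term_tests.loc["x", "lr_chi2"] == pytest.approx(chi2, abs=1e-6)
    assert df == 1
    assert full.term_tests.loc["x", "p"] == pytest.approx(p, abs=1e-8)


def test_lr_term_test_edge_cases():
    rng = np.random.default_rng(17)
    y, X, groups = _toy_glmm(rng, n_groups=20, n_per=5)
    full = sf.fit_poisson_glmm(y, X, groups, term_tests=False)
    assert lr_term_test(full, full) == (0.0, 0, 1.0)
    X2 = X.copy()
    X2["z"] = rng.normal(size=len(y))
    bigger = sf.fit_poisson_glmm(y, X2, groups, term_tests=False)
    with pytest.raises(sf.SchemaError):
        lr_term_test(full, bigger)  # "reduced" model is larger


def test_glmm_input_validation(rng):
    y, X, groups = _toy_glmm(rng)
    with pytest.raises(sf.SchemaError):
        sf.fit_poisson_glmm(np.full(len(y), -1), X, groups)
    with pytest.raises(sf.SchemaError):
        sf.fit_poisson_glmm(y, X, np.zeros(len(y)))  # single group


def test_glmm_dispersion_near_one_under_true_model():
    rng = np.random.default_rng(18)
    y, X, groups = _toy_glmm(rng, n_groups=60, n_per=8, sigma=0.5)
    fit = sf.fit_poisson_glmm(y, X, groups, term_tests=False)
    assert 0.5 < fit.dispersion < 1.5
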
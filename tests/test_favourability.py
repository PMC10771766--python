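"""Logistic fit, stepwise selection, favourability transform, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

import steppefav as sf


# ---------------------------------------------------------------------------
# standardization and VIF


def test_standardize_means_zero_sd_one(rng):
    df = pd.DataFrame(rng.normal(5, 3, (40, 3)), columns=list("abc"))
    out, std = sf.standardize(df)
    assert np.allclose(out.mean(), 0.0, atol=1e-12)
    assert np.allclose(out.std(ddof=1), 1.0, atol=1e-12)
    # the standardizer reproduces the same transform on new data
    pd.testing.assert_frame_equal(std.transform(df), out[list("abc")])


def test_standardize_constant_column_raises(rng):
    df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
    with pytest.raises(sf.DegenerateVariableError, match="b"):
        sf.standardize(df)


def test_vif_independent_near_one_and_collinear_inf(rng):
    n = 500
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    df = pd.DataFrame({"a": a, "b": b, "c": a + b})
    table = sf.vif(df)
    assert np.isinf(table["vif"]).all()  # each is a combination of the others
    assert table["flagged"].all()
    table2 = sf.vif(df[["a", "b"]])
    assert (table2["vif"] < 1.2).all()
    assert not table2["flagged"].any()


# ---------------------------------------------------------------------------
# logistic fit closed forms


def test_intercept_only_fit_is_log_odds_of_prevalence():
    y = np.r_[np.ones(30), np.zeros(408)]
    fit = sf.fit_logistic(y, pd.DataFrame(index=range(438)))
    assert fit.params["intercept"] == pytest.approx(np.log(30 / 408), abs=1e-8)
    assert fit.n1 == 30 and fit.n0 == 408


def test_two_by_two_table_fit_matches_log_odds_ratio():
    # x=0: 10/50 present (odds 0.25); x=1: 40/50 present (odds 4) -> OR = 16
    x = np.r_[np.zeros(50), np.ones(50)]
    y = np.r_[np.ones(10), np.zeros(40), np.ones(40), np.zeros(10)]
    fit = sf.fit_logistic(y, pd.DataFrame({"x": x}))
    assert fit.params["intercept"] == pytest.approx(np.log(0.25), abs=1e-7)
    assert fit.params["x"] == pytest.approx(np.log(16.0), abs=1e-7)


def test_fitted_probabilities_sum_to_presences(rng):
    X = pd.DataFrame(rng.normal(size=(120, 2)), columns=["a", "b"])
    y = rng.binomial(1, expit(-1 + X["a"].to_numpy()))
    fit = sf.fit_logistic(y, X)
    # score equation for the intercept
    assert fit.fitted.sum() == pytest.approx(fit.n1, abs=1e-6)


def test_complete_separation_raises(rng):
    x = np.r_[np.linspace(-2, -1, 20), np.linspace(1, 2, 20)]
    y = (x > 0).astype(float)
    with pytest.raises(sf.SeparationError):
        sf.fit_logistic(y, pd.DataFrame({"x": x}))


def test_single_class_raises():
    with pytest.raises(sf.SeparationError):
        sf.fit_logistic(np.ones(20), pd.DataFrame({"x": np.arange(20.0)}))


def test_rank_deficient_design_raises(rng):
    a = rng.normal(size=30)
    y = rng.integers(0, 2, 30)
    with pytest.raises(sf.SchemaError):
        sf.fit_logistic(y, pd.DataFrame({"a": a, "b": 2 * a}))


# ---------------------------------------------------------------------------
# stepwise AIC


def test_stepwise_keeps_strong_predictor_drops_pure_noise():
    kept_signal, dropped_noise = 0, 0
    n_rep = 30
    for r in range(n_rep):
        rng = np.random.default_rng(400 + r)
        X = pd.DataFrame(rng.normal(size=(300, 4)),
                         columns=["signal", "n1", "n2", "n3"])
        y = rng.binomial(1, expit(-1 + 1.5 * X["signal"].to_numpy()))
        fit = sf.stepwise_aic(y, X)
        kept_signal += "signal" in fit.variables
        dropped_noise += not {"n1", "n2", "n3"} <= set(fit.variables)
    assert kept_signal == n_rep
    assert dropped_noise >= 0.9 * n_rep


def test_stepwise_all_noise_mostly_intercept_only():
    intercept_only = 0
    n_rep = 40
    for r in range(n_rep):
        rng = np.random.default_rng(500 + r)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = rng.binomial(1, 0.3, 200)
        fit = sf.stepwise_aic(y, X)
        intercept_only += len(fit.variables) == 0
    # each noise variable survives with P ~ P(chi2_1 > 2) ~ 0.157
    assert intercept_only >= 0.4 * n_rep


def test_stepwise_never_beats_no_subset(rng):
    X = pd.DataFrame(rng.normal(size=(150, 3)), columns=["a", "b", "c"])
    y = rng.binomial(1, expit(-0.5 + X["a"].to_numpy()))
    best = sf.stepwise_aic(y, X)
    from itertools import combinations

    for k in range(4):
        for subset in combinations(["a", "b", "c"], k):
            f = sf.fit_logistic(y, X[list(subset)])
            assert best.aic <= f.aic + 1e-8


def test_stepwise_empty_candidates_gives_intercept_only(rng):
    y = rng.integers(0, 2, 50)
    fit = sf.stepwise_aic(y, pd.DataFrame(index=range(50)))
    assert fit.variables == []


# ---------------------------------------------------------------------------
# favourability transform


def test_favourability_closed_values():
    n1, n0 = 30, 408
    assert sf.favourability_transform(n1 / (n1 + n0), n1, n0) == pytest.approx(0.5)
    assert sf.favourability_transform(0.0, n1, n0) == 0.0
    assert sf.favourability_transform(1.0, n1, n0) == 1.0
    # P = 0.5 gives odds 1, so F = 1 / (n1/n0 + 1) = n0 / (n0 + n1)
    assert sf.favourability_transform(0.5, n1, n0) == pytest.approx(408 / 438)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.floats(0.001, 0.999),
    st.floats(0.001, 0.999),
    st.integers(1, 200),
    st.integers(1, 200),
)
def test_favourability_monotone_and_bounded(p1, p2, n1, n0):
    f1 = sf.favourability_transform(p1, n1, n0)
    f2 = sf.favourability_transform(p2, n1, n0)
    assert 0.0 <= f1 <= 1.0
    if p1 < p2:
        assert f1 < f2


def test_favourability_equals_shifted_logistic(rng):
    n1, n0 = 25, 175
    p = rng.uniform(0.01, 0.99, 500)
    direct = sf.favourability_transform(p, n1, n0)
    shifted = expit(np.log(p / (1 - p)) - np.log(n1 / n0))
    assert np.max(np.abs(direct - shifted)) < 1e-12


def test_build_model_intercept_shift_and_r2(rng):
    X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
    y = rng.binomial(1, expit(-1.5 + X["a"].to_numpy()))
    Xs, std = sf.standardize(X)
    fit = sf.fit_logistic(y, Xs)
    model = sf.build_favourability_model(fit, std)
    assert model.b0f == pytest.approx(
        fit.params["intercept"] - np.log(fit.n1 / fit.n0)
    )
    fav = model.predict_favourability(X)
    expected = sf.favourability_transform(fit.fitted, fit.n1, fit.n0)
    assert np.max(np.abs(fav - expected)) < 1e-10
    assert 0.0 < model.r2_deviance < 1.0
    assert 0.0 < model.r2_nagelkerke < 1.0


def test_model_json_round_trip(rng, tmp_path):
    X = pd.DataFrame(rng.normal(size=(150, 2)), columns=["a", "b"])
    y = rng.binomial(1, expit(-1 + X["a"].to_numpy()))
    Xs, std = sf.standardize(X)
    model = sf.build_favourability_model(sf.fit_logistic(y, Xs), std)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = sf.FavourabilityModel.from_json(path)
    assert np.allclose(back.predict_favourability(X), model.predict_favourability(X))


# ---------------------------------------------------------------------------
# diagnostics


def _auc_bruteforce(scores, y):
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_matches_pairwise_oracle(rng):
    scores = rng.normal(size=80).round(1)  # rounding forces ties
    y = rng.integers(0, 2, 80)
    if y.sum() in (0, len(y)):
        y[0] = 1 - y[0]
    assert sf.auc(scores, y) == pytest.approx(_auc_bruteforce(scores, y), abs=1e-12)


def test_auc_invariant_to_monotone_transform(rng):
    scores = rng.uniform(0.01, 0.99, 100)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    assert sf.auc(scores, y) == pytest.approx(sf.auc(np.log(scores), y), abs=1e-12)


def test_auc_perfect_and_chance():
    y = np.r_[np.zeros(10), np.ones(10)]
    assert sf.auc(np.arange(20.0), y) == 1.0
    assert sf.auc(np.zeros(20), y) == 0.5
    with pytest.raises(sf.UndefinedAUCError):
        sf.auc(np.arange(5.0), np.ones(5))


def test_quantile_residuals_deterministic_and_calibrated(rng):
    p = rng.uniform(0.05, 0.95, 4000)
    y = rng.binomial(1, p)
    r1 = sf.quantile_residuals(p, y, rng_seed=3)
    r2 = sf.quantile_residuals(p, y, rng_seed=3)
    assert np.array_equal(r1, r2)
    # under a correctly specified model the residuals are exactly N(0, 1)
    assert stats.kstest(r1, "norm").pvalue > 0.01


def test_quantile_residuals_sign_structure():
    p = np.full(10, 0.5)
    y = np.r_[np.ones(5), np.zeros(5)]
    r = sf.quantile_residuals(p, y, rng_seed=0)
    assert (r[:5] > 0).all() and (r[5:] < 0).all()


def test_moran_detects_gradient(rng):
    n = 60
    xy = rng.uniform(0, 1000, (n, 2))
    values = xy[:, 0] / 1000.0 + rng.normal(0, 0.05, n)
    i_obs, p = sf.morans_test(values, xy, n_permutations=499, rng_seed=1)
    assert i_obs > 0
    assert p <= 0.01


def test_moran_null_uniform_p(rng):
    n = 40
    xy = rng.uniform(0, 1000, (n, 2))
    pvals = [
        sf.morans_test(rng.normal(size=n), xy, n_permutations=199, rng_seed=k)[1]
        for k in range(60)
    ]
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_moran_validation_errors(rng):
    xy = rng.uniform(0, 100, (20, 2))
    with pytest.raises(sf.DegenerateVariableError):
        sf.morans_test(np.ones(20), xy)
    with pytest.raises(sf.SchemaError):
        sf.morans_test(rng.normal(size=5), xy[:5])
    xy2 = xy.copy()
    xy2[1] = xy2[0]
    with pytest.raises(sf.SchemaError):
        sf.morans_test(rng.normal(size=20), xy2)


def test_moran_seed_reproducible(rng):
    xy = rng.uniform(0, 100, (30, 2))
    z = rng.normal(size=30)
    a = sf.morans_test(z, xy, n_permutations=199, rng_seed=9)
    b = sf.morans_test(z, xy, n_permutations=199, rng_seed=9)
    assert a == b
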
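"""Logistic fitter, calibration and discrimination diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from jaderpv.cohort import apply_exclusions, derive_records
from jaderpv.logistic import (
    CollinearityError,
    DesignMatrix,
    LogisticFit,
    SeparationWarning,
    design_matrix,
    fit_logistic,
    hosmer_lemeshow,
    roc_auc,
    univariate_screen,
)
from jaderpv.signals import ContingencyTable, odds_ratio_ci
from jaderpv.synthetic import GeneratorConfig, generate


def _design_from_table(a, b, c, d, name="x"):
    """Single binary predictor realizing the 2x2 (rows: outcome)."""
    x = [1] * a + [0] * b + [1] * c + [0] * d
    y = [1] * (a + b) + [0] * (c + d)
    return DesignMatrix(np.array(y), pd.DataFrame({name: x}))


def test_single_predictor_matches_published_age_or():
    X = _design_from_table(248, 61, 511, 251, "age_ge70")
    fit = fit_logistic(X)
    t = fit.term("age_ge70")
    assert round(t.odds_ratio, 2) == 2.00
    assert round(t.ci_low, 2) == 1.45
    assert round(t.ci_high, 2) == 2.75


@given(st.integers(2, 400), st.integers(2, 400),
       st.integers(2, 400), st.integers(2, 400))
@settings(max_examples=40)
def test_single_binary_predictor_equals_cross_product(a, b, c, d):
    """Logistic OR and Wald CI collapse to the 2x2 formulas exactly."""
    fit = fit_logistic(_design_from_table(a, b, c, d))
    ref = odds_ratio_ci(ContingencyTable(a, b, c, d))
    t = fit.term("x")
    assert t.odds_ratio == pytest.approx(ref.ror, rel=1e-6)
    assert t.ci_low == pytest.approx(ref.ci_low, rel=1e-5)
    assert t.ci_high == pytest.approx(ref.ci_high, rel=1e-5)


def test_matches_statsmodels_on_generated_cohort(drug_dict, event_dict):
    import statsmodels.api as sm

    cfg = GeneratorConfig(n_cases=1500, seed=21,
                          exposure_probs={"eldecalcitol": 1.0,
                                          "alfacalcidol": 0.0,
                                          "calcitriol": 0.0})
    cases, _ = generate(cfg)
    filtered, _ = apply_exclusions(cases, drug_dict)
    exposed = [r for r in derive_records(filtered, drug_dict, event_dict)
               if r.exposed_vd3]
    X = design_matrix(exposed)
    fit = fit_logistic(X)
    ref = sm.Logit(np.asarray(X.outcome, float),
                   sm.add_constant(X.predictors.to_numpy(float))).fit(disp=0)
    assert fit.converged
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-8)
    np.testing.assert_allclose([t.se for t in fit.terms], ref.bse, atol=1e-8)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


def test_brute_force_likelihood_oracle(forty_row_design):
    """Coefficients agree with direct numerical maximisation of the
    Bernoulli log-likelihood by an independent optimizer."""
    X = forty_row_design
    fit = fit_logistic(X)
    M = np.column_stack([np.ones(X.n), X.predictors.to_numpy(float)])
    y = np.asarray(X.outcome, float)

    def nll(beta):
        eta = M @ beta
        return -(y @ eta - np.logaddexp(0, eta).sum())

    res = optimize.minimize(nll, np.zeros(3), method="BFGS",
                            options={"gtol": 1e-12})
    np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)


def test_likelihood_ascent(forty_row_design):
    fit = fit_logistic(forty_row_design)
    assert fit.converged and fit.n_iterations <= 50


def test_separation_warning():
    y = np.array([0] * 10 + [1] * 10)
    X = DesignMatrix(y, pd.DataFrame({"x": y, "z": np.tile([0, 1], 10)}))
    with pytest.warns(SeparationWarning):
        fit = fit_logistic(X)
    assert not fit.converged


def test_degenerate_column_rejected():
    X = DesignMatrix(np.array([0, 1] * 10), pd.DataFrame({"x": [0] * 20}))
    with pytest.raises(ValueError, match="degenerate"):
        fit_logistic(X)


def test_collinear_columns_named():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 2, 60)
    y = rng.integers(0, 2, 60)
    X = DesignMatrix(y, pd.DataFrame({"x1": x, "x2": x}))
    with pytest.raises(CollinearityError) as exc:
        fit_logistic(X)
    assert {"x1", "x2"} <= set(exc.value.terms)


def test_single_class_outcome_rejected():
    X = DesignMatrix(np.zeros(20, dtype=int),
                     pd.DataFrame({"x": [0, 1] * 10}))
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(X)


def test_univariate_screen_published_counts():
    """Magnesium oxide 75/234 vs 99/663 -> OR 2.15; loop diuretics -> 1.00."""
    X = _design_from_table(75, 234, 99, 663, "mgo")
    assert round(univariate_screen(X)["mgo"].term("mgo").odds_ratio, 2) == 2.15
    X = _design_from_table(32, 277, 79, 683, "loop_diuretic")
    t = univariate_screen(X)["loop_diuretic"].term("loop_diuretic")
    assert round(t.odds_ratio, 2) == 1.00
    assert (round(t.ci_low, 2), round(t.ci_high, 2)) == (0.65, 1.54)


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow

def _fit_with_probs(probs, outcome):
    probs = np.asarray(probs, float)
    return LogisticFit(terms=(), log_likelihood=0.0, converged=True,
                       n_iterations=1, n=len(probs), fitted=probs)


def test_hl_perfect_calibration_zero_statistic():
    """Groups whose observed counts equal expected give statistic 0."""
    probs = [0.2] * 10 + [0.5] * 10 + [0.8] * 10
    y = [1] * 2 + [0] * 8 + [1] * 5 + [0] * 5 + [1] * 8 + [0] * 2
    X = DesignMatrix(np.array(y), pd.DataFrame({"x": [0] * 30}))
    cal = hosmer_lemeshow(_fit_with_probs(probs, y), X)
    assert cal.hl_statistic == pytest.approx(0.0, abs=1e-12)
    assert cal.hl_p == pytest.approx(1.0)
    assert cal.grouped_by_pattern and cal.hl_df == 1


def test_hl_three_group_worked_fixture():
    """Direct summation oracle: groups (n=10, pbar=.2, O=3), (10, .5, 4),
    (10, .8, 9) give sum (O-E)^2/(n pbar (1-pbar)) = 1.65."""
    probs = [0.2] * 10 + [0.5] * 10 + [0.8] * 10
    y = [1] * 3 + [0] * 7 + [1] * 4 + [0] * 6 + [1] * 9 + [0] * 1
    X = DesignMatrix(np.array(y), pd.DataFrame({"x": [0] * 30}))
    cal = hosmer_lemeshow(_fit_with_probs(probs, y), X)
    expected = ((3 - 2) ** 2 / (10 * 0.2 * 0.8)
                + (4 - 5) ** 2 / (10 * 0.5 * 0.5)
                + (9 - 8) ** 2 / (10 * 0.8 * 0.2))
    assert cal.hl_statistic == pytest.approx(expected, rel=1e-12)
    assert cal.hl_p == pytest.approx(stats.chi2.sf(expected, 1))
    assert sum(g[0] for g in cal.groups) == 30


def test_hl_too_few_patterns_undefined():
    probs = [0.3] * 10 + [0.6] * 10
    y = [0, 1] * 10
    X = DesignMatrix(np.array(y), pd.DataFrame({"x": [0] * 20}))
    with pytest.raises(ValueError, match="distinct"):
        hosmer_lemeshow(_fit_with_probs(probs, y), X)


def test_hl_null_p_values_roughly_uniform(drug_dict, event_dict):
    """Refitting on outcomes resampled from the model yields
    approximately uniform H-L p-values when the risk patterns are
    numerous enough for the chi-square approximation (the approximation
    is known to degrade under heavily tied fitted probabilities)."""
    rng = np.random.default_rng(99)
    n = 500
    base = pd.DataFrame(
        {f"x{j}": rng.integers(0, 2, n) for j in range(8)})
    coefs = np.array([0.5, 0.3, -0.4, 0.25, -0.2, 0.35, -0.3, 0.2])
    eta = -0.7 + base.to_numpy() @ coefs
    p_true = 1 / (1 + np.exp(-eta))
    pvals = []
    for _ in range(250):
        y = rng.binomial(1, p_true)
        if y.sum() in (0, n):
            continue
        X = DesignMatrix(y, base)
        fit = fit_logistic(X)
        pvals.append(hosmer_lemeshow(fit, X).hl_p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# ROC AUC

def _X(y):
    return DesignMatrix(np.asarray(y), pd.DataFrame({"x": np.zeros(len(y))}))


def test_auc_perfect_separation():
    y = [0, 0, 0, 1, 1, 1]
    assert roc_auc(np.array([.1, .2, .3, .7, .8, .9]), _X(y)).auc == 1.0


def test_auc_all_ties_is_half():
    y = [0, 0, 1, 1]
    res = roc_auc(np.full(4, 0.5), _X(y))
    assert res.auc == pytest.approx(0.5)


def test_auc_matches_all_pairs_enumeration():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.8, 0.2])
    y = np.array([0, 0, 1, 1, 0, 1])
    res = roc_auc(scores, _X(y))
    pos = scores[y == 1]
    neg = scores[y == 0]
    conc = sum((1.0 if p > n else 0.5 if p == n else 0.0)
               for p, n in itertools.product(pos, neg))
    assert res.auc == pytest.approx(conc / (len(pos) * len(neg)), rel=1e-12)
    assert res.ci_low <= res.auc <= res.ci_high


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=50)
    y = rng.integers(0, 2, 50)
    base = roc_auc(scores, _X(y))
    for f in (np.exp, lambda s: s ** 3, lambda s: 2 * s + 10):
        assert roc_auc(f(scores), _X(y)).auc == pytest.approx(base.auc)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc(np.array([0.1, 0.2]), _X([1, 1]))
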
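import numpy as np
import pytest
from scipy import stats

import lifelines
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from trajsurv.survival import (breslow_baseline, concordance_index, cox_gradient,
                               cox_neg_log_partial_likelihood, km_estimate,
                               logrank_test, newton_cox_fit,
                               schoenfeld_ph_test, schoenfeld_residuals)
from conftest import make_surv, random_surv
from _oracles import breslow_naive, cindex_bruteforce, cox_nll_naive


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_all_censored_is_flat_one():
    km = km_estimate(make_surv([2, 5, 7], [0, 0, 0]))
    assert km.event_times.size == 0
    assert km.survival_at(10.0) == 1.0


def test_km_no_censoring_closed_form():
    km = km_estimate(make_surv([1, 2, 3], [1, 1, 1]))
    np.testing.assert_allclose(km.survival_prob, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(km.n_at_risk, [3, 2, 1])


def test_km_with_censoring_hand_oracle():
    # times 1, 2+, 3, 4: censoring shrinks the risk set without a step
    km = km_estimate(make_surv([1, 2, 3, 4], [1, 0, 1, 1]))
    np.testing.assert_allclose(km.event_times, [1, 3, 4])
    np.testing.assert_allclose(km.survival_prob, [3 / 4, 3 / 8, 0.0])


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(1)
    t = rng.exponential(3.0, size=40)
    km = km_estimate(make_surv(t, np.ones(40)))
    for tau in [0.5, 1.0, 2.5]:
        assert km.survival_at(tau) == pytest.approx(np.mean(t > tau))


def test_km_matches_lifelines_on_random_censored_data():
    rng = np.random.default_rng(7)
    surv = random_surv(rng, 80)
    km = km_estimate(surv)
    kmf = lifelines.KaplanMeierFitter().fit(surv.time_days, surv.event)
    for tau, s in zip(km.event_times, km.survival_prob):
        assert s == pytest.approx(kmf.predict(tau), abs=1e-12)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [1, 2, 3, 4, 5]
    e = [1, 1, 0, 1, 1]
    surv = make_surv(t + t, e + e)
    res = logrank_test(surv, ["a"] * 5 + ["b"] * 5)
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_logrank_three_groups_matches_lifelines():
    surv = make_surv([1, 3, 5, 2, 4, 9, 6, 7, 8],
                     [1, 1, 0, 1, 1, 1, 0, 1, 1])
    labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
    res = logrank_test(surv, labels)
    ref = multivariate_logrank_test(surv.time_days, labels, surv.event)
    assert res.df == 2
    assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_permutation_null_p_values_roughly_uniform():
    rng = np.random.default_rng(5)
    surv = random_surv(rng, 60)
    pvals = []
    for _ in range(300):
        labels = rng.permutation(np.repeat([0, 1], 30))
        pvals.append(logrank_test(surv, labels).p_value)
    # under the permutation null the p-value is approximately U(0, 1)
    assert 0.04 < np.mean(np.asarray(pvals) < 0.1) < 0.18
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_logrank_rejects_degenerate_groupings():
    surv = make_surv([1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        logrank_test(surv, ["a", "a", "a"])
    with pytest.raises(ValueError):
        logrank_test(make_surv([1, 2], [0, 0]), ["a", "b"])


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_cindex_perfect_and_tied_scores():
    surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
    assert concordance_index(surv, [4, 3, 2, 1]) == 1.0
    assert concordance_index(surv, [0, 0, 0, 0]) == 0.5


def test_cindex_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(20):
        surv = random_surv(rng, 20)
        scores = rng.normal(size=20)
        ours = concordance_index(surv, scores)
        ref = cindex_bruteforce(surv.time_days, surv.event, scores)
        assert ours == pytest.approx(ref, abs=1e-12)


def test_cindex_invariant_to_monotone_transform():
    rng = np.random.default_rng(11)
    surv = random_surv(rng, 30)
    scores = rng.normal(size=30)
    base = concordance_index(surv, scores)
    for f in (lambda s: 3 * s + 2, np.tanh, lambda s: np.exp(s / 2)):
        assert concordance_index(surv, f(scores)) == pytest.approx(base)


def test_cindex_no_comparable_pairs_raises():
    with pytest.raises(ValueError):
        concordance_index(make_surv([5, 5], [1, 1]), [1.0, 2.0])


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def test_cox_nll_at_zero_is_log_risk_set_sizes():
    surv = make_surv([1, 2, 3, 4], [1, 1, 0, 1])
    nll = cox_neg_log_partial_likelihood(np.zeros(2), np.zeros((4, 2)), surv)
    assert nll == pytest.approx(np.log(4) + np.log(3) + np.log(1))


def test_cox_nll_single_event_closed_form():
    x = np.array([[1.0], [2.0]])
    surv = make_surv([1, 2], [1, 0])
    beta = np.array([0.7])
    expected = -np.log(np.exp(0.7) / (np.exp(0.7) + np.exp(1.4)))
    assert cox_neg_log_partial_likelihood(beta, x, surv) == pytest.approx(expected)


def test_cox_nll_matches_naive_risk_set_oracle():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(30, 3))
    surv = random_surv(rng, 30)
    beta = rng.normal(size=3)
    ours = cox_neg_log_partial_likelihood(beta, X, surv)
    ref = cox_nll_naive(beta, X, surv.time_days, surv.event)
    assert ours == pytest.approx(ref, abs=1e-10)


def test_cox_nll_handles_tied_event_times():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(20, 2))
    t = rng.integers(1, 5, size=20).astype(float)  # heavy ties
    surv = make_surv(t, np.ones(20))
    beta = np.array([0.3, -0.4])
    ref = cox_nll_naive(beta, X, surv.time_days, surv.event)
    assert cox_neg_log_partial_likelihood(beta, X, surv) == pytest.approx(ref, abs=1e-10)


def test_cox_nll_is_convex_on_random_midpoints():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(25, 3))
    surv = random_surv(rng, 25)
    for _ in range(10):
        b1, b2 = rng.normal(size=(2, 3))
        mid = cox_neg_log_partial_likelihood((b1 + b2) / 2, X, surv)
        ends = (cox_neg_log_partial_likelihood(b1, X, surv)
                + cox_neg_log_partial_likelihood(b2, X, surv)) / 2
        assert mid <= ends + 1e-10


def test_cox_gradient_matches_finite_differences():
    rng = np.random.default_rng(19)
    X = rng.normal(size=(15, 3))
    surv = random_surv(rng, 15)
    beta = rng.normal(size=3) * 0.5
    g = cox_gradient(beta, X, surv)
    h = 1e-6
    for j in range(3):
        ej = np.eye(3)[j] * h
        fd = (cox_neg_log_partial_likelihood(beta + ej, X, surv)
              - cox_neg_log_partial_likelihood(beta - ej, X, surv)) / (2 * h)
        assert g[j] == pytest.approx(fd, abs=1e-5)


# ---------------------------------------------------------------------------
# Breslow baseline
# ---------------------------------------------------------------------------

def test_breslow_at_zero_beta_distinct_times():
    surv = make_surv([1, 2, 3, 4], [1, 1, 1, 1])
    bh = breslow_baseline(np.zeros(1), np.zeros((4, 1)), surv)
    np.testing.assert_allclose(bh.hazard_increments, [1 / 4, 1 / 3, 1 / 2, 1.0])
    np.testing.assert_allclose(bh.cumulative, np.cumsum(bh.hazard_increments))


def test_breslow_identical_covariates_beta_invariant_after_centering():
    surv = make_surv([1, 2, 3, 5], [1, 0, 1, 1])
    X = np.full((4, 2), 3.7)
    Xc = X - X.mean(axis=0)
    h_a = breslow_baseline(np.array([0.0, 0.0]), Xc, surv)
    h_b = breslow_baseline(np.array([5.0, -2.0]), Xc, surv)
    np.testing.assert_allclose(h_a.cumulative, h_b.cumulative)


def test_breslow_matches_naive_oracle():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(25, 2))
    surv = random_surv(rng, 25)
    beta = np.array([0.5, -0.3])
    bh = breslow_baseline(beta, X, surv)
    ref = breslow_naive(beta, X, surv.time_days, surv.event)
    for tau, h in zip(bh.event_times, bh.hazard_increments):
        assert h == pytest.approx(ref[tau], abs=1e-12)


def test_newton_cox_matches_lifelines():
    rng = np.random.default_rng(29)
    X = rng.normal(size=(80, 3))
    beta_true = np.array([0.6, -0.4, 0.0])
    t = rng.exponential(np.exp(-(X @ beta_true)))
    surv = make_surv(t, np.ones(80))
    beta, cov, _ = newton_cox_fit(X, surv)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["T"], df["E"] = t, 1
    cph = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(beta, cph.params_.values, atol=1e-5)
    np.testing.assert_allclose(np.sqrt(np.diag(cov)),
                               cph.standard_errors_.values, atol=1e-4)


# ---------------------------------------------------------------------------
# proportional-hazards check
# ---------------------------------------------------------------------------

def test_schoenfeld_residuals_sum_to_zero_at_fitted_beta():
    rng = np.random.default_rng(31)
    X = rng.normal(size=(60, 2))
    t = rng.exponential(np.exp(-X[:, 0] * 0.5))
    surv = make_surv(t, np.ones(60))
    beta, _, _ = newton_cox_fit(X, surv)
    resid = schoenfeld_residuals(beta, X, surv)
    np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-6)


def test_schoenfeld_type_one_error_calibrated_under_ph():
    # data simulated under exact proportional hazards; the global test should
    # reject at close to its nominal 5% level. n is large enough for the
    # chi-square asymptotics the score test relies on.
    rng = np.random.default_rng(37)
    n, reps = 400, 500
    rejections = 0
    for _ in range(reps):
        X = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        surv = make_surv(t, np.ones(n))
        beta, _, _ = newton_cox_fit(X, surv, tol=1e-6, max_iter=25)
        _, glob = schoenfeld_ph_test(beta, X, surv)
        rejections += glob.p_value < 0.05
    assert 0.03 <= rejections / reps <= 0.07


def test_schoenfeld_detects_time_varying_effect():
    # beta(t) flips sign mid-study: generated by piecewise-exponential
    # sampling with a covariate whose effect reverses after t = 1
    rng = np.random.default_rng(41)
    hits = 0
    reps = 20
    for _ in range(reps):
        n = 150
        x = rng.normal(size=(n, 1))
        beta_early, beta_late = 1.5, -1.5
        t1 = rng.exponential(np.exp(-beta_early * x[:, 0]))
        t = np.where(t1 < 1.0, t1,
                     1.0 + rng.exponential(np.exp(-beta_late * x[:, 0])))
        surv = make_surv(t, np.ones(n))
        beta, _, _ = newton_cox_fit(x, surv, tol=1e-6, max_iter=25)
        per_var, _ = schoenfeld_ph_test(beta, x, surv)
        hits += per_var[0].p_value < 0.05
    assert hits >= 0.9 * reps


def test_schoenfeld_requires_two_events():
    surv = make_surv([1, 2, 3], [1, 0, 0])
    with pytest.raises(ValueError):
        schoenfeld_ph_test(np.zeros(1), np.zeros((3, 1)), surv)
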
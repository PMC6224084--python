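"""Distribution fitting: censored likelihoods, MAP-EM mixture, regression."""

import numpy as np
import pytest
from scipy import stats

from bbqrisk import params as P
from bbqrisk.fitting import (
    CensoredConcentrationSet,
    FittingError,
    MixturePriors,
    assign_weight_class,
    censored_lognormal_loglik,
    fit_bodyweight_regression,
    fit_censored_lognormal,
    fit_censored_lognormal_mixture_map,
    fit_gamma_consumption,
    predict_bodyweight,
)
from bbqrisk.params import BodyweightRegression, LognormalParams
from bbqrisk.synthetic import gen_consumption_survey, GroundTruth


def _censored_set(draws, lod, meat="beef"):
    draws = np.asarray(draws)
    cens = draws < lod
    return CensoredConcentrationSet(meat, draws[~cens], np.full(cens.sum(), lod))


# ------------------------------ gamma -------------------------------------


def test_gamma_recovery_and_moment_identity(rng):
    x = rng.gamma(3.0, 1 / 0.015, size=5000)
    fit = fit_gamma_consumption(x)
    assert abs(fit.shape - 3.0) / 3.0 < 0.10
    # gamma MLE in the shape/rate parameterisation matches the sample mean
    assert abs(fit.mean - x.mean()) / x.mean() < 0.01


def test_gamma_degenerate_inputs():
    with pytest.raises(FittingError):
        fit_gamma_consumption(np.full(100, 5.0))
    with pytest.raises(FittingError):
        fit_gamma_consumption([1.0] * 5)
    with pytest.raises(FittingError):
        fit_gamma_consumption(np.r_[np.ones(20), -1.0])


# ------------------------- censored lognormal -----------------------------


def test_loglik_reduces_to_uncensored_case(rng):
    x = rng.lognormal(1.0, 0.5, 200)
    data = CensoredConcentrationSet("beef", x, np.empty(0))
    ll = censored_lognormal_loglik(LognormalParams(1.0, 0.5), data)
    ref = stats.lognorm.logpdf(x, s=0.5, scale=np.exp(1.0)).sum()
    assert np.isclose(ll, ref, rtol=1e-12)


def test_loglik_censored_record_at_median_contributes_log_half():
    data_det = CensoredConcentrationSet("beef", [2.0, 3.0], np.empty(0))
    median = np.exp(1.0)
    data_cens = CensoredConcentrationSet("beef", [2.0, 3.0], [median])
    p = LognormalParams(1.0, 0.7)
    delta = censored_lognormal_loglik(p, data_cens) - censored_lognormal_loglik(p, data_det)
    assert np.isclose(delta, np.log(0.5), atol=1e-12)


def test_loglik_degenerate_sdlog_limit(rng):
    x = rng.lognormal(0.0, 1.0, 50)
    data = CensoredConcentrationSet("beef", x, np.empty(0))
    lls = [censored_lognormal_loglik(LognormalParams(0.0, s), data) for s in (1.0, 0.1, 0.01)]
    assert lls[0] > lls[1] > lls[2]


def test_censored_fit_recovers_parameters(rng):
    x = rng.lognormal(1.0, 0.8, 500)
    lod = np.quantile(x, 0.4)  # ~40% censored
    fit = fit_censored_lognormal(_censored_set(x, lod))
    assert abs(fit.meanlog - 1.0) < 0.1
    assert abs(fit.sdlog - 0.8) < 0.15


def test_censored_fit_matches_closed_form_without_censoring(rng):
    x = rng.lognormal(0.5, 0.6, 300)
    fit = fit_censored_lognormal(CensoredConcentrationSet("pork", x, np.empty(0)))
    y = np.log(x)
    assert abs(fit.meanlog - y.mean()) < 1e-6
    assert abs(fit.sdlog - y.std()) < 1e-6


def test_censored_fit_mle_dominates_truth(rng):
    x = rng.lognormal(0.0, 1.0, 400)
    data = _censored_set(x, np.quantile(x, 0.3))
    fit = fit_censored_lognormal(data)
    assert censored_lognormal_loglik(fit, data) >= censored_lognormal_loglik(
        LognormalParams(0.0, 1.0), data
    )


def test_censored_fit_bias_shrinks_with_n():
    errs = {}
    for n in (200, 5000):
        e = []
        for rep in range(8):
            r = np.random.default_rng(1000 * n + rep)
            x = r.lognormal(0.0, 1.0, n)
            fit = fit_censored_lognormal(_censored_set(x, np.quantile(x, 0.3)))
            e.append(abs(fit.meanlog - 0.0) + abs(fit.sdlog - 1.0))
        errs[n] = np.mean(e)
    assert errs[5000] < errs[200]


def test_all_censored_rejected():
    with pytest.raises(FittingError):
        fit_censored_lognormal(CensoredConcentrationSet("beef", np.empty(0), np.ones(50)))


# ------------------------------- mixture ----------------------------------


def _mixture_sample(rng, n=600, w=0.6, mu=(-1.0, 2.0), sd=(0.5, 0.5)):
    pick = rng.random(n) < w
    x = np.where(
        pick,
        rng.lognormal(mu[0], sd[0], n),
        rng.lognormal(mu[1], sd[1], n),
    )
    return x


def test_mixture_recovery_with_mild_censoring(rng):
    x = _mixture_sample(rng)
    lod = 0.15  # censors part of the low component only
    res = fit_censored_lognormal_mixture_map(_censored_set(x, lod))
    assert abs(res.params.w - 0.6) < 0.1
    assert abs(res.params.component1.meanlog - (-1.0)) < 0.3
    assert abs(res.params.component2.meanlog - 2.0) < 0.3


def test_mixture_log_posterior_monotone(rng):
    x = _mixture_sample(rng, n=400)
    res = fit_censored_lognormal_mixture_map(_censored_set(x, 0.15))
    trace = res.log_posterior_trace
    assert np.all(np.diff(trace) > -1e-6 * (1 + np.abs(trace[:-1])))


def test_mixture_label_invariance(rng):
    x = _mixture_sample(rng, n=500)
    data = _censored_set(x, 0.15)
    r1 = fit_censored_lognormal_mixture_map(
        data, init=(0.5, np.array([-1.5, 2.5]), np.array([0.6, 0.6]))
    )
    r2 = fit_censored_lognormal_mixture_map(
        data, init=(0.5, np.array([2.5, -1.5]), np.array([0.6, 0.6]))
    )
    assert np.isclose(r1.params.component1.meanlog, r2.params.component1.meanlog, atol=1e-4)
    assert np.isclose(r1.params.w, r2.params.w, atol=1e-4)


def test_mixture_collapses_to_single_component_under_prior(rng):
    """A weight prior with essentially all mass at 1 reduces the mixture to
    the single censored lognormal fit."""
    x = rng.lognormal(0.5, 0.7, 400)
    data = _censored_set(x, np.quantile(x, 0.2))
    single = fit_censored_lognormal(data)
    res = fit_censored_lognormal_mixture_map(
        data, priors=MixturePriors(w_a=1e6, w_b=1.0), max_iter=2000
    )
    w1 = res.params.w
    dominant = res.params.component1 if w1 > 0.5 else res.params.component2
    assert max(w1, 1 - w1) > 0.999
    assert abs(dominant.meanlog - single.meanlog) < 0.05
    assert abs(dominant.sdlog - single.sdlog) < 0.05


# ------------------------ bodyweight regression ---------------------------


def test_regression_recovery_from_synthetic_population():
    truth = GroundTruth()
    survey = gen_consumption_survey(3000, truth, seed=21)
    fit = fit_bodyweight_regression(survey)
    reg = truth.regression
    # 3-SE-scale tolerance on each coefficient (SEs are sub-unit at n=3000)
    assert abs(fit.beta_sex - reg.beta_sex) < 2.0
    assert abs(fit.beta_age - reg.beta_age) < 0.15
    assert abs(fit.beta_logage - reg.beta_logage) < 5.0
    assert abs(fit.residual_sd - reg.residual_sd) < 1.0


def test_regression_exact_on_noiseless_data(rng):
    import pandas as pd

    n = 200
    sex = rng.integers(1, 3, n)
    age = rng.integers(16, 76, n)
    w = -14.476 * sex - 0.829 * age + 36.406 * np.log(age)
    df = pd.DataFrame({"sex": sex, "age": age, "bodyweight": w})
    fit = fit_bodyweight_regression(df)
    assert np.allclose(
        [fit.beta_sex, fit.beta_age, fit.beta_logage],
        [-14.476, -0.829, 36.406],
        atol=1e-8,
    )


def test_regression_single_sex_warns(rng):
    import pandas as pd

    n = 100
    age = rng.integers(16, 76, n)
    w = -14.476 - 0.829 * age + 36.406 * np.log(age) + rng.normal(0, 5, n)
    df = pd.DataFrame({"sex": np.ones(n, dtype=int), "age": age, "bodyweight": w})
    with pytest.warns(UserWarning):
        fit_bodyweight_regression(df)


def test_predict_bodyweight_plugin_values():
    reg = BodyweightRegression()
    man = predict_bodyweight(reg, P.MALE, 40, 0.0)
    woman = predict_bodyweight(reg, P.FEMALE, 40, 0.0)
    assert abs(man - 86.67) < 0.01
    assert abs(woman - 72.19) < 0.01
    assert np.isclose(
        predict_bodyweight(reg, 1, 40, 1.0) - man, reg.residual_sd, atol=1e-12
    )


@pytest.mark.parametrize(
    "sex, weight, expected",
    [
        (P.MALE, 76.0, "low"),
        (P.MALE, 80.5, "medium"),
        (P.MALE, 88.0, "high"),
        (P.FEMALE, 62.4, "low"),
        (P.FEMALE, 73.0, "high"),
        (P.FEMALE, 67.0, "medium"),
    ],
)
def test_weight_class_banding(sex, weight, expected):
    assert assign_weight_class(sex, weight) == expected
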
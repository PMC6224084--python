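"""Risk engine: conversion factors, dimension separation, 2D Monte Carlo
collapse to the deterministic composition, and summaries."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bbqrisk import params as P
from bbqrisk.doseresponse import TwoStageParams, two_stage_extra_risk
from bbqrisk.exposure import simulate_subgroups
from bbqrisk.params import ConversionFactorConfig
from bbqrisk.risk import (
    UncertaintySample,
    allometric_cf,
    animal_dose,
    events_to_exceed,
    run_2dmc_population,
    run_2dmc_subgroups,
    sample_gsd_intra,
    summarize_uncertainty,
)

CFG = ConversionFactorConfig()


def _degenerate_u(n=1, gsd=1.0 + 1e-12, b=29089.6, c=8.925):
    return UncertaintySample(
        ap=np.full(n, CFG.ap_mean),
        cf_tktd=np.ones(n),
        gsd_intra=np.full(n, gsd),
        b=np.full(n, b),
        c=np.full(n, c),
    )


def test_allometric_factor():
    assert np.isclose(allometric_cf(76.0, 0.03, 0.7), 10.50, atol=0.01)
    assert allometric_cf(76.0, 0.03, 1.0) == 1.0
    assert allometric_cf(96.0, 0.03, 0.7) > allometric_cf(71.0, 0.03, 0.7)
    with pytest.raises(ValueError):
        allometric_cf(-1.0, 0.03, 0.7)


def test_gsd_uncertainty_mapping():
    assert np.isclose(sample_gsd_intra(CFG, 21.0), 3.6, rtol=1e-12)
    assert np.isclose(sample_gsd_intra(CFG, 1e12), 1.0, atol=1e-5)
    rng = np.random.default_rng(3)
    draws = sample_gsd_intra(CFG, rng.chisquare(21, 100_000))
    expected_median = 3.6 ** np.sqrt(21 / stats.chi2.median(21))
    assert abs(np.median(draws) - expected_median) < 0.02


def test_animal_dose_arithmetic():
    assert animal_dose(0.0, 1.3, 0.7, 1.0, 3.6, CFG) == 0.0
    d = animal_dose(0.07, 0.0, 0.7, 1.0, 3.6, CFG)
    assert np.isclose(d, 0.735, atol=0.001)
    hi = animal_dose(1.0, 1.0, 0.7, 1.0, 3.6, CFG)
    lo = animal_dose(1.0, -1.0, 0.7, 1.0, 3.6, CFG)
    assert np.isclose(hi / lo, 3.6**2, rtol=1e-10)


def test_2dmc_collapses_to_deterministic_composition(population_small):
    """With all uncertain quantities fixed at central values, the 2D MC is
    the plain exposure -> animal dose -> extra risk mapping, element-wise."""
    u = _degenerate_u()
    surf = run_2dmc_population(
        population_small, CFG, n_unc=1, seed=0, uncertainty=u, keep_matrix=True
    )
    y = population_small["exposure"].to_numpy()
    z = population_small["z"].to_numpy()
    direct = two_stage_extra_risk(
        animal_dose(y, z, CFG.ap_mean, 1.0, u.gsd_intra[0], CFG),
        TwoStageParams(b=29089.6, c=8.925),
    )
    assert np.allclose(surf.matrix[0], direct, rtol=1e-12)
    assert surf.mean_risk[0] == pytest.approx(direct.mean(), rel=1e-12)


def test_zero_exposure_stays_zero_risk(population_small):
    surf = run_2dmc_population(population_small, CFG, n_unc=5, seed=4, keep_matrix=True)
    zero = population_small["exposure"].to_numpy() == 0
    assert (surf.matrix[:, zero] == 0).all()
    assert ((surf.matrix >= 0) & (surf.matrix < 1)).all()
    # per-iteration mean is exactly the row average
    assert np.allclose(surf.mean_risk, surf.matrix.mean(axis=1), rtol=1e-15)


def test_variability_dimension_untouched_by_uncertainty_seed(population_small):
    before = population_small[["exposure", "z"]].copy()
    run_2dmc_population(population_small, CFG, n_unc=10, seed=1)
    run_2dmc_population(population_small, CFG, n_unc=10, seed=999)
    pd.testing.assert_frame_equal(population_small[["exposure", "z"]], before)


def test_rank_preservation_with_shared_uncertainty(population_small):
    u = _degenerate_u(n=3, gsd=2.0)
    surf = run_2dmc_population(
        population_small, CFG, n_unc=3, seed=0, uncertainty=u, keep_matrix=True
    )
    order = np.argsort(surf.matrix[0], kind="stable")
    for row in surf.matrix[1:]:
        assert np.array_equal(np.argsort(row, kind="stable"), order)


def test_doubled_exposure_raises_every_iteration(population_small):
    doubled = population_small.copy()
    doubled["exposure"] = 2 * doubled["exposure"]
    a = run_2dmc_population(population_small, CFG, n_unc=50, seed=7, keep_matrix=False)
    b = run_2dmc_population(doubled, CFG, n_unc=50, seed=7, keep_matrix=False)
    assert (b.mean_risk > a.mean_risk).all()


def test_uncertainty_interval_widens_with_tktd_spread(population_small):
    wide_cfg = dataclasses.replace(CFG, gsd_tktd=4.0)
    a = run_2dmc_population(population_small, CFG, n_unc=300, seed=5, keep_matrix=False)
    b = run_2dmc_population(population_small, wide_cfg, n_unc=300, seed=5, keep_matrix=False)
    sa, sb = summarize_uncertainty(a), summarize_uncertainty(b)
    assert (sb["p97.5"] / sb["p2.5"]) > (sa["p97.5"] / sa["p2.5"])


def test_subgroups_identical_under_equal_inputs(cfg):
    """Two subgroups fed identical exposures, quantiles and bodyweights get
    identical risk surfaces because the uncertainty draws are shared."""
    sub = simulate_subgroups(5, 200, cfg, seed=8)
    sub.exposure[1] = sub.exposure[0]
    sub.z[1] = sub.z[0]
    sub.bodyweights[:] = 76.0
    mr = run_2dmc_subgroups(sub, CFG, n_unc=20, seed=2)
    assert np.array_equal(mr[:, 0], mr[:, 1])


def test_subgroup_mean_risk_monotone_in_events(cfg):
    sub = simulate_subgroups(15, 300, cfg, seed=9)
    mr = run_2dmc_subgroups(sub, CFG, n_unc=30, seed=3)
    assert (np.diff(mr, axis=-1) >= 0).all()


def test_lighter_subgroup_has_smaller_allometric_factor():
    ap = 0.7
    assert allometric_cf(58.0, 0.03, ap) < allometric_cf(96.0, 0.03, ap)


def test_events_to_exceed_definitions():
    b_values = np.arange(1, 41)
    base = np.linspace(1e-6, 4e-5, 40)  # crosses 2.45e-5 between B=25 and 26
    mean_risk = np.tile(base, (30, 2, 3, 1))
    out = events_to_exceed(mean_risk, b_values, threshold=base[24], statistic="median")
    assert (out["events"] == 26).all()
    out0 = events_to_exceed(mean_risk, b_values, threshold=0.0, statistic="median")
    assert (out0["events"] == 1).all()
    rng = np.random.default_rng(1)
    noisy = mean_risk * rng.lognormal(0, 1, (30, 1, 1, 1))
    med = events_to_exceed(noisy, b_values, 2e-5, "median")["events"]
    hi = events_to_exceed(noisy, b_values, 2e-5, "p97.5")["events"]
    assert (hi <= med).all()
    with pytest.raises(ValueError):
        events_to_exceed(np.empty((0, 2, 3, 0)), np.empty(0), 0.1)


def test_summary_properties():
    const = np.full(100, 3e-5)
    s = summarize_uncertainty(const)
    assert s["median"] == s["p2.5"] == s["p97.5"] == 3e-5
    rng = np.random.default_rng(2)
    draws = rng.lognormal(-9.0, 0.8, 200_000)
    s = summarize_uncertainty(draws, population_size=1_000_000)
    assert np.isclose(s["median"], np.exp(-9.0), rtol=0.02)
    assert np.isclose(s["p97.5"], np.exp(-9.0 + 1.96 * 0.8), rtol=0.03)
    assert np.isclose(s["expected_cases_median"], s["median"] * 1e6, rtol=1e-12)
    perm = rng.permutation(draws)
    assert summarize_uncertainty(perm)["median"] == s["median"]
    with pytest.raises(ValueError):
        summarize_uncertainty(np.array([1e-5]))
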
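"""Event-based exposure simulation: samplers, the yearly-intake identity,
population and subgroup structure."""

import dataclasses
import math

import numpy as np
import pytest

from bbqrisk import params as P
from bbqrisk.exposure import (
    Individual,
    sample_frequency_scenario,
    sample_meal_composition,
    simulate_population,
    simulate_subgroups,
    simulate_yearly_exposure,
)
from bbqrisk.params import ComboRow, GammaParams, LognormalParams, PipelineConfig


def _point_mass_config(amount_g=200.0, conc=5.0, meat="beef"):
    """Config with near-degenerate amount and concentration distributions."""
    gp = GammaParams(shape=1e8, rate=1e8 / amount_g)  # cv 1e-4
    cp = {m: LognormalParams(math.log(conc), 1e-9) for m in P.MEAT_TYPES}
    combo = (ComboRow((meat,), (1.0,), 1.0),)
    return PipelineConfig(
        gamma_params={k: gp for k in P.DEFAULT_GAMMA_PARAMS},
        concentration_params=cp,
        combo_table=combo,
    )


def test_frequency_scenario_matches_fractions(rng):
    draws = sample_frequency_scenario(P.FREQUENCY_FRACTIONS, rng, size=10_000)
    se = np.sqrt(0.04 * 0.96 / 10_000)
    assert abs((draws == 0).mean() - 0.040) < 3 * se
    assert abs(draws.mean() - 28.88) < 3 * 18.0 / np.sqrt(10_000)
    assert (sample_frequency_scenario((0, 0, 0, 1), rng, size=100) == 63).all()
    with pytest.raises(ValueError):
        sample_frequency_scenario((0.9, 0.2, 0, 0), rng)


def test_meal_composition_single_row(rng):
    combo = (ComboRow(("beef",), (1.0,), 1.0),)
    mc = sample_meal_composition(combo, rng)
    assert mc.meats == ("beef",) and mc.fractions == (1.0,)
    with pytest.raises(ValueError):
        sample_meal_composition((), rng)


def test_meal_composition_frequencies_match_multinomial_oracle(cfg, rng):
    n = 50_000
    counts = {row.meats: 0 for row in cfg.combo_table}
    for _ in range(n):
        mc = sample_meal_composition(cfg.combo_table, rng)
        counts[mc.meats] += 1
    for row in cfg.combo_table:
        p = row.probability
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts[row.meats] / n - p) < 4 * se


def test_yearly_exposure_zero_events(cfg, rng):
    ind = Individual(0, P.MALE, 40, 80.0, "medium", 0, 0.0)
    res = simulate_yearly_exposure(
        ind, cfg.gamma_params, cfg.concentration_params, cfg.combo_table, rng
    )
    assert res.exposure == 0.0


def test_yearly_exposure_point_mass_arithmetic(rng):
    """One event, 200 g at 5 ug/kg eaten by a 76 kg person:
    y = 0.2 * 5 / 76."""
    cfg = _point_mass_config()
    ind = Individual(0, P.MALE, 40, 76.0, "low", 1, 0.0)
    res = simulate_yearly_exposure(
        ind, cfg.gamma_params, cfg.concentration_params, cfg.combo_table, rng
    )
    assert np.isclose(res.exposure, 0.2 * 5.0 / 76.0, rtol=1e-3)


def test_yearly_exposure_inverse_bodyweight_scaling(cfg):
    r1 = np.random.default_rng(5)
    r2 = np.random.default_rng(5)
    a = simulate_yearly_exposure(
        Individual(0, P.MALE, 40, 70.0, "low", 9, 0.0),
        cfg.gamma_params, cfg.concentration_params, cfg.combo_table, r1,
    )
    b = simulate_yearly_exposure(
        Individual(0, P.MALE, 40, 140.0, "low", 9, 0.0),
        cfg.gamma_params, cfg.concentration_params, cfg.combo_table, r2,
    )
    assert np.isclose(a.exposure, 2 * b.exposure, rtol=1e-12)


def test_population_nonzero_iff_events(cfg):
    pop = simulate_population(3000, cfg, seed=17)
    assert ((pop["exposure"] > 0) == (pop["b_events"] > 0)).all()
    assert pop["exposure"].mean() > pop["exposure"].median()  # right skew


def test_population_all_in_zero_scenario(cfg):
    zero_cfg = dataclasses.replace(cfg, frequency_fractions=(1.0, 0.0, 0.0, 0.0))
    pop = simulate_population(200, zero_cfg, seed=1)
    assert (pop["exposure"] == 0).all()


def test_population_missing_meat_parameters_raises(cfg):
    bad = dataclasses.replace(
        cfg,
        concentration_params={
            k: v for k, v in cfg.concentration_params.items() if k != "pork"
        },
    )
    with pytest.raises(ValueError, match="pork"):
        simulate_population(10, bad, seed=1)


def test_exposure_scale_equivariance(cfg):
    """Multiplying every concentration by k multiplies every exposure by k
    under matched seeds."""
    k = 3.0
    scaled = {}
    for meat, model in cfg.concentration_params.items():
        if hasattr(model, "w"):
            scaled[meat] = dataclasses.replace(
                model,
                component1=dataclasses.replace(
                    model.component1, meanlog=model.component1.meanlog + math.log(k)
                ),
                component2=dataclasses.replace(
                    model.component2, meanlog=model.component2.meanlog + math.log(k)
                ),
            )
        else:
            scaled[meat] = dataclasses.replace(model, meanlog=model.meanlog + math.log(k))
    cfg2 = dataclasses.replace(cfg, concentration_params=scaled)
    a = simulate_population(500, cfg, seed=23)
    b = simulate_population(500, cfg2, seed=23)
    assert np.allclose(b["exposure"], k * a["exposure"], rtol=1e-10)


def test_subgroup_exposure_linear_in_events(cfg):
    sub = simulate_subgroups(40, 400, cfg, seed=2)
    means = sub.exposure.mean(axis=-1)  # (2, 3, B)
    assert (np.diff(means, axis=-1) > 0).all()
    b = sub.b_values.astype(float)
    for si in range(2):
        for ci in range(3):
            r = np.corrcoef(b, means[si, ci])[0, 1]
            assert r**2 > 0.99


def test_subgroup_bodyweight_ratio_with_equal_consumption(cfg):
    """With identical gammas across classes, per-event mean exposure of
    men-low vs men-high is the inverse bodyweight ratio 96/71."""
    gp = cfg.gamma_params[(P.MALE, "low")]
    eq = dataclasses.replace(cfg, gamma_params={k: gp for k in cfg.gamma_params})
    sub = simulate_subgroups(30, 3000, eq, seed=3)
    pe = sub.per_event_mean()
    ratio = pe[0, 0] / pe[0, 2]
    assert abs(ratio - 96.0 / 71.0) < 0.06


def test_subgroup_first_event_mean_matches_independence_product(cfg):
    """At one event per year the subgroup mean equals
    E[amount_kg] x E[concentration] / median bodyweight."""
    sub = simulate_subgroups(1, 20_000, cfg, seed=4)
    mean_conc = 0.0
    for row in cfg.combo_table:
        for meat, frac in zip(row.meats, row.fractions):
            mean_conc += row.probability * frac * cfg.concentration_params[meat].mean
    si, ci = 0, 0
    gp = cfg.gamma_params[(P.MALE, "low")]
    expected = (gp.mean / 1000.0) * mean_conc / 71.0
    observed = sub.exposure[si, ci, 0, :]
    se = observed.std() / np.sqrt(observed.size)
    assert abs(observed.mean() - expected) < 3 * se
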
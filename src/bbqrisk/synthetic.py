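"""Synthetic survey-shaped data with known ground truth.

The original surveys behind the exposure model (a national 7-day dietary
record, barbecued-meat monitoring samples, a household barbecue-frequency
survey and a mouse tumour study) are not publicly deposited.  This module
generates datasets of exactly those shapes from known parameters, so every
downstream fitting and simulation stage can be tested end to end: fit the
generated data, recover the generating parameters.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import params as P
from .params import (
    BodyweightRegression,
    ConcentrationModel,
    GammaParams,
    LognormalParams,
    MixtureLognormalParams,
)


@dataclass
class GroundTruth:
    """Generating parameters for every synthetic dataset."""

    gamma_params: dict[tuple[int, str], GammaParams] = field(
        default_factory=lambda: dict(P.DEFAULT_GAMMA_PARAMS)
    )
    concentration_params: dict[str, ConcentrationModel] = field(
        default_factory=lambda: dict(P.DEFAULT_CONCENTRATION_PARAMS)
    )
    regression: BodyweightRegression = field(default_factory=BodyweightRegression)
    frequency_fractions: tuple[float, ...] = P.FREQUENCY_FRACTIONS
    dose_response_b: float = P.B_SUMMARY_POPULATION.median
    dose_response_c: float = P.C_SUMMARY_POPULATION.median
    mean_dinners_per_person: float = 7.0
    age_range: tuple[int, int] = P.DEFAULT_AGE_RANGE
    male_fraction: float = P.DEFAULT_MALE_FRACTION

    def validate(self) -> None:
        if abs(sum(self.frequency_fractions) - 1.0) > 1e-9:
            raise ValueError("frequency fractions must sum to 1")
        if self.dose_response_b <= 0 or self.dose_response_c < 0:
            raise ValueError("dose-response parameters out of range")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male fraction must be a probability")


def sample_demographics(
    n: int, truth: GroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sexes (1/2) and integer ages for ``n`` individuals."""
    sex = np.where(rng.random(n) < truth.male_fraction, P.MALE, P.FEMALE)
    lo, hi = truth.age_range
    age = rng.integers(lo, hi + 1, size=n)
    return sex, age


def sample_bodyweight(
    sex: np.ndarray,
    age: np.ndarray,
    reg: BodyweightRegression,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bodyweights from the sex/age regression with normal residuals;
    draws at or below the plausibility floor are resampled."""
    mean = reg.mean(sex, age)
    w = mean + reg.residual_sd * rng.standard_normal(mean.shape)
    bad = w <= P.MIN_BODYWEIGHT_KG
    while np.any(bad):
        w[bad] = mean[bad] + reg.residual_sd * rng.standard_normal(int(bad.sum()))
        bad = w <= P.MIN_BODYWEIGHT_KG
    return w


def gen_consumption_survey(
    n_individuals: int, truth: GroundTruth, seed: int
) -> pd.DataFrame:
    """Dinner-level meat consumption survey.

    Returns one row per (person, dinner): person_id, sex, age, bodyweight,
    weight_class, meat_type, amount_g.  Amounts are drawn from the gamma of
    the person's sex x weight class; the meat type label is drawn uniformly
    (the label does not affect the class-specific amount model).
    """
    from .fitting import assign_weight_class

    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    truth.validate()
    rng = np.random.default_rng(seed)

    sex, age = sample_demographics(n_individuals, truth, rng)
    weight = sample_bodyweight(sex, age, truth.regression, rng)
    wclass = np.array([assign_weight_class(s, w) for s, w in zip(sex, weight)])
    n_dinners = 1 + rng.poisson(truth.mean_dinners_per_person - 1.0, n_individuals)

    rows = []
    for i in range(n_individuals):
        gp = truth.gamma_params[(int(sex[i]), wclass[i])]
        amounts = rng.gamma(gp.shape, gp.scale, size=n_dinners[i])
        meats = rng.choice(P.MEAT_TYPES, size=n_dinners[i])
        for m, a in zip(meats, amounts):
            if a <= 0:  # only dinners with non-zero consumption are retained
                continue
            rows.append((i, int(sex[i]), int(age[i]), float(weight[i]), wclass[i], m, float(a)))
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "sex",
            "age",
            "bodyweight",
            "weight_class",
            "meat_type",
            "amount_g",
        ],
    )


def _draw_concentration(
    model: ConcentrationModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(model, MixtureLognormalParams):
        pick1 = rng.random(n) < model.w
        out = np.empty(n)
        out[pick1] = rng.lognormal(
            model.component1.meanlog, model.component1.sdlog, int(pick1.sum())
        )
        out[~pick1] = rng.lognormal(
            model.component2.meanlog, model.component2.sdlog, int((~pick1).sum())
        )
        return out
    return rng.lognormal(model.meanlog, model.sdlog, n)


def gen_concentration_samples(
    n_per_type: int,
    truth: GroundTruth,
    lod_values,
    seed: int,
    meat_types=P.MEAT_TYPES,
) -> pd.DataFrame:
    """Left-censored concentration samples per meat type.

    Each sample draws a true concentration from the type's (mixture)
    lognormal and a limit of detection uniformly from ``lod_values``; draws
    below their LOD are reported censored, carrying the LOD but no value.

    Columns: meat_type, value (NaN if censored), lod, censored.
    """
    lod_values = np.asarray(lod_values, dtype=float)
    if lod_values.size == 0 or np.any(lod_values <= 0):
        raise ValueError("lod_values must be non-empty and positive")
    truth.validate()
    rng = np.random.default_rng(seed)

    frames = []
    for meat in meat_types:
        true_c = _draw_concentration(truth.concentration_params[meat], n_per_type, rng)
        lod = rng.choice(lod_values, size=n_per_type)
        censored = true_c < lod
        value = np.where(censored, np.nan, true_c)
        frames.append(
            pd.DataFrame(
                {"meat_type": meat, "value": value, "lod": lod, "censored": censored}
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_frequency_survey(n_households: int, fractions, seed: int) -> np.ndarray:
    """Annual barbecue-event counts for households, multinomial over the
    four frequency scenarios."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (len(P.FREQUENCY_EVENTS),) or abs(fractions.sum() - 1) > 1e-9:
        raise ValueError("fractions must be a probability vector over the scenarios")
    if np.any(fractions < 0):
        raise ValueError("fractions must be non-negative")
    if n_households < 1:
        raise ValueError("n_households must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice(np.asarray(P.FREQUENCY_EVENTS), size=n_households, p=fractions)


def gen_dose_response_study(
    doses, n_per_dose: int, truth_b: float, truth_c: float, seed: int
) -> pd.DataFrame:
    """Quantal tumour study: counts ~ Binomial(n, ER(dose; b, c)), zero
    background.  Columns: dose, n, n_tumor."""
    from .doseresponse import TwoStageParams, two_stage_extra_risk

    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be >= 1")
    rng = np.random.default_rng(seed)
    p = two_stage_extra_risk(doses, TwoStageParams(b=truth_b, c=truth_c))
    n_tumor = rng.binomial(n_per_dose, p)
    return pd.DataFrame({"dose": doses, "n": n_per_dose, "n_tumor": n_tumor})


#: dose grid of the default synthetic tumour study, spanning low to
#: near-saturating response under the central two-stage parameters.
DEFAULT_STUDY_DOSES: tuple[float, ...] = (0.0, 1000.0, 3000.0, 10000.0, 30000.0)
DEFAULT_STUDY_N_PER_DOSE: int = 48
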
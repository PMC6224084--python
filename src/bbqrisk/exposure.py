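"""Event-based yearly exposure simulation.

For individual i with bodyweight w_i (kg) and B_i barbecue events per year,
the yearly intake rate of the contaminant is

    y_i = (1 / w_i) * sum_b sum_k  x_ibk * c_ibk      [ug/kg bw/year]

where event b involves K_ib (1 or 2) meat types, x_ibk is the amount of
type k eaten at that event (kg; a single gamma-distributed total amount is
split by the meal-composition shares) and c_ibk its contaminant
concentration (ug/kg), drawn i.i.d. from the type's (mixture) lognormal.

Amounts are carried in g everywhere and converted to kg only here, where
x * c is formed, to keep the unit change in one visible place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import params as P
from ._rng import rng_stream
from .fitting import assign_weight_class
from .params import MixtureLognormalParams, PipelineConfig
from .synthetic import _draw_concentration, sample_bodyweight, sample_demographics


@dataclass(frozen=True)
class Individual:
    person_id: int
    sex: int
    age: int
    bodyweight: float
    weight_class: str
    b_events: int
    z: float  # standard-normal sensitivity quantile, fixed across uncertainty

    def __post_init__(self):
        if self.bodyweight <= 0:
            raise ValueError("bodyweight must be positive")
        if not 0 <= self.b_events <= 365:
            raise ValueError("annual events must lie in [0, 365]")
        if not np.isfinite(self.z):
            raise ValueError("sensitivity quantile must be finite")


@dataclass(frozen=True)
class MealComposition:
    meats: tuple[str, ...]
    fractions: tuple[float, ...]


@dataclass
class ExposureResult:
    exposure: float  # ug/kg bw/year
    per_event: np.ndarray | None = None


def sample_frequency_scenario(fractions, rng, size=None, events=P.FREQUENCY_EVENTS):
    """Annual event count(s) drawn from the frequency scenarios."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (len(events),) or np.any(fractions < 0):
        raise ValueError("fractions must be a probability vector over the scenarios")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    draw = rng.choice(np.asarray(events), size=size, p=fractions)
    return draw


def sample_meal_composition(combo_table, rng) -> MealComposition:
    """One categorical draw over the meal-composition table rows."""
    if not combo_table:
        raise ValueError("combo table must be non-empty")
    probs = np.array([row.probability for row in combo_table])
    idx = rng.choice(len(combo_table), p=probs / probs.sum())
    row = combo_table[idx]
    return MealComposition(meats=row.meats, fractions=row.fractions)


def draw_event_intakes(
    n_events: int, gamma, concentration_params, combo_table, rng
) -> np.ndarray:
    """Contaminant intake (ug) of ``n_events`` independent events for one
    sex x weight-class gamma: total amount drawn per event, split across the
    event's meat types, each multiplied by a fresh concentration draw."""
    if n_events == 0:
        return np.empty(0)
    for row in combo_table:
        for meat in row.meats:
            if meat not in concentration_params:
                raise KeyError(f"no concentration parameters for meat type {meat!r}")
    amounts_g = rng.gamma(gamma.shape, gamma.scale, size=n_events)
    probs = np.array([row.probability for row in combo_table])
    row_idx = rng.choice(len(combo_table), size=n_events, p=probs / probs.sum())
    intake = np.zeros(n_events)
    for r, row in enumerate(combo_table):
        mask = row_idx == r
        m = int(mask.sum())
        if m == 0:
            continue
        for meat, frac in zip(row.meats, row.fractions):
            conc = _draw_concentration(concentration_params[meat], m, rng)
            intake[mask] += (amounts_g[mask] / 1000.0) * frac * conc
    return intake


def simulate_yearly_exposure(
    ind: Individual,
    gamma_params,
    concentration_params,
    combo_table,
    rng,
    keep_events: bool = False,
) -> ExposureResult:
    """Yearly exposure of one individual; exactly zero iff B_i = 0."""
    gamma = gamma_params[(ind.sex, ind.weight_class)]
    per_event = draw_event_intakes(
        ind.b_events, gamma, concentration_params, combo_table, rng
    )
    y = float(per_event.sum() / ind.bodyweight)
    return ExposureResult(exposure=y, per_event=per_event if keep_events else None)


def simulate_population(
    n: int, config: PipelineConfig, seed: int | None = None
) -> pd.DataFrame:
    """Simulated national population with per-individual yearly exposure.

    Demographics -> bodyweight regression -> weight class -> frequency
    scenario -> event-level intakes, each from its own named seed substream,
    so e.g. changing the uncertainty iteration count elsewhere never alters
    these draws.  Returns one row per individual with columns person_id,
    sex, age, bodyweight, weight_class, b_events, z, exposure.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    seed = config.seed if seed is None else seed

    from .synthetic import GroundTruth

    truth = GroundTruth(regression=config.regression)
    rng_demo = rng_stream(seed, "demographics")
    sex, age = sample_demographics(n, truth, rng_demo)
    weight = sample_bodyweight(sex, age, config.regression, rng_demo)
    wclass = np.array([assign_weight_class(s, w) for s, w in zip(sex, weight)])

    rng_freq = rng_stream(seed, "frequency")
    b_events = sample_frequency_scenario(
        config.frequency_fractions, rng_freq, size=n, events=config.frequency_events
    )
    z = rng_stream(seed, "sensitivity").standard_normal(n)

    rng_exp = rng_stream(seed, "exposure")
    person_of_event = np.repeat(np.arange(n), b_events)
    intake = np.zeros(person_of_event.size)
    cell_code = (sex - 1) * 3 + np.array(
        [P.WEIGHT_CLASSES.index(w) for w in wclass]
    )
    event_cell = cell_code[person_of_event]
    for code in range(6):
        mask = event_cell == code
        m = int(mask.sum())
        if m == 0:
            continue
        s = P.SEXES[code // 3]
        wc = P.WEIGHT_CLASSES[code % 3]
        intake[mask] = draw_event_intakes(
            m,
            config.gamma_params[(s, wc)],
            config.concentration_params,
            config.combo_table,
            rng_exp,
        )
    exposure = np.bincount(person_of_event, weights=intake, minlength=n) / weight

    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": sex,
            "age": age,
            "bodyweight": weight,
            "weight_class": wclass,
            "b_events": b_events,
            "z": z,
            "exposure": exposure,
        }
    )


@dataclass
class SubgroupExposures:
    """Exposure of "typical" individuals of each sex x weight class as a
    function of annual events.

    ``exposure`` is indexed (sex, weight_class, B, replicate) with B running
    1..b_max; each replicate accumulates its own event stream, so a
    replicate's exposure is exactly its cumulative intake divided by the
    class-median bodyweight (common random numbers across the B grid).
    ``z`` carries each replicate's fixed sensitivity quantile; replicate r
    shares its quantile across the six cells, again as common random
    numbers, so subgroup contrasts are not blurred by independent
    sensitivity noise.
    """

    exposure: np.ndarray
    z: np.ndarray
    b_values: np.ndarray
    bodyweights: np.ndarray  # (sex, class) median bodyweights used

    def per_event_mean(self) -> np.ndarray:
        """Mean per-event exposure by subgroup (ug/kg bw per event)."""
        return self.exposure[:, :, -1, :].mean(axis=-1) / self.b_values[-1]


def simulate_subgroups(
    b_max: int, n_per_cell: int, config: PipelineConfig, seed: int | None = None
) -> SubgroupExposures:
    """Subgroup exposure grid: six sex x weight-class cells, annual events
    B = 1..b_max, ``n_per_cell`` replicates each, bodyweight fixed at the
    class median."""
    if n_per_cell < 1 or b_max < 1:
        raise ValueError("n_per_cell and b_max must be >= 1")
    config.validate()
    seed = config.seed if seed is None else seed
    rng = rng_stream(seed, "subgroup_exposure")

    exposure = np.empty((2, 3, b_max, n_per_cell))
    bodyweights = np.empty((2, 3))
    for si, s in enumerate(P.SEXES):
        for ci, wc in enumerate(P.WEIGHT_CLASSES):
            w_med = P.WEIGHT_CLASS_MEDIANS[(s, wc)]
            bodyweights[si, ci] = w_med
            intakes = draw_event_intakes(
                b_max * n_per_cell,
                config.gamma_params[(s, wc)],
                config.concentration_params,
                config.combo_table,
                rng,
            ).reshape(b_max, n_per_cell)
            exposure[si, ci] = np.cumsum(intakes, axis=0) / w_med
    z_shared = rng_stream(seed, "sensitivity").standard_normal(n_per_cell)
    z = np.broadcast_to(z_shared, (2, 3, n_per_cell)).copy()
    return SubgroupExposures(
        exposure=exposure,
        z=z,
        b_values=np.arange(1, b_max + 1),
        bodyweights=bodyweights,
    )
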
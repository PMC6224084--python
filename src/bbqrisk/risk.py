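"""Human-to-animal dose conversion and the two-dimensional Monte Carlo.

The yearly human exposure y_i (ug/kg bw) is converted to an
animal-equivalent dose

    d_i = y_i * CF_intra,i * CF_inter,allometric * CF_inter,TKTD

and pushed through the two-stage model to an extra lifetime risk.  The
simulation keeps two dimensions strictly separated:

* variability — the fixed roster of individuals: exposure y_i and
  sensitivity quantile z_i (CF_intra,i = GSD^z_i, geometric mean 1) never
  change across uncertainty iterations;
* uncertainty — per iteration u one draw of the intraspecies GSD
  (chi-squared uncertainty on the log-scale SD), the allometric power AP,
  the TKTD factor, and the two-stage parameters (b, c).

Each uncertainty iteration therefore yields one plausible risk value per
individual; averaging over individuals gives the per-iteration mean risk,
whose distribution over iterations is the uncertainty of the population
mean risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import params as P
from ._rng import rng_stream
from .doseresponse import ParamUncertainty, sample_from_percentiles
from .params import ConversionFactorConfig, PercentileSummary


def allometric_cf(bw_human: float, bw_animal: float, ap) -> float | np.ndarray:
    """Allometric interspecies factor (bw_human / bw_animal)^(1 - AP)."""
    if bw_human <= 0 or bw_animal <= 0:
        raise ValueError("bodyweights must be positive")
    return (bw_human / bw_animal) ** (1.0 - np.asarray(ap))


def sample_gsd_intra(config: ConversionFactorConfig, chi2_draw) -> float | np.ndarray:
    """Uncertain intraspecies GSD: GSD0^sqrt(df / chi2).

    A chi-squared draw at its df reproduces GSD0; an infinite draw collapses
    the sensitivity variability entirely (GSD -> 1).
    """
    chi2_draw = np.asarray(chi2_draw, dtype=float)
    if np.any(chi2_draw <= 0):
        raise ValueError("chi-squared draw must be positive")
    out = config.gsd_intra0 ** np.sqrt(config.df / chi2_draw)
    return out if out.ndim else float(out)


@dataclass
class UncertaintySample:
    """One draw (or a vector of draws) of everything that is uncertain."""

    ap: np.ndarray
    cf_tktd: np.ndarray
    gsd_intra: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def n(self) -> int:
        return int(np.asarray(self.ap).size)


def draw_uncertainty(
    n_unc: int,
    config: ConversionFactorConfig,
    rng,
    b_summary: PercentileSummary | None = None,
    c_summary: PercentileSummary | None = None,
    param_uncertainty: ParamUncertainty | None = None,
) -> UncertaintySample:
    """The uncertainty stream: AP (normal), TKTD factor (lognormal, GM 1),
    intraspecies GSD (chi-squared on the log-scale SD) and (b, c).

    (b, c) come either jointly from an empirical bootstrap sample or
    independently from two percentile-matched two-piece lognormals (the
    published summaries do not carry their correlation).
    """
    ap = rng.normal(config.ap_mean, config.ap_sd, n_unc)
    cf_tktd = rng.lognormal(np.log(config.gm_tktd), np.log(config.gsd_tktd), n_unc)
    gsd = sample_gsd_intra(config, rng.chisquare(config.df, n_unc))
    if param_uncertainty is not None:
        idx = rng.integers(0, param_uncertainty.n, n_unc)
        b, c = param_uncertainty.b[idx], param_uncertainty.c[idx]
    else:
        if b_summary is None or c_summary is None:
            raise ValueError("need either bootstrap draws or percentile summaries")
        b = sample_from_percentiles(b_summary, n_unc, rng)
        c = sample_from_percentiles(c_summary, n_unc, rng)
    return UncertaintySample(ap=ap, cf_tktd=cf_tktd, gsd_intra=gsd, b=b, c=c)


def animal_dose(y, z, u_ap, u_tktd, u_gsd, config: ConversionFactorConfig, bw_human=None):
    """Animal-equivalent dose for exposure(s) y with sensitivity quantile(s)
    z under one uncertainty draw."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("exposure must be non-negative")
    bw = config.bw_human if bw_human is None else bw_human
    cf_intra = config.gm_intra * np.asarray(u_gsd) ** np.asarray(z)
    return y * cf_intra * allometric_cf(bw, config.bw_animal, u_ap) * u_tktd


def _er(dose, b, c):
    q = dose / b
    return -np.expm1(-(q + c * q * q))


@dataclass
class RiskSurface:
    """Extra-lifetime-risk values indexed (uncertainty iteration, ...).

    ``mean_risk`` is the per-iteration average over the variability
    dimension; ``matrix`` optionally retains the full (u x i) surface.
    """

    mean_risk: np.ndarray
    uncertainty: UncertaintySample
    matrix: np.ndarray | None = None


def run_2dmc_population(
    exposures: pd.DataFrame,
    config: ConversionFactorConfig,
    n_unc: int,
    seed: int,
    b_summary: PercentileSummary = P.B_SUMMARY_POPULATION,
    c_summary: PercentileSummary = P.C_SUMMARY_POPULATION,
    param_uncertainty: ParamUncertainty | None = None,
    keep_matrix: bool | None = None,
    uncertainty: UncertaintySample | None = None,
) -> RiskSurface:
    """Two-dimensional Monte Carlo over a fixed simulated population.

    ``exposures`` must carry columns ``exposure`` and ``z`` (from
    :func:`bbqrisk.exposure.simulate_population`); they are never modified
    or redrawn here — only the uncertainty dimension is sampled.  An
    explicit ``uncertainty`` sample (e.g. degenerate central values) bypasses
    the sampling entirely.
    """
    if n_unc < 1:
        raise ValueError("n_unc must be >= 1")
    y = exposures["exposure"].to_numpy(dtype=float)
    z = exposures["z"].to_numpy(dtype=float)
    if uncertainty is not None:
        u = uncertainty
        n_unc = u.n
    else:
        rng = rng_stream(seed, "uncertainty")
        u = draw_uncertainty(
            n_unc, config, rng, b_summary, c_summary, param_uncertainty
        )
    if keep_matrix is None:
        keep_matrix = n_unc * y.size <= 20_000_000

    allo = allometric_cf(config.bw_human, config.bw_animal, u.ap)
    mean_risk = np.empty(n_unc)
    matrix = np.empty((n_unc, y.size)) if keep_matrix else None
    for j in range(n_unc):
        dose = y * (config.gm_intra * u.gsd_intra[j] ** z) * allo[j] * u.cf_tktd[j]
        er = _er(dose, u.b[j], u.c[j])
        mean_risk[j] = er.mean()
        if keep_matrix:
            matrix[j] = er
    return RiskSurface(mean_risk=mean_risk, uncertainty=u, matrix=matrix)


def run_2dmc_subgroups(
    subgroups,
    config: ConversionFactorConfig,
    n_unc: int,
    seed: int,
    b_summary: PercentileSummary = P.B_SUMMARY_SUBGROUPS,
    c_summary: PercentileSummary = P.C_SUMMARY_SUBGROUPS,
    param_uncertainty: ParamUncertainty | None = None,
    uncertainty: UncertaintySample | None = None,
) -> np.ndarray:
    """Uncertainty distribution of the mean risk per (sex, class, B).

    One shared uncertainty stream serves every subgroup (common random
    numbers), and each subgroup's allometric factor uses its class-median
    bodyweight.  Returns ``mean_risk`` with shape (n_unc, 2, 3, B).
    """
    if n_unc < 1:
        raise ValueError("n_unc must be >= 1")
    if uncertainty is not None:
        u = uncertainty
        n_unc = u.n
    else:
        rng = rng_stream(seed, "uncertainty")
        u = draw_uncertainty(n_unc, config, rng, b_summary, c_summary, param_uncertainty)

    exp = subgroups.exposure  # (2, 3, B, reps)
    z = subgroups.z[:, :, None, :]  # (2, 3, 1, reps)
    n_b = exp.shape[2]
    mean_risk = np.empty((n_unc, 2, 3, n_b))
    for j in range(n_unc):
        cf_intra = config.gm_intra * u.gsd_intra[j] ** z
        for si in range(2):
            for ci in range(3):
                allo = allometric_cf(
                    subgroups.bodyweights[si, ci], config.bw_animal, u.ap[j]
                )
                dose = exp[si, ci] * cf_intra[si, ci] * allo * u.cf_tktd[j]
                mean_risk[j, si, ci] = _er(dose, u.b[j], u.c[j]).mean(axis=-1)
    return mean_risk


def summarize_uncertainty(
    surface: RiskSurface | np.ndarray,
    percentiles=(2.5, 97.5),
    population_size: int | None = None,
) -> dict:
    """Median and outer percentiles of the per-iteration mean risks, plus an
    optional expected-cases conversion for an explicit population size."""
    mean_risk = surface.mean_risk if isinstance(surface, RiskSurface) else np.asarray(surface)
    if mean_risk.shape[0] < 2:
        raise ValueError("need at least 2 uncertainty iterations to summarise")
    lo, hi = percentiles
    out = {
        "median": float(np.median(mean_risk, axis=0))
        if mean_risk.ndim == 1
        else np.median(mean_risk, axis=0),
        f"p{lo}": np.percentile(mean_risk, lo, axis=0),
        f"p{hi}": np.percentile(mean_risk, hi, axis=0),
    }
    if mean_risk.ndim == 1:
        out[f"p{lo}"] = float(out[f"p{lo}"])
        out[f"p{hi}"] = float(out[f"p{hi}"])
    if population_size is not None:
        out["expected_cases_median"] = (
            np.asarray(out["median"]) * population_size
            if mean_risk.ndim > 1
            else out["median"] * population_size
        )
    return out


def events_to_exceed(
    subgroup_mean_risk: np.ndarray,
    b_values: np.ndarray,
    threshold: float,
    statistic: str = "median",
) -> pd.DataFrame:
    """Smallest annual event count at which each subgroup's chosen
    uncertainty statistic of the mean risk strictly exceeds ``threshold``.

    ``statistic`` is "median" or "p97.5".  Unreachable within the grid is
    reported as NaN.
    """
    if subgroup_mean_risk.size == 0 or len(b_values) == 0:
        raise ValueError("empty subgroup risk grid")
    if statistic == "median":
        stat = np.median(subgroup_mean_risk, axis=0)  # (2, 3, B)
    elif statistic in ("p97.5", "p97_5"):
        stat = np.percentile(subgroup_mean_risk, 97.5, axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    rows = []
    for si, sex in enumerate(("men", "women")):
        for ci, wc in enumerate(P.WEIGHT_CLASSES):
            above = stat[si, ci] > threshold
            b_cross = float(b_values[np.argmax(above)]) if above.any() else float("nan")
            rows.append({"sex": sex, "weight_class": wc, "events": b_cross})
    return pd.DataFrame(rows)
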
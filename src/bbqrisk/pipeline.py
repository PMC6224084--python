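"""Pipeline orchestration: synthetic surveys -> fitting -> exposure ->
dose-response -> risk -> report, with a manifest for exact re-runs.

Every stage is a plain function over the library modules; the command-line
interface and the numbered analysis scripts are thin wrappers around these.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as P
from .doseresponse import bmd, bmdl, bootstrap_two_stage, fit_two_stage_ml
from .exposure import simulate_population, simulate_subgroups
from .fitting import (
    CensoredConcentrationSet,
    fit_bodyweight_regression,
    fit_censored_lognormal,
    fit_censored_lognormal_mixture_map,
    fit_gamma_consumption,
)
from .params import PipelineConfig, save_config
from .risk import events_to_exceed, run_2dmc_population, run_2dmc_subgroups, summarize_uncertainty
from .synthetic import (
    DEFAULT_STUDY_DOSES,
    DEFAULT_STUDY_N_PER_DOSE,
    GroundTruth,
    gen_concentration_samples,
    gen_consumption_survey,
    gen_dose_response_study,
    gen_frequency_survey,
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_synth(config: PipelineConfig, outdir: Path, n_survey=3000, n_conc=400):
    """Generate all survey-shaped inputs from the shipped ground truth."""
    truth = GroundTruth(
        gamma_params=config.gamma_params,
        concentration_params=config.concentration_params,
        regression=config.regression,
        frequency_fractions=config.frequency_fractions,
        dose_response_b=config.b_summary.median,
        dose_response_c=config.c_summary.median,
    )
    survey = gen_consumption_survey(n_survey, truth, seed=config.seed)
    conc = gen_concentration_samples(
        max(n_conc // len(P.MEAT_TYPES), 30), truth, P.DEFAULT_LOD_VALUES, seed=config.seed + 1
    )
    freq = pd.DataFrame(
        {"events_per_year": gen_frequency_survey(1000, truth.frequency_fractions, seed=config.seed + 2)}
    )
    study = gen_dose_response_study(
        DEFAULT_STUDY_DOSES,
        DEFAULT_STUDY_N_PER_DOSE,
        truth.dose_response_b,
        truth.dose_response_c,
        seed=config.seed + 3,
    )
    survey.to_csv(outdir / "consumption_survey.csv", index=False)
    conc.to_csv(outdir / "concentration_samples.csv", index=False)
    freq.to_csv(outdir / "frequency_survey.csv", index=False)
    study.to_csv(outdir / "dose_response_study.csv", index=False)
    return {"survey": survey, "concentrations": conc, "frequency": freq, "study": study}


def stage_fit(config: PipelineConfig, data: dict, outdir: Path) -> PipelineConfig:
    """Fit every input distribution to the (synthetic) surveys and return a
    config carrying the fitted parameters in place of the generating ones."""
    survey = data["survey"]
    fitted_gammas = {}
    for sex in P.SEXES:
        for wc in P.WEIGHT_CLASSES:
            sub = survey[(survey["sex"] == sex) & (survey["weight_class"] == wc)]
            fitted_gammas[(sex, wc)] = fit_gamma_consumption(sub["amount_g"].to_numpy())

    fitted_conc = {}
    for meat in P.MEAT_TYPES:
        cset = CensoredConcentrationSet.from_dataframe(data["concentrations"], meat)
        if meat == "minced_beef":
            fitted_conc[meat] = fit_censored_lognormal_mixture_map(cset).params
        else:
            fitted_conc[meat] = fit_censored_lognormal(cset)

    reg = fit_bodyweight_regression(survey)

    freq_counts = data["frequency"]["events_per_year"].value_counts(normalize=True)
    fitted_fractions = tuple(
        float(freq_counts.get(e, 0.0)) for e in config.frequency_events
    )

    fitted = PipelineConfig(
        **{
            **{f: getattr(config, f) for f in (
                "n_population",
                "n_uncertainty_population",
                "n_per_subgroup",
                "n_uncertainty_subgroups",
                "b_grid_max",
                "seed",
                "output_dir",
                "percentiles",
                "population_size",
                "frequency_events",
                "b_summary",
                "c_summary",
                "b_summary_subgroups",
                "c_summary_subgroups",
                "cf_config",
            )},
            "frequency_fractions": fitted_fractions,
            "gamma_params": fitted_gammas,
            "concentration_params": fitted_conc,
            "combo_table": config.combo_table,
            "regression": reg,
        }
    )
    fitted.validate()
    # the serialized parameter file carries no run-specific paths
    import dataclasses

    save_config(dataclasses.replace(fitted, output_dir="."), outdir / "fitted_parameters.yaml")
    return fitted


def stage_expose(config: PipelineConfig, outdir: Path):
    pop = simulate_population(config.n_population, config, seed=config.seed)
    pop.to_csv(outdir / "population_exposure.csv", index=False)
    sub = simulate_subgroups(
        config.b_grid_max, config.n_per_subgroup, config, seed=config.seed
    )
    long = pd.DataFrame(
        {
            "sex": np.repeat(["men", "women"], 3 * len(sub.b_values)),
            "weight_class": np.tile(np.repeat(P.WEIGHT_CLASSES, len(sub.b_values)), 2),
            "b": np.tile(sub.b_values, 6),
            "mean_exposure": sub.exposure.mean(axis=-1).reshape(-1),
        }
    )
    long.to_csv(outdir / "subgroup_exposure_curves.csv", index=False)
    return pop, sub


def stage_doseresponse(config: PipelineConfig, study: pd.DataFrame, outdir: Path, n_boot=200):
    fit = fit_two_stage_ml(study)
    boot = bootstrap_two_stage(study, n_boot=max(n_boot, 100), seed=config.seed)
    pd.DataFrame({"b": boot.b, "c": boot.c}).to_csv(outdir / "bootstrap_bc.csv", index=False)
    out = {
        "b": fit.b,
        "c": fit.c,
        "background": fit.a,
        "bmd10": bmd(fit, 0.10),
        "bmdl10": bmdl(boot, 0.10),
    }
    (outdir / "dose_response_fit.json").write_text(json.dumps(out, indent=2))
    return fit, boot, out


def stage_risk(config: PipelineConfig, pop, sub, outdir: Path):
    surface = run_2dmc_population(
        pop,
        config.cf_config,
        n_unc=config.n_uncertainty_population,
        seed=config.seed,
        b_summary=config.b_summary,
        c_summary=config.c_summary,
        keep_matrix=False,
    )
    pop_summary = summarize_uncertainty(
        surface, config.percentiles, config.population_size
    )
    sub_risk = run_2dmc_subgroups(
        sub,
        config.cf_config,
        n_unc=config.n_uncertainty_subgroups,
        seed=config.seed,
        b_summary=config.b_summary_subgroups,
        c_summary=config.c_summary_subgroups,
    )
    threshold = pop_summary["median"]
    e_med = events_to_exceed(sub_risk, sub.b_values, threshold, "median")
    e_hi = events_to_exceed(sub_risk, sub.b_values, threshold, "p97.5")
    events = e_med.merge(e_hi, on=["sex", "weight_class"], suffixes=("_median", "_p97.5"))
    return surface, pop_summary, sub_risk, events


def report_tables(results: dict, outdir: Path, plots: bool = False) -> list[Path]:
    """Write the summary tables (and optional plots); deterministic output."""
    written = []

    freq = pd.DataFrame(
        {
            "events_per_year": results["config"].frequency_events,
            "fraction": results["config"].frequency_fractions,
        }
    )
    p = outdir / "table_frequency_scenarios.csv"
    freq.to_csv(p, index=False, float_format="%.3f")
    written.append(p)

    s = results["population_summary"]
    lo, hi = results["config"].percentiles
    pop = pd.DataFrame(
        [{"median": s["median"], f"p{lo}": s[f"p{lo}"], f"p{hi}": s[f"p{hi}"]}]
    )
    p = outdir / "population_risk_summary.csv"
    pop.to_csv(p, index=False, float_format="%.6e")
    written.append(p)

    p = outdir / "table_events_to_exceed.csv"
    results["events_to_exceed"].to_csv(p, index=False)
    written.append(p)

    sub_risk = results["subgroup_mean_risk"]
    b_values = results["subgroups"].b_values
    rows = []
    for si, sex in enumerate(("men", "women")):
        for ci, wc in enumerate(P.WEIGHT_CLASSES):
            med = np.median(sub_risk[:, si, ci, :], axis=0)
            plo = np.percentile(sub_risk[:, si, ci, :], lo, axis=0)
            phi = np.percentile(sub_risk[:, si, ci, :], hi, axis=0)
            for bi, bval in enumerate(b_values):
                rows.append(
                    {
                        "sex": sex,
                        "weight_class": wc,
                        "b": int(bval),
                        "median": med[bi],
                        f"p{lo}": plo[bi],
                        f"p{hi}": phi[bi],
                    }
                )
    p = outdir / "subgroup_risk_curves.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6e")
    written.append(p)

    if plots:
        written += _plots(results, outdir)
    return written


def _plots(results: dict, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    pop = results["population"]
    nz = pop.loc[pop["exposure"] > 0, "exposure"]
    fig, ax = plt.subplots()
    ax.hist(np.log10(nz), bins=50)
    ax.set_xlabel("log10 yearly exposure (ug/kg bw)")
    ax.set_ylabel("individuals")
    p = outdir / "fig_population_exposure_log10.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots()
    ax.hist(np.log10(results["population_surface"].mean_risk), bins=50)
    ax.set_xlabel("log10 mean extra lifetime risk")
    ax.set_ylabel("uncertainty iterations")
    p = outdir / "fig_mean_risk_uncertainty_log10.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written


def run_pipeline(config: PipelineConfig, plots: bool = False) -> dict:
    """Execute the full pipeline and write all artifacts plus a manifest.

    Returns a dict of in-memory results keyed by stage.  Any stage error
    aborts with a stage-named diagnostic.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}
    results: dict = {"config": config}

    def run_stage(name, fn):
        t = time.time()
        try:
            out = fn()
        except Exception as exc:  # re-raise with the failing stage named
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.time() - t, 3)
        return out

    data = run_stage("synth", lambda: stage_synth(config, outdir))
    results["synthetic"] = data
    fitted = run_stage("fit", lambda: stage_fit(config, data, outdir))
    results["fitted_config"] = fitted
    pop, sub = run_stage("expose", lambda: stage_expose(fitted, outdir))
    results["population"], results["subgroups"] = pop, sub
    fit, boot, dr = run_stage(
        "doseresponse", lambda: stage_doseresponse(config, data["study"], outdir)
    )
    results["dose_response"] = dr
    surface, pop_summary, sub_risk, events = run_stage(
        "risk", lambda: stage_risk(fitted, pop, sub, outdir)
    )
    results.update(
        population_surface=surface,
        population_summary=pop_summary,
        subgroup_mean_risk=sub_risk,
        events_to_exceed=events,
    )
    written = run_stage("report", lambda: report_tables(results, outdir, plots=plots))

    manifest = {
        "seed": config.seed,
        "sizes": {
            "n_population": config.n_population,
            "n_uncertainty_population": config.n_uncertainty_population,
            "n_per_subgroup": config.n_per_subgroup,
            "n_uncertainty_subgroups": config.n_uncertainty_subgroups,
            "b_grid_max": config.b_grid_max,
        },
        "python": platform.python_version(),
        "numpy": np.__version__,
        "timings_s": timings,
        "total_s": round(time.time() - t0, 3),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.suffix in {".csv", ".yaml", ".json"}
            and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
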
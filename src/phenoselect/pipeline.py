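"""Staged analysis pipeline over prepared or synthetic data.

Stages (each resumable and individually invokable through the CLI):
prepare → phenology → animal-model → optimum (fitness, eggs, stage
survival, subset robustness) → selection → power.  Every stage writes its
tables (TSV) plus a manifest (YAML) with the seed and settings that
produced it, so every number in the report traces back to a manifest
entry.
"""

from __future__ import annotations

import json
import logging
import pathlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .animal import AnimalModel, heritability_repeatability, mother_daughter_h2
from .glmm import ModelSpec, Term, aic_stepwise, fit_mixed_model
from .optimum import GaussianOptimumModel, quadratic_pretest, trait_mode
from .power import run_power_study, summarize_power
from .records import prepare_dataset, read_records_csv, read_temperature_csv
from .pedigree import Pedigree, read_pedigree_csv
from .selection import SelectionStats
from .survival import female_outcome_models, stage_survival_models

logger = logging.getLogger(__name__)


@dataclass
class PipelineSettings:
    """Knobs for one pipeline run; MCMC lengths default to quick settings
    suitable for the synthetic fixtures (pass the study protocol for a
    full-length run)."""

    seed: int = 1
    animal_iter: int = 20_000
    animal_burn: int = 2_000
    animal_thin: int = 10
    optimum_chains: int = 2
    optimum_iter: int = 12_000
    optimum_burn: int = 2_000
    optimum_thin: int = 10
    power_replicates: int = 5
    power_iter: int = 6_000
    power_burn: int = 1_000
    n_boot: int = 1000


def _write(df: pd.DataFrame, out_dir: pathlib.Path, name: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / name, sep="\t", index=False)


def _manifest(out_dir: pathlib.Path, stage: str, payload: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{stage}.manifest.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True, default_flow_style=False)


def load_inputs(records_csv=None, pedigree_csv=None, temps_csv=None, fixture: str | None = None,
                seed: int = 1, config=None):
    """Load CSV inputs or generate a named synthetic fixture."""
    if fixture is not None:
        study = synthetic.make_fixture(size=fixture, seed=seed, config=config)
        return study.records, study.pedigree, study.temperatures, study.truth
    records = read_records_csv(records_csv)
    pedigree = read_pedigree_csv(pedigree_csv)
    temps = read_temperature_csv(temps_csv) if temps_csv else None
    return records, pedigree, temps, None


def stage_prepare(records, temps, out_dir: pathlib.Path | None = None) -> dict:
    prep = prepare_dataset(records, temps)
    season = prep["season_table"]
    s = season["start_day"].astype(float)
    season["start_day_std"] = (s - s.mean()) / s.std(ddof=1)
    if "cue" in prep:
        cue = prep["cue"]
        prep["cue_std"] = (cue - cue.mean()) / cue.std(ddof=1)
    if out_dir:
        _write(prep["records"], out_dir, "prepared_records.tsv")
        _write(season, out_dir, "season_table.tsv")
        _manifest(out_dir, "prepare", {
            "grand_mean_start_day": prep["grand_mean_start_day"],
            "lay_mean": prep["lay_standardizer"].mean,
            "lay_sd": prep["lay_standardizer"].sd,
            "n_records": int(len(prep["records"])),
        })
    return prep


def stage_phenology(prep: dict, settings: PipelineSettings, out_dir=None) -> dict:
    """Start-of-season age-model selection and the temperature-plasticity test."""
    season = prep["season_table"].copy()
    base = ModelSpec(response="start_day", random_terms=["female_id", "season"], family="gaussian")
    variants = ["linear", "quadratic", "break2", "break2_6", "firstyear_plus_break"]
    fits = {}
    for v in variants:
        spec = base.with_terms([Term("female_age", "age", variant=v, label=f"age_{v}")])
        fits[v] = fit_mixed_model(spec, season)
    best = min(fits, key=lambda v: fits[v].aic)
    out = {"age_model_aic": {v: fits[v].aic for v in variants}, "best_age_model": best,
           "best_fit": fits[best]}

    if "cue_std" in prep:
        season = season.merge(prep["cue_std"].rename("cue_std"), left_on="season", right_index=True)
        spec0 = base.with_terms([Term("female_age", "age", variant=best, label="age")])
        spec1 = base.with_terms([Term("female_age", "age", variant=best, label="age"),
                                 Term("cue_std", "linear", label="cue")])
        f0 = fit_mixed_model(spec0, season)
        f1 = fit_mixed_model(spec1, season)
        cue_row = f1.estimates.loc[f1.estimates["term"] == "cue_std"]
        out["cue_test"] = {
            "aic_without": f0.aic,
            "aic_with": f1.aic,
            "supported": bool(f0.aic - f1.aic > 2),
            "slope_per_sd_cue": float(cue_row["estimate"].iloc[0]),
            "slope_se": float(cue_row["se"].iloc[0]),
        }
    if out_dir:
        _manifest(out_dir, "phenology", {
            "age_model_aic": {k: float(v) for k, v in out["age_model_aic"].items()},
            "best_age_model": best,
            "cue_test": {k: v for k, v in out.get("cue_test", {}).items()},
        })
    return out


def stage_animal(prep: dict, pedigree: Pedigree, settings: PipelineSettings, out_dir=None) -> dict:
    model = AnimalModel(
        n_iter=settings.animal_iter, thin=settings.animal_thin, burn_in=settings.animal_burn,
        seed=settings.seed, min_ess=200.0,
    )
    model.fit(prep["records"], pedigree)
    hr = heritability_repeatability(model)
    md = mother_daughter_h2(prep["records"], pedigree)
    out = {"model": model, "h2": hr["h2"], "r2": hr["r2"], "mother_daughter": md}
    if out_dir:
        _write(model.summary(), out_dir, "animal_model_summary.tsv")
        model.draws_.to_csv(out_dir / "animal_model_draws.tsv", sep="\t", index=False)
        _manifest(out_dir, "animal", {
            "seed": settings.seed, "n_iter": settings.animal_iter,
            "burn_in": settings.animal_burn, "thin": settings.animal_thin,
            "h2_mode": float(hr["h2"]["mode"]), "h2_median": float(hr["h2"]["median"]),
            "mother_daughter_h2": float(md["h2"]) if np.isfinite(md["h2"]) else None,
        })
    return out


def stage_optimum(prep: dict, settings: PipelineSettings, out_dir=None, cue=None) -> dict:
    recs = prep["records"].copy()
    st = prep["lay_standardizer"]
    mcmc = dict(n_chains=settings.optimum_chains, n_iter=settings.optimum_iter,
                burn_in=settings.optimum_burn, thin=settings.optimum_thin)
    out: dict = {}

    pre = quadratic_pretest(recs, "n_recruits", family="poisson")
    model = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
    model.fit(recs, response="n_recruits", standardizer=st, pretest=pre)
    out["fitness"] = {"pretest": pre, "model": model, "summary": model.optimum_summary()}

    pre_eggs = quadratic_pretest(recs, "n_eggs", family="poisson")
    eggs = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
    eggs.fit(recs, response="n_eggs", standardizer=st, pretest=pre_eggs)
    out["eggs"] = {"pretest": pre_eggs, "model": eggs, "summary": eggs.optimum_summary()}

    out["mode"] = trait_mode(recs["lay_day"].to_numpy())

    if cue is not None:
        cued = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
        cued.fit(recs, response="n_recruits", standardizer=st, cue=cue)
        out["cue_model"] = {"model": cued, "B_pmcmc": cued.B_pmcmc_,
                            "B_median": float(cued.draws_["B"].median())}

    # subset robustness: middle-aged females; females surviving to next year
    season = prep["season_table"]
    mid = recs[(recs["female_age"] >= 2) & (recs["female_age"] <= 6)]
    if mid["season"].nunique() >= 3:
        m = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
        m.fit(mid, response="n_recruits", standardizer=st)
        out["subset_middle_aged"] = {"model": m, "summary": m.optimum_summary()}
    surv = season[season["survived_to_next_season"] == True][["female_id", "season"]]  # noqa: E712
    svrecs = recs.merge(surv, on=["female_id", "season"])
    if len(svrecs) > 50 and svrecs["season"].nunique() >= 3:
        m = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
        m.fit(svrecs, response="n_recruits", standardizer=st)
        out["subset_survivors"] = {"model": m, "summary": m.optimum_summary()}
    # annual fitness: start of season vs summed recruits
    annual = season.copy()
    annual["start_day_std"] = st.transform(annual["start_day"])
    m = GaussianOptimumModel(family="poisson", a_max=5.0, seed=settings.seed, **mcmc)
    m.fit(annual, lay_col="start_day_std", response="annual_recruits", standardizer=st)
    out["annual_fitness"] = {"model": m, "summary": m.optimum_summary()}

    if out_dir:
        rows = []
        for key in ("fitness", "eggs", "subset_middle_aged", "subset_survivors", "annual_fitness"):
            if key in out and "summary" in out[key]:
                s = out[key]["summary"]
                row = {"analysis": key, **{f"mu_{k}": v for k, v in s["std"].items()}}
                if "day" in s:
                    row.update({f"day_{k}": v for k, v in s["day"].items()})
                rows.append(row)
        _write(pd.DataFrame(rows), out_dir, "optima.tsv")
        out["fitness"]["model"].per_year_optima().to_csv(out_dir / "per_year_optima.tsv", sep="\t", index=False)
        _manifest(out_dir, "optimum", {"seed": settings.seed, **mcmc,
                                       "mode_day": out["mode"]["mode_day"]})
    return out


def stage_selection(prep: dict, settings: PipelineSettings, out_dir=None) -> dict:
    recs = prep["records"].dropna(subset=["lay_day", "n_recruits"])
    per_clutch = SelectionStats.compute(
        recs["lay_day"].to_numpy(), recs["n_recruits"].to_numpy(),
        n_boot=settings.n_boot, seed=settings.seed,
    )
    season = prep["season_table"].dropna(subset=["start_day", "annual_recruits"])
    per_season = SelectionStats.compute(
        season["start_day"].to_numpy(), season["annual_recruits"].to_numpy(),
        n_boot=settings.n_boot, seed=settings.seed,
    )
    out = {"per_clutch": per_clutch, "per_female_season": per_season}
    if out_dir:
        frame = pd.concat([
            per_clutch.to_frame().assign(unit="clutch"),
            per_season.to_frame().assign(unit="female_season"),
        ])
        _write(frame, out_dir, "selection_stats.tsv")
        _manifest(out_dir, "selection", {"seed": settings.seed, "n_boot": settings.n_boot})
    return out


def stage_survival(prep: dict, settings: PipelineSettings, out_dir=None) -> dict:
    mcmc = dict(n_chains=settings.optimum_chains, n_iter=settings.optimum_iter,
                burn_in=settings.optimum_burn, thin=settings.optimum_thin)
    stages = stage_survival_models(prep["records"], optimum_mcmc=mcmc, seed=settings.seed,
                                   standardizer=prep["lay_standardizer"])
    outcomes = female_outcome_models(prep["season_table"])
    out = {"stages": stages, "female_outcomes": outcomes}
    if out_dir:
        rows = []
        for name, res in stages.items():
            row = {"stage": name, "skipped": res.get("skipped", False),
                   "mean_survival": res.get("mean_survival"),
                   "selected_terms": "+".join(res.get("selected_terms", []))}
            if "optimum_summary" in res and "day" in res["optimum_summary"]:
                row["optimum_day"] = res["optimum_summary"]["day"]["median"]
            rows.append(row)
        _write(pd.DataFrame(rows), out_dir, "stage_survival.tsv")
        _manifest(out_dir, "survival", {"seed": settings.seed})
    return out


def stage_power(prep: dict, pedigree: Pedigree, settings: PipelineSettings,
                reference_mode: float, reference_median: float, out_dir=None) -> dict:
    table = run_power_study(
        pedigree, prep["records"], target_h2=0.1,
        replicates=settings.power_replicates, seed=settings.seed,
        n_iter=settings.power_iter, burn_in=settings.power_burn, thin=settings.animal_thin,
    )
    summary = summarize_power(table, reference_mode, reference_median) if len(table) >= 10 else {
        "n_replicates": len(table), "mean_posterior_median": float(table["h2_median"].mean())}
    if out_dir:
        _write(table, out_dir, "power_replicates.tsv")
        _manifest(out_dir, "power", {"seed": settings.seed, **summary})
    return {"table": table, "summary": summary}


def run_pipeline(
    records=None, pedigree=None, temps=None, fixture: str | None = None,
    settings: PipelineSettings | None = None, out_dir=None, config=None,
) -> dict:
    """Run every stage in order and return the full report bundle."""
    settings = settings or PipelineSettings()
    if fixture is not None:
        records, pedigree, temps, truth = load_inputs(fixture=fixture, seed=settings.seed, config=config)
    else:
        truth = None
    out_path = pathlib.Path(out_dir) if out_dir else None
    report: dict = {"truth": truth}
    prep = stage_prepare(records, temps, out_path)
    report["prepare"] = prep
    report["phenology"] = stage_phenology(prep, settings, out_path)
    report["animal"] = stage_animal(prep, pedigree, settings, out_path)
    cue = prep.get("cue_std")
    report["optimum"] = stage_optimum(prep, settings, out_path, cue=cue)
    report["selection"] = stage_selection(prep, settings, out_path)
    report["survival"] = stage_survival(prep, settings, out_path)
    h2 = report["animal"]["h2"]
    report["power"] = stage_power(prep, pedigree, settings,
                                  reference_mode=h2["mode"], reference_median=h2["median"],
                                  out_dir=out_path)
    return report
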
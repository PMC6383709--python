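"""Stage-wise juvenile survival and female outcome models.

Survival through the juvenile stages (egg→hatchling, hatchling→fledgling,
fledgling→recruit and the compound egg→recruit) is analysed at the clutch
level with binomial mixed models (year and female identity as random
intercepts), candidate covariates being the standardized lay date (as a
quadratic effect), clutch number and female quality (age class, size,
inbreeding).  Where the quadratic lay-date term survives AIC selection,
the Gaussian optimum model (binomial family, A_max = 1) is fitted to
locate the survival optimum.  Female outcomes (probability of a second
clutch; survival to the next season) are binomial mixed models on the
season table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .glmm import ModelSpec, Term, aic_stepwise, fit_mixed_model
from .optimum import GaussianOptimumModel, quadratic_pretest

logger = logging.getLogger(__name__)

STAGES = {
    "egg_hatch": ("n_eggs", "n_hatchlings"),
    "hatch_fledge": ("n_hatchlings", "n_fledglings"),
    "fledge_recruit": ("n_fledglings", "n_recruits"),
    "egg_recruit": ("n_eggs", "n_recruits"),
}

AGE_CLASS_BINS = [0, 1, 6, np.inf]
AGE_CLASS_LABELS = ["young", "middle", "old"]


def age_class(ages) -> pd.Categorical:
    """Young (1 year) / middle (2–6) / old (>6) female age classes."""
    return pd.cut(pd.Series(ages), AGE_CLASS_BINS, labels=AGE_CLASS_LABELS)


def _prepare_stage(records: pd.DataFrame, trials_col: str, succ_col: str) -> pd.DataFrame:
    d = records.copy()
    d = d[d[trials_col].fillna(0) > 0].reset_index(drop=True)
    d["age_class"] = age_class(d["female_age"])
    # middle-aged females as the reference level
    d["age_class"] = pd.Categorical(d["age_class"], categories=["middle", "young", "old"])
    return d


def stage_survival_models(
    records: pd.DataFrame,
    stages: dict | None = None,
    lay_col: str = "lay_day_std",
    optimum_mcmc: dict | None = None,
    seed: int | None = None,
    standardizer=None,
) -> dict:
    """AIC-selected binomial GLMM per juvenile stage, plus the survival
    optimum where the quadratic lay-date effect is retained.

    Stages with no outcome variation (all survive / none survive) are
    flagged and skipped.  Returns a dict keyed by stage name.
    """
    stages = stages or STAGES
    optimum_mcmc = optimum_mcmc or {}
    results: dict = {}
    for stage, (trials_col, succ_col) in stages.items():
        d = _prepare_stage(records, trials_col, succ_col)
        if len(d) == 0:
            results[stage] = {"skipped": True, "reason": "no records with trials"}
            continue
        rate = d[succ_col].sum() / d[trials_col].sum()
        if rate in (0.0, 1.0):
            logger.warning("stage %s has no outcome variation (rate=%s); skipped", stage, rate)
            results[stage] = {"skipped": True, "reason": "no variation", "mean_survival": float(rate)}
            continue
        base = ModelSpec(
            response=succ_col,
            random_terms=["season", "female_id"],
            family="binomial",
            trials=trials_col,
        )
        candidates = [
            Term(lay_col, "quadratic", label="lay_date"),
            Term("clutch_number", "linear", label="clutch_number"),
            Term("age_class", "categorical", label="age_class"),
        ]
        if d["female_tarsus"].notna().any():
            candidates.append(Term("female_tarsus", "linear", label="tarsus"))
        step = aic_stepwise(candidates, base, d)
        selected_names = [t.name for t in step.selected.fixed_terms]
        fit = step.fits[tuple(selected_names)]
        entry = {
            "skipped": False,
            "mean_survival": float(rate),
            "selected_terms": selected_names,
            "fit": fit,
            "trace": step.trace,
            "n_obs": fit.n_obs,
        }
        if "lay_date" in selected_names:
            model = GaussianOptimumModel(
                family="binomial",
                a_max=1.0,
                seed=seed,
                **optimum_mcmc,
            )
            model.fit(d, lay_col=lay_col, response=succ_col, year_col="season",
                      trials_col=trials_col, standardizer=standardizer)
            entry["optimum"] = model
            entry["optimum_summary"] = model.optimum_summary()
        results[stage] = entry
    return results


def compound_survival_consistency(results: dict) -> dict:
    """Product of the three stage means vs the direct egg→recruit mean."""
    try:
        prod = (
            results["egg_hatch"]["mean_survival"]
            * results["hatch_fledge"]["mean_survival"]
            * results["fledge_recruit"]["mean_survival"]
        )
        direct = results["egg_recruit"]["mean_survival"]
    except (KeyError, TypeError):
        return {"available": False}
    return {"available": True, "product_of_stages": float(prod), "egg_recruit_mean": float(direct)}


def _best_age_encoding(base: ModelSpec, data: pd.DataFrame, age_col: str = "female_age"):
    """Choose among age encodings (linear; first-year vs older; three classes)
    by single-term AIC, mirroring how alternative age models are screened."""
    encodings = {
        "age_linear": Term(age_col, "linear", label="age_linear"),
        "age_firstyear": Term(age_col, "firstyear", label="age_firstyear"),
        "age_class": Term("age_class", "categorical", label="age_class"),
    }
    best_name, best_aic, best_term = None, np.inf, None
    for name, term in encodings.items():
        try:
            f = fit_mixed_model(base.with_terms([term]), data)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if f.aic < best_aic:
            best_name, best_aic, best_term = name, f.aic, term
    return best_term


def female_outcome_models(
    season_table: pd.DataFrame,
    start_col: str = "start_day_std",
) -> dict:
    """AIC-selected models for reclutch probability and overwinter survival."""
    d = season_table.copy()
    if start_col not in d:
        s = d["start_day"].astype(float)
        d[start_col] = (s - s.mean()) / s.std(ddof=1)
    d["age_class"] = age_class(d["female_age"])
    d["age_class"] = pd.Categorical(d["age_class"], categories=["middle", "young", "old"])
    d["_ones"] = 1.0

    out: dict = {}

    # probability of reclutching (more than one clutch)
    drc = d.copy()
    drc["reclutched01"] = drc["reclutched"].astype(float)
    base_rc = ModelSpec(response="reclutched01", random_terms=["season", "female_id"],
                        family="binomial", trials="_ones")
    age_term = _best_age_encoding(base_rc, drc)
    candidates = [Term(start_col, "linear", label="start_day")]
    if age_term is not None:
        candidates.append(age_term)
    if drc["female_tarsus"].notna().any():
        candidates.append(Term("female_tarsus", "linear", label="tarsus"))
    step_rc = aic_stepwise(candidates, base_rc, drc)
    sel = [t.name for t in step_rc.selected.fixed_terms]
    out["reclutch"] = {"selected_terms": sel, "fit": step_rc.fits[tuple(sel)], "trace": step_rc.trace}

    # female survival to the next season
    ds = d[d["survived_to_next_season"].notna()].copy()
    ds["survived01"] = ds["survived_to_next_season"].astype(float)
    base_s = ModelSpec(response="survived01", random_terms=["season", "female_id"],
                       family="binomial", trials="_ones")
    candidates_s = [
        Term(start_col, "linear", label="start_day"),
        Term("n_clutches", "linear", label="n_clutches"),
        Term("female_age", "linear", label="age_linear"),
    ]
    if ds["female_tarsus"].notna().any():
        candidates_s.append(Term("female_tarsus", "linear", label="tarsus"))
    step_s = aic_stepwise(candidates_s, base_s, ds)
    sel_s = [t.name for t in step_s.selected.fixed_terms]
    out["survival"] = {"selected_terms": sel_s, "fit": step_s.fits[tuple(sel_s)], "trace": step_s.trace}
    return out
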
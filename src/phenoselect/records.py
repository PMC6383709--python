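"""Breeding-record, pedigree and temperature ingestion and derived variables.

The study system is an austral-spring breeder: a breeding season spans
September–February and is labelled by its starting calendar year.  Lay
dates are expressed in *season days*: days since 1 September of the
season's starting year (1 Sept → 0).  From validated clutch records we
derive clutch numbers (rank of the attempt within female × season,
regardless of success), the start of breeding season (lay date of the
first clutch), per-clutch fitness (offspring later recruited as
breeders), and the yearly temperature cue (mean daily maximum
temperature over the 50 days before the grand-mean start of breeding).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

#: columns a breeding-record table must carry after column mapping
RECORD_COLUMNS = [
    "female_id",
    "social_male_id",
    "season",
    "lay_day",
    "hatch_day",
    "fledge_day",
    "n_eggs",
    "n_hatchlings",
    "n_fledglings",
    "n_recruits",
    "clutch_number",
    "female_age",
    "female_tarsus",
    "female_inbreeding",
]


class RecordValidationError(ValueError):
    pass


def to_season_day(date: dt.date, season_start_year: int) -> int:
    """Days since 1 September of ``season_start_year`` (1 Sept → 0).

    Raises if the date falls outside the 1 Sept – 31 Aug season window.
    """
    start = dt.date(season_start_year, 9, 1)
    end = dt.date(season_start_year + 1, 8, 31)
    if not (start <= date <= end):
        raise RecordValidationError(
            f"date {date.isoformat()} outside season {season_start_year} "
            f"window [{start.isoformat()}, {end.isoformat()}]"
        )
    return (date - start).days


def season_day_to_date(day: int | float, season_start_year: int) -> dt.date:
    """Inverse of :func:`to_season_day` (day 0 → 1 Sept)."""
    return dt.date(season_start_year, 9, 1) + dt.timedelta(days=int(round(day)))


def season_of_date(date: dt.date) -> int:
    """Season label of a calendar date: Sept–Dec → that year, Jan–Aug → previous."""
    return date.year if date.month >= 9 else date.year - 1


#: lay-to-hatch interval (days) used to impute lay dates from hatch dates
LAY_TO_HATCH_DAYS = 17


def impute_lay_from_hatch(hatch_day: float) -> float:
    """Impute a missing lay day as 17 days before the recorded hatch day."""
    return hatch_day - LAY_TO_HATCH_DAYS


def impute_missing_lay_days(records: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ``lay_day`` from ``hatch_day`` − 17; drop records lacking both.

    Adds a boolean ``lay_imputed`` column.  Every imputation/exclusion is logged.
    """
    out = records.copy()
    out["lay_imputed"] = False
    miss = out["lay_day"].isna()
    can = miss & out["hatch_day"].notna()
    out.loc[can, "lay_day"] = out.loc[can, "hatch_day"] - LAY_TO_HATCH_DAYS
    out.loc[can, "lay_imputed"] = True
    for _, row in out.loc[can].iterrows():
        logger.info("imputed lay_day=%s from hatch_day for female=%s season=%s",
                    row["lay_day"], row["female_id"], row["season"])
    drop = out["lay_day"].isna()
    if drop.any():
        for _, row in out.loc[drop].iterrows():
            logger.warning("excluding record with no lay or hatch day: female=%s season=%s",
                           row["female_id"], row["season"])
        out = out.loc[~drop]
    return out.reset_index(drop=True)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check stage monotonicity and structural invariants; raise on violation."""
    r = records
    counts = ["n_eggs", "n_hatchlings", "n_fledglings", "n_recruits"]
    for c in counts:
        if (r[c].dropna() < 0).any():
            raise RecordValidationError(f"negative counts in {c}")
    chain = r[counts].to_numpy(dtype=float)
    ok = np.all(np.diff(chain, axis=1) <= 1e-9, axis=1) | np.isnan(chain).any(axis=1)
    if not ok.all():
        bad = r.loc[~ok, ["female_id", "season"]].iloc[0]
        raise RecordValidationError(
            f"stage counts not monotone (eggs >= hatchlings >= fledglings >= recruits) "
            f"for female={bad['female_id']} season={bad['season']}"
        )
    for a, b in [("lay_day", "hatch_day"), ("hatch_day", "fledge_day")]:
        both = r[a].notna() & r[b].notna()
        if (r.loc[both, a] > r.loc[both, b]).any():
            raise RecordValidationError(f"{a} after {b} in some record")
    if (r["female_age"].dropna() < 1).any():
        raise RecordValidationError("female_age must be >= 1")
    return r


def derive_clutch_structure(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Number clutches within female × season and build the season table.

    Returns ``(records, season_table)``.  Clutches are ranked by ``lay_day``
    (ties broken by ``hatch_day`` then stable input order; ties are logged).
    The season table has one row per female × season with the start of
    breeding season (lay day of clutch 1), clutch count, annual totals,
    a reclutching flag and survival to the next observed season.
    """
    out = records.copy().reset_index(drop=True)
    out["_order"] = np.arange(len(out))
    hatch_key = out["hatch_day"].fillna(np.inf) if "hatch_day" in out else np.inf
    out["_hatch_key"] = hatch_key
    out = out.sort_values(["female_id", "season", "lay_day", "_hatch_key", "_order"],
                          kind="stable")
    dup = out.duplicated(subset=["female_id", "season", "lay_day"], keep=False)
    if dup.any():
        for (f, s), grp in out.loc[dup].groupby(["female_id", "season"]):
            logger.info("tied lay_day within female=%s season=%s broken by hatch_day/input order", f, s)
    out["clutch_number"] = out.groupby(["female_id", "season"]).cumcount() + 1
    out = out.sort_values("_order").drop(columns=["_order", "_hatch_key"]).reset_index(drop=True)

    grp = out.groupby(["female_id", "season"])
    season = grp.agg(
        start_day=("lay_day", "min"),
        n_clutches=("clutch_number", "max"),
        annual_eggs=("n_eggs", "sum"),
        annual_fledglings=("n_fledglings", "sum"),
        annual_recruits=("n_recruits", "sum"),
        female_age=("female_age", "first"),
        female_tarsus=("female_tarsus", "first"),
        female_inbreeding=("female_inbreeding", "first"),
    ).reset_index()
    season["reclutched"] = season["n_clutches"] > 1

    last = out.groupby("female_id")["season"].max()
    final_season = out["season"].max()
    season["survived_to_next_season"] = season.apply(
        lambda row: float(row["season"] < last.loc[row["female_id"]]), axis=1
    )
    # survival at the final study season is unobservable, not "died"
    season.loc[season["season"] == final_season, "survived_to_next_season"] = np.nan
    return out, season


def breeder_set(records: pd.DataFrame, after_season: int | None = None) -> set:
    """Identifiers observed breeding (as dam or social sire), optionally after a season."""
    r = records if after_season is None else records[records["season"] > after_season]
    breeders = set(r["female_id"].dropna())
    if "social_male_id" in r:
        breeders |= set(r["social_male_id"].dropna())
    if "genetic_sire_id" in r:
        breeders |= set(r["genetic_sire_id"].dropna())
    return breeders


def compute_fitness(
    records: pd.DataFrame,
    pedigree: Pedigree,
    offspring_clutch: Mapping | pd.Series,
    breeders: set | None = None,
) -> pd.DataFrame:
    """Recompute per-clutch recruit counts from the pedigree.

    ``offspring_clutch`` maps each pedigree individual to the index (in
    ``records``) of the clutch it fledged from; individuals with unknown dam
    or no clutch assignment are not credited anywhere.  ``breeders`` defaults
    to every individual later observed as a dam or social sire.  Records from
    the final season are flagged ``recruitment_truncated`` because their
    offspring cannot yet be observed recruiting.
    """
    out = records.copy()
    if breeders is None:
        breeders = breeder_set(records)
    n_recruits = np.zeros(len(out), dtype=int)
    mapping = offspring_clutch if isinstance(offspring_clutch, Mapping) else offspring_clutch.to_dict()
    dam_known = {ped_id: (pedigree.dam[i] >= 0) for i, ped_id in enumerate(pedigree.ids)}
    for ind, rec_idx in mapping.items():
        if rec_idx is None or (isinstance(rec_idx, float) and np.isnan(rec_idx)):
            continue
        if not dam_known.get(ind, False):
            continue
        if ind in breeders:
            n_recruits[int(rec_idx)] += 1
    out["n_recruits"] = n_recruits
    final_season = out["season"].max()
    out["recruitment_truncated"] = out["season"] == final_season
    return out


DEFAULT_CUE_WINDOW = 50
DEFAULT_MISSING_TOLERANCE = 0.10


def compute_temperature_cue(
    temps: pd.DataFrame,
    grand_mean_start_day: float,
    seasons: Sequence[int],
    window: int = DEFAULT_CUE_WINDOW,
    missing_tolerance: float = DEFAULT_MISSING_TOLERANCE,
) -> pd.Series:
    """Per-season cue: mean daily max temperature over the window before the
    grand-mean start of breeding.

    ``temps`` has columns ``date`` (datetime-like, strictly increasing, no
    duplicates) and ``tmax`` (°C).  ``grand_mean_start_day`` is the
    across-season mean start of breeding in season days; the window covers
    the ``window`` days strictly before that date in each season's calendar.
    A season whose window has more than ``missing_tolerance`` of its days
    missing gets a NaN cue (with a warning); otherwise the mean uses the
    available days.
    """
    t = temps.copy()
    t["date"] = pd.to_datetime(t["date"]).dt.date
    if t["date"].duplicated().any():
        raise RecordValidationError("duplicate dates in temperature series")
    if not t["date"].is_monotonic_increasing:
        raise RecordValidationError("temperature dates must be strictly increasing")
    bydate = dict(zip(t["date"], t["tmax"]))

    out = {}
    for season in seasons:
        anchor = season_day_to_date(grand_mean_start_day, int(season))
        days = [anchor - dt.timedelta(days=k) for k in range(1, window + 1)]
        vals = np.array([bydate.get(d, np.nan) for d in days], dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing > missing_tolerance * window:
            logger.warning("season %s cue window missing %d/%d days; cue set to NaN",
                           season, n_missing, window)
            out[season] = np.nan
        else:
            out[season] = float(np.nanmean(vals))
    return pd.Series(out, name="cue").rename_axis("season")


@dataclass
class Standardizer:
    """Mean-centre and scale to unit variance, retaining the transform.

    Uses the sample (n−1) standard deviation.  ``inverse`` maps
    standardized values back to the original scale (e.g. season days).
    """

    mean: float
    sd: float

    @classmethod
    def fit(cls, values: np.ndarray) -> "Standardizer":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError("need at least two non-missing values to standardize")
        sd = float(np.std(v, ddof=1))
        if sd <= 0:
            raise ValueError("zero variance: cannot standardize")
        return cls(mean=float(np.mean(v)), sd=sd)

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


def standardize(values) -> tuple[np.ndarray, Standardizer]:
    """Standardize a vector; returns ``(standardized, transform)``."""
    st = Standardizer.fit(values)
    return st.transform(values), st


# ---------------------------------------------------------------------------
# CSV ingestion with explicit column maps

def read_records_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a breeding-record CSV.  ``column_map`` maps file columns to the
    canonical names in :data:`RECORD_COLUMNS`; missing optional columns are
    filled with NaN."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[RECORD_COLUMNS + [c for c in df.columns if c not in RECORD_COLUMNS]]


def read_temperature_csv(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if not {"date", "tmax"} <= set(df.columns):
        raise RecordValidationError("temperature CSV must have 'date' and 'tmax' columns")
    df["date"] = pd.to_datetime(df["date"])
    return df[["date", "tmax"]]


def prepare_dataset(
    records: pd.DataFrame,
    temps: pd.DataFrame | None = None,
    cue_window: int = DEFAULT_CUE_WINDOW,
) -> dict:
    """Run the full preparation chain: imputation, validation, clutch
    structure, start of season, standardization and (optionally) the
    temperature cue.  Returns a dict of derived tables."""
    recs = impute_missing_lay_days(records)
    recs = validate_records(recs)
    recs, season = derive_clutch_structure(recs)
    std_lay, lay_std = standardize(recs["lay_day"].to_numpy())
    recs["lay_day_std"] = std_lay
    grand_mean_start = float(season["start_day"].mean())
    out = {
        "records": recs,
        "season_table": season,
        "lay_standardizer": lay_std,
        "grand_mean_start_day": grand_mean_start,
    }
    if temps is not None:
        seasons = sorted(recs["season"].unique())
        out["cue"] = compute_temperature_cue(temps, grand_mean_start, seasons, window=cue_window)
    return out
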
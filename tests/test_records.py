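"""Breeding-record derivation: season days, imputation, clutch structure,
fitness, the temperature cue and standardization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoselect.records import (
    RecordValidationError,
    Standardizer,
    compute_fitness,
    compute_temperature_cue,
    derive_clutch_structure,
    impute_lay_from_hatch,
    impute_missing_lay_days,
    prepare_dataset,
    season_day_to_date,
    season_of_date,
    standardize,
    to_season_day,
    validate_records,
)


@pytest.mark.parametrize(
    "date, season, expected",
    [
        (dt.date(2000, 9, 1), 2000, 0),
        (dt.date(2000, 11, 1), 2000, 61),
        (dt.date(2001, 1, 1), 2000, 122),  # 30 + 31 + 30 + 31 days
        (dt.date(2001, 8, 31), 2000, 364),
    ],
)
def test_season_day(date, season, expected):
    assert to_season_day(date, season) == expected


def test_season_day_rejects_out_of_window():
    with pytest.raises(RecordValidationError):
        to_season_day(dt.date(2000, 8, 31), 2000)
    with pytest.raises(RecordValidationError):
        to_season_day(dt.date(2001, 9, 1), 2000)


@settings(derandomize=True, max_examples=60)
@given(offset=st.integers(min_value=0, max_value=364), year=st.integers(min_value=1995, max_value=2015))
def test_season_day_round_trip(offset, year):
    date = season_day_to_date(offset, year)
    assert to_season_day(date, year) == offset
    # Sept-Dec belongs to that year's season, Jan-Aug to the previous
    assert season_of_date(date) == year


@pytest.mark.parametrize("hatch, lay", [(51, 34), (17, 0), (40, 23)])
def test_impute_lay_from_hatch(hatch, lay):
    assert impute_lay_from_hatch(hatch) == lay


def test_impute_missing_lay_days_flags_and_drops(caplog):
    df = pd.DataFrame(
        {
            "female_id": ["a", "b", "c"],
            "season": [1997] * 3,
            "lay_day": [10.0, np.nan, np.nan],
            "hatch_day": [27.0, 30.0, np.nan],
        }
    )
    out = impute_missing_lay_days(df)
    assert out["lay_day"].tolist() == [10.0, 13.0]
    assert out["lay_imputed"].tolist() == [False, True]


def _records(rows):
    base = {
        "hatch_day": np.nan, "fledge_day": np.nan, "n_eggs": 4, "n_hatchlings": 3,
        "n_fledglings": 2, "n_recruits": 0, "female_age": 2, "female_tarsus": 29.0,
        "female_inbreeding": np.nan, "social_male_id": "m",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def test_clutch_structure_orders_by_lay_day():
    recs = _records(
        [
            {"female_id": "F", "season": 2005, "lay_day": 70.0},
            {"female_id": "F", "season": 2005, "lay_day": 34.0},
            {"female_id": "F", "season": 2005, "lay_day": 110.0},
        ]
    )
    out, season = derive_clutch_structure(recs)
    assert out["clutch_number"].tolist() == [2, 1, 3]
    assert season["start_day"].tolist() == [34.0]
    assert season["n_clutches"].tolist() == [3]
    assert bool(season["reclutched"].iloc[0])


def test_clutch_structure_single_and_multiple_females():
    recs = _records(
        [
            {"female_id": "A", "season": 2005, "lay_day": 50.0},
            {"female_id": "B", "season": 2005, "lay_day": 60.0},
        ]
    )
    out, season = derive_clutch_structure(recs)
    assert (out["clutch_number"] == 1).all()
    assert len(season) == 2
    assert (~season["reclutched"]).all()


def test_clutch_structure_matches_generator(tiny_study):
    """The derived clutch order reproduces the generator's known order for
    every female (the generator writes clutch_number itself)."""
    recs = tiny_study.records.drop(columns=["clutch_number"]).assign(
        clutch_number=np.nan
    )
    out, _ = derive_clutch_structure(recs)
    assert (out["clutch_number"].to_numpy() == tiny_study.records["clutch_number"].to_numpy()).all()


def test_stage_monotonicity_enforced():
    bad = _records([{"female_id": "F", "season": 2000, "lay_day": 10.0, "n_hatchlings": 5}])
    with pytest.raises(RecordValidationError):
        validate_records(bad)


def test_compute_fitness_counts_breeders(tiny_study):
    recs = tiny_study.records
    ped = tiny_study.pedigree
    clutch_map = _generator_clutch_map(tiny_study)
    # everyone breeds: n_recruits == n_fledglings for every clutch
    all_fledge = compute_fitness(recs, ped, clutch_map, breeders=set(ped.ids))
    assert (all_fledge["n_recruits"] == recs["n_fledglings"]).all()
    # observed breeders: recomputation matches the generator's stored counts
    stored = compute_fitness(recs, ped, clutch_map, breeders=None)
    assert (stored["n_recruits"] == recs["n_recruits"]).all()
    # final-season clutches are flagged as truncated
    assert stored.loc[stored["season"] == recs["season"].max(), "recruitment_truncated"].all()


def _generator_clutch_map(study):
    """Rebuild offspring -> clutch index from the generated study (fledglings
    were appended in record order, dam known)."""
    recs = study.records
    ped = study.pedigree
    mapping = {}
    counts = recs["n_fledglings"].to_numpy().astype(int)
    # generator ids are sequential; non-founders appear in clutch order
    nonfounders = [ped.ids[i] for i in range(len(ped)) if ped.dam[i] >= 0]
    nonfounders.sort()  # C00001 < C00002 ... zero-padded, so lexicographic = creation order
    k = 0
    for rec_idx, c in enumerate(counts):
        for _ in range(c):
            mapping[nonfounders[k]] = rec_idx
            k += 1
    return mapping


def test_cue_constant_series():
    dates = pd.date_range("2000-06-01", "2000-12-31")
    temps = pd.DataFrame({"date": dates, "tmax": 20.0})
    cue = compute_temperature_cue(temps, 60.0, [2000])
    assert cue.loc[2000] == pytest.approx(20.0)


def test_cue_linear_window_mean():
    """tmax rising 10..59 over the 50 window days -> mean 34.5."""
    anchor = season_day_to_date(60, 2000)
    dates = pd.date_range("2000-06-01", "2000-12-31")
    vals = np.zeros(len(dates))
    for i, d in enumerate(dates):
        lag = (anchor - d.date()).days
        if 1 <= lag <= 50:
            vals[i] = 10 + (50 - lag)
    temps = pd.DataFrame({"date": dates, "tmax": vals})
    cue = compute_temperature_cue(temps, 60.0, [2000])
    assert cue.loc[2000] == pytest.approx(34.5)


def test_cue_ignores_outside_window():
    anchor = season_day_to_date(60, 2000)
    dates = pd.date_range("2000-06-01", "2000-12-31")
    temps = pd.DataFrame({"date": dates, "tmax": 15.0})
    noisy = temps.copy()
    out_of_window = [(anchor - d.date()).days > 50 or (anchor - d.date()).days < 1 for d in dates]
    noisy.loc[out_of_window, "tmax"] = 99.0
    assert compute_temperature_cue(noisy, 60.0, [2000]).loc[2000] == pytest.approx(
        compute_temperature_cue(temps, 60.0, [2000]).loc[2000]
    )


def test_cue_missing_window_is_nan():
    dates = pd.date_range("2000-11-15", "2000-12-31")  # window before start missing
    temps = pd.DataFrame({"date": dates, "tmax": 20.0})
    cue = compute_temperature_cue(temps, 60.0, [2000])
    assert np.isnan(cue.loc[2000])


def test_standardize_contract_and_round_trip():
    v = np.array([1.0, 2.0, 3.0])
    z, st_ = standardize(v)
    assert np.mean(z) == pytest.approx(0.0)
    assert np.var(z, ddof=1) == pytest.approx(1.0)
    assert st_.inverse(z) == pytest.approx(v)
    z2, _ = standardize(z)
    assert z2 == pytest.approx(z)
    with pytest.raises(ValueError):
        standardize(np.ones(5))


def test_prepare_dataset_validates_generator_output(tiny_study):
    prep = prepare_dataset(tiny_study.records, tiny_study.temperatures)
    recs = prep["records"]
    assert recs["lay_day_std"].mean() == pytest.approx(0.0, abs=1e-9)
    assert len(prep["season_table"]) == recs.groupby(["female_id", "season"]).ngroups
    assert prep["cue"].notna().all()
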
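"""Mixed-model engine and AIC stepwise selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from phenoselect.glmm import (
    ModelSpec,
    Term,
    aic,
    aic_stepwise,
    build_age_design,
    fit_mixed_model,
)


@pytest.mark.parametrize("lnL, k, expected", [(0.0, 3, 6.0), (-100.0, 5, 210.0)])
def test_aic_formula(lnL, k, expected):
    assert aic(lnL, k) == expected


def test_delta_aic_invariant_to_lnL_shift():
    assert (aic(-5.0, 2) - aic(-8.0, 3)) == pytest.approx(aic(-5.0 + 7, 2) - aic(-8.0 + 7, 3) )


def test_age_design_hinges():
    X, names = build_age_design(np.array([4.0]), "break2_6")
    row = dict(zip(names, X[0]))
    assert row["age-2+"] == 2.0 and row["age-6+"] == 0.0
    X, names = build_age_design(np.array([1.0, 3.0]), "firstyear_plus_break")
    assert X[0, names.index("first_year")] == 1.0
    assert X[1, names.index("first_year")] == 0.0


def test_age_design_per_transition_rank():
    ages = np.array([1, 2, 2, 3, 5, 5, 6], dtype=float)
    X, names = build_age_design(ages, "per_transition")
    # one column per transition between consecutive integer ages present
    assert X.shape[1] == 5  # transitions 1->2 .. 5->6
    distinct_transitions = len(np.unique(ages)) - 1 + 1  # gaps share ramp columns
    assert np.linalg.matrix_rank(np.column_stack([np.ones(len(ages)), X])) == 1 + 4


def test_age_design_rejects_bad_input():
    with pytest.raises(ValueError):
        build_age_design(np.array([0.5]), "linear")
    with pytest.raises(ValueError):
        build_age_design(np.array([2.0]), "nope")


def test_gaussian_degenerate_limit_matches_ols():
    rng = np.random.default_rng(0)
    n = 500
    x = rng.normal(size=n)
    y = 2.0 + 1.5 * x + rng.normal(0, 1, n)  # no group effect at all
    df = pd.DataFrame({"y": y, "x": x, "g": rng.integers(0, 10, n)})
    fit = fit_mixed_model(ModelSpec("y", [Term("x")], ["g"], "gaussian"), df)
    X = np.column_stack([np.ones(n), x])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert fit.estimates["estimate"].to_numpy() == pytest.approx(ols, abs=1e-3)
    assert fit.vc["g"] < 0.01 * fit.vc["residual"]


def test_poisson_intercept_only_closed_form():
    rng = np.random.default_rng(1)
    y = rng.poisson(3.0, 2000)
    df = pd.DataFrame({"y": y, "g": rng.integers(0, 50, 2000)})
    fit = fit_mixed_model(ModelSpec("y", [], ["g"], "poisson"), df)
    assert fit.estimates["estimate"].iloc[0] == pytest.approx(np.log(y.mean()), abs=0.02)


def test_binomial_slope_recovery():
    rng = np.random.default_rng(2)
    n = 5000
    x = rng.normal(size=n)
    g = rng.integers(0, 40, n)
    u = rng.normal(0, 0.5, 40)
    trials = np.full(n, 4)
    y = rng.binomial(trials, expit(-0.5 + 1.5 * x + u[g]))
    df = pd.DataFrame({"y": y, "x": x, "g": g, "n": trials})
    fit = fit_mixed_model(ModelSpec("y", [Term("x")], ["g"], "binomial", trials="n"), df)
    row = fit.estimates.loc[fit.estimates["term"] == "x"]
    est, se = float(row["estimate"].iloc[0]), float(row["se"].iloc[0])
    assert abs(est - 1.5) < 2 * se


def test_noise_covariate_never_decreases_lnL():
    """Nesting: adding a pure-noise column cannot lower the ML log-likelihood,
    and AIC penalizes it by >= 2 - 2*(lnL gain)."""
    rng = np.random.default_rng(3)
    n = 400
    x = rng.normal(size=n)
    g = rng.integers(0, 10, n)
    y = 1.0 + x + rng.normal(0, 1, n) + rng.normal(0, 0.7, 10)[g]
    df = pd.DataFrame({"y": y, "x": x, "noise": rng.normal(size=n), "g": g})
    f0 = fit_mixed_model(ModelSpec("y", [Term("x")], ["g"], "gaussian"), df)
    f1 = fit_mixed_model(ModelSpec("y", [Term("x"), Term("noise")], ["g"], "gaussian"), df)
    assert f1.loglik_ml >= f0.loglik_ml - 1e-6
    assert f1.aic >= f0.aic + 2 - 2 * (f1.loglik_ml - f0.loglik_ml) - 1e-6


def _stepwise_data(seed=7, n=2000):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    g = rng.integers(0, 20, n)
    y = 5.0 * x1 + rng.normal(0, 1, n) + rng.normal(0, 0.5, 20)[g]
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "g": g})


def test_stepwise_keeps_strong_drops_null():
    df = _stepwise_data()
    res = aic_stepwise([Term("x1"), Term("x2")], ModelSpec("y", [], ["g"], "gaussian"), df)
    assert [t.name for t in res.selected.fixed_terms] == ["x1:linear"]
    assert {"null", "screen"} <= set(res.trace["stage"])


def test_stepwise_all_null_returns_null_model():
    df = _stepwise_data()
    rng = np.random.default_rng(0)
    df["y"] = rng.normal(size=len(df))
    res = aic_stepwise([Term("x1"), Term("x2")], ModelSpec("y", [], ["g"], "gaussian"), df)
    assert res.selected.fixed_terms == []


def test_stepwise_duplicate_predictor_keeps_one():
    df = _stepwise_data()
    df["x1copy"] = df["x1"]
    res = aic_stepwise(
        [Term("x1"), Term("x1copy", label="x1copy")], ModelSpec("y", [], ["g"], "gaussian"), df
    )
    assert len(res.selected.fixed_terms) == 1


def test_stepwise_deterministic_replay():
    df = _stepwise_data()
    cands = [Term("x1"), Term("x2")]
    r1 = aic_stepwise(cands, ModelSpec("y", [], ["g"], "gaussian"), df)
    r2 = aic_stepwise(cands, ModelSpec("y", [], ["g"], "gaussian"), df)
    pd.testing.assert_frame_equal(r1.trace, r2.trace)
    assert [t.name for t in r1.selected.fixed_terms] == [t.name for t in r2.selected.fixed_terms]


def test_listwise_deletion_logged(caplog):
    df = _stepwise_data(n=300)
    df.loc[:20, "x1"] = np.nan
    fit = fit_mixed_model(ModelSpec("y", [Term("x1")], ["g"], "gaussian"), df)
    assert fit.n_obs == len(df) - 21


def test_grouping_factor_needs_levels():
    df = _stepwise_data(n=100)
    df["g"] = 0
    with pytest.raises(ValueError, match="levels"):
        fit_mixed_model(ModelSpec("y", [Term("x1")], ["g"], "gaussian"), df)
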
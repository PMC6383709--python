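"""Gaussian fitness-optimum model: curve arithmetic, pretest, sampler
correctness (grid oracle), cue slope, diagnostics and predictive checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoselect.mcmc import gelman_rubin_psrf, hpd_interval, kde_mode
from phenoselect.optimum import (
    GaussianOptimumModel,
    _reflect,
    fitness_curve,
    format_season_day,
    quadratic_pretest,
    trait_mode,
)
from phenoselect.synthetic import simulate_optimum_data


def test_fitness_curve_closed_forms():
    assert fitness_curve(0.0, A=2.5, lam=0.0, sigma=1.0) == 2.5  # peak
    assert fitness_curve(1.0, A=1.0, lam=0.0, sigma=1.0) == pytest.approx(np.exp(-1))
    # wide sigma -> flat line near A across the lay-date range
    z = fitness_curve(np.linspace(-2, 2, 9), A=5.0, lam=0.0, sigma=100.0)
    assert z.min() > 4.99 and z.max() <= 5.0
    with pytest.raises(ValueError):
        fitness_curve(0.0, 1.0, 0.0, -1.0)


@settings(derandomize=True, max_examples=50)
@given(
    x=st.floats(-3, 3), lam=st.floats(-2, 2),
    a=st.floats(0.1, 5), sig=st.floats(0.1, 10),
)
def test_fitness_curve_symmetric_around_optimum(x, lam, a, sig):
    left = fitness_curve(lam - (x - lam), a, lam, sig)
    right = fitness_curve(x, a, lam, sig)
    assert left == pytest.approx(right, rel=1e-12, abs=1e-300)


def test_reflect_stays_in_bounds():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 5, 1000)
    y = _reflect(x, -2.0, 2.0)
    assert (y >= -2).all() and (y <= 2).all()
    inside = np.array([0.3, -1.9, 1.99])
    assert _reflect(inside, -2, 2) == pytest.approx(inside)


def test_quadratic_pretest_decisions():
    df, _ = simulate_optimum_data(A=1.5, mu=-0.9, sigma=0.6, n_records=1000, seed=11)
    res = quadratic_pretest(df, "response")
    assert res["supported"] and res["delta_aic"] > 2
    rng = np.random.default_rng(0)
    flat = df.copy()
    flat["response"] = rng.poisson(1.0, len(flat))
    assert not quadratic_pretest(flat, "response")["supported"]


def test_quadratic_pretest_monotone_loglinear_prefers_linear():
    rng = np.random.default_rng(1)
    wins = 0
    for rep in range(5):
        n = 800
        x = rng.normal(0, 1, n)
        y = rng.poisson(np.exp(0.1 + 0.5 * x))
        df = pd.DataFrame({"lay_day_std": x, "season": rng.integers(0, 8, n) + 2000, "response": y})
        wins += not quadratic_pretest(df, "response")["supported"]
    assert wins >= 4


def test_sampler_matches_grid_oracle():
    """Single-year toy with known sigma and A: the sampler's posterior of the
    optimum matches a dense grid approximation within total variation 0.05."""
    rng = np.random.default_rng(3)
    x = np.clip(rng.normal(0, 1, 300), -3, 3)
    A, sig, lam_true = 1.5, 0.8, -0.5
    y = rng.poisson(A * np.exp(-(((x - lam_true) / sig) ** 2)))
    df = pd.DataFrame({"lay_day_std": x, "season": 2000, "response": y})
    m = GaussianOptimumModel(family="poisson", a_max=5, n_chains=2, n_iter=30_000,
                             burn_in=3_000, fix_sigma=sig, fix_a=A, fix_sigma_u2=0.0, seed=0)
    m.fit(df, response="response")
    draws = m.draws_["mu"].to_numpy()

    grid = np.linspace(-2, 2, 2001)
    ll = np.array([
        np.sum(y * (np.log(A) - ((x - g) / sig) ** 2) - A * np.exp(-(((x - g) / sig) ** 2)))
        for g in grid
    ])
    post = np.exp(ll - ll.max())
    post /= post.sum()
    bins = np.linspace(-2, 2, 81)
    hist, _ = np.histogram(draws, bins=bins)
    hist = hist / hist.sum()
    gridbin = np.add.reduceat(post, np.searchsorted(grid, bins[:-1]))
    gridbin = gridbin / gridbin.sum()
    tv = 0.5 * np.abs(hist - gridbin).sum()
    assert tv < 0.05


def test_psrf_constructed_chains():
    rng = np.random.default_rng(4)
    iid = rng.normal(size=(4, 2000))
    assert 1.0 <= gelman_rubin_psrf(iid) <= 1.05
    offset = iid + 5.0 * np.arange(4)[:, None]
    assert gelman_rubin_psrf(offset) > 1.1
    one = rng.normal(size=(1, 2000))
    dup = np.vstack([one, one])
    n = 2000
    assert gelman_rubin_psrf(dup, split=False) == pytest.approx(np.sqrt((n - 1) / n))


def test_flat_data_pushes_sigma_up_and_curve_flat():
    rng = np.random.default_rng(5)
    n = 800
    x = np.clip(rng.normal(0, 1, n), -3, 3)
    y = rng.poisson(1.2, n)  # no lay-date effect
    df = pd.DataFrame({"lay_day_std": x, "season": rng.integers(0, 8, n) + 2000, "response": y})
    m = GaussianOptimumModel(family="poisson", a_max=5, n_chains=2, n_iter=8_000,
                             burn_in=2_000, seed=1)
    m.fit(df, response="response")
    grid = np.linspace(-2, 2, 41)
    mu = m.draws_["mu"].to_numpy()
    A = m.draws_["A"].to_numpy()
    sig = m.draws_["sigma"].to_numpy()
    zbar = np.mean([fitness_curve(grid, A[k], mu[k], sig[k]) for k in range(0, len(mu), 10)], axis=0)
    assert zbar.max() - zbar.min() < 0.1 * A.mean()


def test_cue_slope_recovery_and_pmcmc():
    from phenoselect.mcmc import truncated_normal

    rng = np.random.default_rng(5)
    n_years, n = 16, 1400
    theta = rng.normal(0, 1, n_years)
    x = np.clip(rng.normal(0, 1, n), -3, 3)
    years = rng.integers(0, n_years, n)
    u = truncated_normal(rng, 0, np.sqrt(0.03), -2, 2, size=n_years)
    lam = -0.5 - 0.5 * theta + u
    y = rng.poisson(1.5 * np.exp(-(((x - lam[years]) / 0.8) ** 2)))
    df = pd.DataFrame({"lay_day_std": x, "season": years + 2000, "response": y})
    cue = pd.Series(theta, index=np.arange(n_years) + 2000)
    m = GaussianOptimumModel(family="poisson", a_max=5, n_chains=2, n_iter=10_000,
                             burn_in=2_000, seed=0)
    m.fit(df, response="response", cue=cue)
    assert m.draws_["B"].median() < 0
    assert m.B_pmcmc_ < 0.05
    assert abs(m.draws_["B"].median() - (-0.5)) < 0.2


def test_cue_missing_season_rejected():
    df, _ = simulate_optimum_data(n_years=4, n_records=100, seed=0)
    cue = pd.Series({2000: 0.1, 2001: -0.2})  # seasons 2002, 2003 missing
    m = GaussianOptimumModel(n_chains=1, n_iter=200, burn_in=50, seed=0)
    with pytest.raises(ValueError, match="cue missing"):
        m.fit(df, response="response", cue=cue)


def test_pmcmc_sign_conventions():
    from phenoselect.mcmc import pmcmc

    assert pmcmc(np.array([0.2, 0.5, 1.0, 0.1])) == 0.0
    rng = np.random.default_rng(6)
    assert pmcmc(rng.normal(size=100_000)) == pytest.approx(1.0, abs=0.03)


def test_binomial_latent_in_unit_interval():
    df, _ = simulate_optimum_data(A=0.8, mu=-0.3, sigma=0.9, family="binomial",
                                  trials=4, n_records=600, seed=9)
    m = GaussianOptimumModel(family="binomial", a_max=1.0, n_chains=2, n_iter=4_000,
                             burn_in=1_000, seed=2)
    m.fit(df, response="response", trials_col="trials")
    assert (m.draws_["A"] <= 1.0).all() and (m.draws_["A"] > 0).all()
    with pytest.raises(ValueError, match="a_max"):
        GaussianOptimumModel(family="binomial", a_max=5.0).fit(df, response="response", trials_col="trials")


def test_posterior_predictive_check_counts_and_zero_inflation():
    df, _ = simulate_optimum_data(A=3.0, mu=-0.3, sigma=1.3, sigma_u2=0.02,
                                  n_records=1000, seed=21)
    m = GaussianOptimumModel(family="poisson", a_max=5, n_chains=2, n_iter=6_000,
                             burn_in=1_500, seed=3)
    m.fit(df, response="response")
    ppc = m.posterior_predictive_check(n_rep=300, seed=0)
    assert len(ppc["replicates"]) == 300  # replicate count equals request
    # self-consistency: observed zero fraction inside the central 95%
    assert ppc["replicate_q025"] <= ppc["observed_zero_fraction"] <= ppc["replicate_q975"]
    # constructed misfit: injecting extra zeros is detected
    df_zi = df.copy()
    zi = np.random.default_rng(1).random(len(df_zi)) < 0.2
    df_zi.loc[zi, "response"] = 0
    m2 = GaussianOptimumModel(family="poisson", a_max=5, n_chains=2, n_iter=6_000,
                              burn_in=1_500, seed=4)
    m2.fit(df_zi, response="response")
    ppc2 = m2.posterior_predictive_check(n_rep=300, seed=0)
    assert ppc2["zero_enrichment"]


def test_trait_mode_orderings():
    rng = np.random.default_rng(7)
    sym = rng.normal(60, 10, 5000)
    res = trait_mode(sym)
    assert abs(res["mode_day"] - sym.mean()) < 2.0  # within bandwidth of the mean
    skew = 40 + rng.lognormal(2.5, 0.6, 5000)
    assert trait_mode(skew)["mode_day"] < skew.mean()
    with pytest.raises(ValueError):
        trait_mode(sym[:10])


def test_format_season_day():
    assert format_season_day(0) == "September 1"
    assert format_season_day(61) == "November 1"
    assert format_season_day(34) == "October 5"
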
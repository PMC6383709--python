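"""Bayesian Gaussian animal model for lay date.

Decomposes lay-date variance into additive genetic (V_A, structured by the
pedigree relationship matrix), permanent environment (V_PE, female
identity), social mate (V_Mate), year (V_Year) and residual (V_R)
components, with clutch number as a fixed effect.  Heritability is
h² = V_A / (V_F + V_Mate + V_PE + V_A + V_R) where V_F is the variance of
the fixed-effect predictor — the within-year phenotypic variance, i.e.
V_Year is excluded from the denominator.  Repeatability is
r² = (V_A + V_PE) over the same denominator.

The sampler is a blocked Gibbs sampler: fixed effects and each
random-effect block have conjugate Gaussian full conditionals (the genetic
block is drawn exactly in a whitened eigenbasis of the relationship
matrix, so its cost per sweep is one q×q matrix–vector product), the
residual variance has a conjugate inverse-gamma update, and the four
random-effect variances use Metropolis steps on the log scale against a
parameter-expanded prior (variance/1000 ~ F(1,1), i.e. a half-Cauchy prior
with scale sqrt(1000) on each standard deviation; the residual prior is
inverse-gamma with shape = rate = 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .mcmc import (
    effective_sample_size,
    heidelberger_welch_table,
    kde_mode,
    posterior_point_and_interval,
    psrf_table,
)
from .pedigree import Pedigree, additive_relationship

logger = logging.getLogger(__name__)

VARIANCE_COLUMNS = ["V_A", "V_PE", "V_Mate", "V_Year", "V_R"]


@dataclass(frozen=True)
class AnimalModelPriors:
    """Priors in the parameter-expansion parametrization.

    Random-effect variances: V = 1, nu = 1, alpha_mu = 0, alpha_V = 1000,
    whose marginal is variance / alpha_V ~ F(1, nu) (central because
    alpha_mu = 0), equivalently sd ~ half-Cauchy(sqrt(alpha_V)).
    Residual: inverse-gamma with V = 1, nu = 0.02, i.e. IG(nu/2, nu*V/2).
    """

    alpha_V: float = 1000.0
    nu: float = 1.0
    resid_V: float = 1.0
    resid_nu: float = 0.02


def fixed_effect_variance(X: np.ndarray, beta: np.ndarray) -> float:
    """Variance over observations of the fixed-effect linear predictor."""
    eta = np.asarray(X) @ np.asarray(beta)
    return float(np.var(eta))  # population (1/n) variance of the predictor


def _log_prior_halfcauchy_var(x: float, scale2: float) -> float:
    # log density of log-variance x when sd ~ half-Cauchy(sqrt(scale2))
    return 0.5 * x - np.log1p(np.exp(x) / scale2)


class AnimalModel(BaseEstimator):
    """Animal model estimator (scikit-learn style).

    Parameters
    ----------
    n_iter, thin, burn_in :
        MCMC protocol; the study defaults are 500,000 iterations thinned by
        10 after a 3,000-iteration burn-in (aimed at effective sample sizes
        above 8,000 for every parameter).  Reduced settings are fine for
        simulation studies but are flagged by the ESS warning.
    n_chains :
        Chains run sequentially from ``seed``-derived substreams.
    response, clutch_col, female_col, mate_col, year_col :
        Column names in the records table.
    clutch_as_factor :
        Fit clutch number as categorical rather than a linear slope.
    min_ess :
        Warn when any parameter's ESS falls below this.
    """

    def __init__(
        self,
        n_iter: int = 500_000,
        thin: int = 10,
        burn_in: int = 3_000,
        n_chains: int = 1,
        seed: int | None = None,
        priors: AnimalModelPriors | None = None,
        response: str = "lay_day",
        clutch_col: str = "clutch_number",
        female_col: str = "female_id",
        mate_col: str = "social_male_id",
        year_col: str = "season",
        clutch_as_factor: bool = False,
        min_ess: float = 8_000.0,
    ):
        self.n_iter = n_iter
        self.thin = thin
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.seed = seed
        self.priors = priors
        self.response = response
        self.clutch_col = clutch_col
        self.female_col = female_col
        self.mate_col = mate_col
        self.year_col = year_col
        self.clutch_as_factor = clutch_as_factor
        self.min_ess = min_ess

    # ------------------------------------------------------------------

    def _prepare(self, records: pd.DataFrame, pedigree: Pedigree):
        cols = [self.response, self.clutch_col, self.female_col, self.year_col]
        sub = records.copy()
        complete = sub[cols].notna().all(axis=1)
        if (~complete).any():
            logger.info("animal model: dropping %d records with missing response/clutch/ids",
                        int((~complete).sum()))
        sub = sub.loc[complete].reset_index(drop=True)

        females = pd.unique(sub[self.female_col])
        missing = [f for f in females if f not in pedigree._index]
        if missing:
            raise ValueError(f"females absent from pedigree: {missing[:10]}"
                             + (" ..." if len(missing) > 10 else ""))
        A = additive_relationship(pedigree)
        fem_idx = np.array([pedigree.index_of(f) for f in females])
        A_obs = A[np.ix_(fem_idx, fem_idx)]
        Ainv = np.linalg.inv(A_obs)

        f_codes = pd.Categorical(sub[self.female_col], categories=females).codes
        mates = sub[self.mate_col].astype(object).where(sub[self.mate_col].notna(), None)
        # a record with no known social mate gets its own mate level
        mates = [m if m is not None else f"_unknown_mate_{i}" for i, m in enumerate(mates)]
        m_codes = pd.Categorical(mates).codes
        y_codes = pd.Categorical(sub[self.year_col]).codes

        y = sub[self.response].to_numpy(dtype=float)
        if self.clutch_as_factor:
            dummies = pd.get_dummies(sub[self.clutch_col].astype(int), drop_first=True, dtype=float)
            X = np.column_stack([np.ones(len(sub))] + [dummies[c].to_numpy() for c in dummies])
            xnames = ["(Intercept)"] + [f"clutch_{c}" for c in dummies.columns]
        else:
            X = np.column_stack([np.ones(len(sub)), sub[self.clutch_col].to_numpy(dtype=float)])
            xnames = ["(Intercept)", "clutch_number"]
        return sub, y, X, xnames, f_codes, m_codes, y_codes, A_obs, Ainv, list(females)

    def _run_chain(self, rng, y, X, f_codes, m_codes, y_codes, Ainv, priors):
        n = y.size
        p = X.shape[1]
        nf = Ainv.shape[0]
        nm = int(m_codes.max()) + 1
        ny = int(y_codes.max()) + 1

        d_f = np.bincount(f_codes, minlength=nf).astype(float)
        d_m = np.bincount(m_codes, minlength=nm).astype(float)
        d_y = np.bincount(y_codes, minlength=ny).astype(float)

        # whitened eigenbasis for the exact genetic block draw
        dsqrt = np.sqrt(d_f)
        M = Ainv / dsqrt[:, None] / dsqrt[None, :]
        lam, U = np.linalg.eigh(M)
        lam = np.maximum(lam, 1e-12)

        XtX = X.T @ X
        XtX_chol = np.linalg.cholesky(np.linalg.inv(XtX))

        # state
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        a = np.zeros(nf)
        pe = np.zeros(nf)
        mate = np.zeros(nm)
        year = np.zeros(ny)
        v_y = max(np.var(y), 1.0)
        var = {"V_A": v_y / 10, "V_PE": v_y / 10, "V_Mate": v_y / 10, "V_Year": v_y / 10}
        s2r = v_y / 2

        e = y - X @ beta
        scale2 = priors.alpha_V
        prop_sd = {k: 1.0 for k in var}
        accepts = {k: 0 for k in var}

        n_store = max((self.n_iter - self.burn_in) // self.thin, 0)
        out = np.empty((n_store, 5 + p + 2))  # variances, beta, VF, h2 filled later
        stored = 0

        def mh_variance(name, quad, q):
            x = np.log(var[name])
            xp = x + prop_sd[name] * rng.standard_normal()
            lp_cur = -0.5 * q * x - 0.5 * quad * np.exp(-x) + _log_prior_halfcauchy_var(x, scale2)
            lp_prop = -0.5 * q * xp - 0.5 * quad * np.exp(-xp) + _log_prior_halfcauchy_var(xp, scale2)
            if np.log(rng.random()) < lp_prop - lp_cur:
                var[name] = float(np.exp(xp))
                accepts[name] += 1

        for it in range(self.n_iter):
            # fixed effects (flat prior)
            e += X @ beta
            mean = np.linalg.solve(XtX, X.T @ e)
            beta = mean + np.sqrt(s2r) * (XtX_chol @ rng.standard_normal(p))
            e -= X @ beta

            # genetic block, exact draw in the whitened eigenbasis
            e += a[f_codes]
            r = np.bincount(f_codes, weights=e, minlength=nf)
            prec_b = 1.0 / s2r + lam / var["V_A"]
            rhs_b = (U.T @ (r / dsqrt)) / s2r
            b = rhs_b / prec_b + rng.standard_normal(nf) / np.sqrt(prec_b)
            a = (U @ b) / dsqrt
            e -= a[f_codes]

            # iid random-intercept blocks (diagonal full conditionals)
            for codes, vec, name, d, size in (
                (f_codes, pe, "V_PE", d_f, nf),
                (m_codes, mate, "V_Mate", d_m, nm),
                (y_codes, year, "V_Year", d_y, ny),
            ):
                e += vec[codes]
                r = np.bincount(codes, weights=e, minlength=size)
                prec = d / s2r + 1.0 / var[name]
                newv = (r / s2r) / prec + rng.standard_normal(size) / np.sqrt(prec)
                if name == "V_PE":
                    pe = newv
                elif name == "V_Mate":
                    mate = newv
                else:
                    year = newv
                e -= newv[codes]

            # variance updates
            mh_variance("V_A", float(a @ (Ainv @ a)), nf)
            mh_variance("V_PE", float(pe @ pe), nf)
            mh_variance("V_Mate", float(mate @ mate), nm)
            mh_variance("V_Year", float(year @ year), ny)
            shape = 0.5 * (priors.resid_nu + n)
            rate = 0.5 * (priors.resid_nu * priors.resid_V + float(e @ e))
            s2r = float(rate / rng.gamma(shape))

            # adapt proposal scales during burn-in only
            if it < self.burn_in and (it + 1) % 50 == 0:
                for k in var:
                    rate_acc = accepts[k] / 50
                    prop_sd[k] = float(np.clip(prop_sd[k] * np.exp(rate_acc - 0.44), 1e-3, 10.0))
                    accepts[k] = 0

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and stored < n_store:
                vf = fixed_effect_variance(X, beta)
                vp = vf + var["V_Mate"] + var["V_PE"] + var["V_A"] + s2r
                out[stored, :5] = [var["V_A"], var["V_PE"], var["V_Mate"], var["V_Year"], s2r]
                out[stored, 5 : 5 + p] = beta
                out[stored, 5 + p] = vf
                out[stored, 5 + p + 1] = vp
                stored += 1
        return out[:stored]

    def fit(self, records: pd.DataFrame, pedigree: Pedigree):
        priors = self.priors or AnimalModelPriors()
        sub, y, X, xnames, f_codes, m_codes, y_codes, A_obs, Ainv, females = self._prepare(records, pedigree)
        root = np.random.SeedSequence(self.seed)
        chains = []
        for c, ss in enumerate(root.spawn(self.n_chains)):
            rng = np.random.default_rng(ss)
            draws = self._run_chain(rng, y, X, f_codes, m_codes, y_codes, Ainv, priors)
            chains.append(draws)
        draws = np.vstack(chains)
        p = X.shape[1]
        colnames = VARIANCE_COLUMNS + xnames + ["V_F", "V_P"]
        df = pd.DataFrame(draws, columns=colnames)
        df["h2"] = df["V_A"] / df["V_P"]
        df["r2"] = (df["V_A"] + df["V_PE"]) / df["V_P"]
        df["chain"] = np.repeat(np.arange(self.n_chains), [len(c) for c in chains])

        self.draws_ = df
        self.X_ = X
        self.xnames_ = xnames
        self.records_used_ = sub
        self.females_ = females
        self.A_obs_ = A_obs
        params = VARIANCE_COLUMNS + ["h2", "r2"]
        self.ess_ = {k: effective_sample_size(df[k].to_numpy()) for k in params}
        low = {k: v for k, v in self.ess_.items() if v < self.min_ess}
        self.ess_ok_ = not low
        if low:
            logger.warning("effective sample size below %.0f for: %s", self.min_ess,
                           {k: round(v) for k, v in low.items()})
        if self.n_chains > 1:
            self.psrf_ = psrf_table(df[params], self.n_chains)
        clutch_cols = [c for c in xnames if c != "(Intercept)"]
        self.pmcmc_clutch_ = (
            float(_pmcmc(df[clutch_cols[0]].to_numpy())) if clutch_cols else np.nan
        )
        return self

    # -- post-fit summaries -------------------------------------------------

    def summary(self, interval: str = "hpd") -> pd.DataFrame:
        rows = []
        for parm in VARIANCE_COLUMNS + ["V_F", "V_P", "h2", "r2"] + self.xnames_:
            s = posterior_point_and_interval(self.draws_[parm].to_numpy(), interval=interval)
            rows.append({"parameter": parm, **s, "ess": effective_sample_size(self.draws_[parm].to_numpy())})
        return pd.DataFrame(rows)

    def convergence(self) -> pd.DataFrame:
        params = VARIANCE_COLUMNS + ["h2", "r2"]
        return heidelberger_welch_table(self.draws_[params])


def _pmcmc(draws):
    from .mcmc import pmcmc

    return pmcmc(draws)


def fit_animal_model(
    records: pd.DataFrame,
    pedigree: Pedigree,
    priors: AnimalModelPriors | None = None,
    n_iter: int = 500_000,
    thin: int = 10,
    burn_in: int = 3_000,
    n_chains: int = 1,
    seed: int | None = None,
    **kwargs,
) -> AnimalModel:
    """Functional wrapper over :class:`AnimalModel`."""
    model = AnimalModel(
        n_iter=n_iter, thin=thin, burn_in=burn_in, n_chains=n_chains, seed=seed,
        priors=priors, **kwargs,
    )
    return model.fit(records, pedigree)


def heritability_repeatability(fit: AnimalModel | pd.DataFrame) -> dict:
    """Posterior h² and r² with mode/median/95% HPD summaries.

    Ratios are computed per posterior draw (mode of the ratio draws, not
    ratio of the component modes — the two differ, which is documented).
    """
    draws = fit.draws_ if isinstance(fit, AnimalModel) else fit
    out = {}
    for key in ("h2", "r2"):
        d = draws[key].to_numpy()
        out[key] = {"draws": d, **posterior_point_and_interval(d)}
    return out


def mother_daughter_h2(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    id_col: str = "female_id",
    value_col: str = "lay_day",
    double_slope: bool = True,
) -> dict:
    """Heritability from a mother–daughter regression of mean lay dates.

    Regresses each daughter's mean phenotype on her dam's mean phenotype.
    Under a single-parent regression the expected slope is h²/2, so the
    default convention reports h² = 2 × slope; the raw slope is always
    included since published values sometimes are the undoubled slope.
    """
    means = phenotypes.groupby(id_col)[value_col].mean()
    pairs = []
    for i, ind in enumerate(pedigree.ids):
        d = pedigree.dam[i]
        if d < 0:
            continue
        dam_id = pedigree.ids[d]
        if ind in means.index and dam_id in means.index:
            pairs.append((means.loc[dam_id], means.loc[ind]))
    n = len(pairs)
    low_power = n < 30
    if low_power:
        logger.warning("only %d mother-daughter pairs; regression is low-powered", n)
    if n < 3:
        return {"slope": np.nan, "h2": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                "n_pairs": n, "low_power": True}
    x = np.array([p[0] for p in pairs])
    z = np.array([p[1] for p in pairs])
    res = stats.linregress(x, z)
    mult = 2.0 if double_slope else 1.0
    return {
        "slope": float(res.slope),
        "h2": float(mult * res.slope),
        "se": float(mult * res.stderr),
        "t": float(res.slope / res.stderr) if res.stderr > 0 else np.nan,
        "p": float(res.pvalue),
        "n_pairs": n,
        "low_power": low_power,
        "doubled": double_slope,
    }


def mcmc_convergence(draws: pd.DataFrame) -> pd.DataFrame:
    """Heidelberger–Welch + ESS table for a draws frame."""
    return heidelberger_welch_table(draws)
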
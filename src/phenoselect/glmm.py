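"""Mixed models and AIC model selection for the phenology analyses.

Provides design-matrix builders for the candidate age models (linear,
quadratic, broken-line with knots, per-transition, first-year indicator),
a mixed-model fitter for Gaussian / binomial / Poisson responses with
crossed random intercepts, and the stepwise AIC selection procedure
(single-variable screening, full model of survivors, drop-one to a fixed
point, parsimony rule within ΔAIC < 2).

The fitter maximizes the Laplace-approximate marginal likelihood for
binomial/Poisson responses (exact for Gaussian, where maximum likelihood
and REML are both available).  AIC always uses the ML log-likelihood;
Gaussian point estimates are reported at REML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

AGE_VARIANTS = ("linear", "quadratic", "break2", "break2_6", "per_transition", "firstyear_plus_break")


def _hinge(x: np.ndarray, knot: float) -> np.ndarray:
    return np.maximum(0.0, x - knot)


def build_age_design(ages: np.ndarray, variant: str) -> tuple[np.ndarray, list[str]]:
    """Design columns (no intercept) for one candidate age model.

    Broken-line bases use hinge terms ``max(0, age − knot)``; the
    per-transition variant has one bounded ramp column per age transition
    (slope free between every pair of consecutive ages); the first-year
    variant combines an ``age == 1`` indicator with a linear slope and a
    slope change after age 6 (a discontinuous broken-line with breaks at
    ages 1 and 6).
    """
    a = np.asarray(ages, dtype=float)
    if np.any(a < 1):
        raise ValueError("ages must be >= 1")
    if variant == "linear":
        return a[:, None], ["age"]
    if variant == "quadratic":
        return np.column_stack([a, a**2]), ["age", "age^2"]
    if variant == "break2":
        return np.column_stack([a, _hinge(a, 2)]), ["age", "age-2+"]
    if variant == "break2_6":
        return np.column_stack([a, _hinge(a, 2), _hinge(a, 6)]), ["age", "age-2+", "age-6+"]
    if variant == "per_transition":
        max_age = int(a.max())
        cols, names = [], []
        for t in range(1, max_age):
            cols.append(np.clip(a - t, 0.0, 1.0))
            names.append(f"age{t}->{t + 1}")
        return np.column_stack(cols), names
    if variant == "firstyear_plus_break":
        return (
            np.column_stack([(a == 1).astype(float), a, _hinge(a, 6)]),
            ["first_year", "age", "age-6+"],
        )
    raise ValueError(f"unknown age-model variant {variant!r}; choose from {AGE_VARIANTS}")


@dataclass(frozen=True)
class Term:
    """One fixed-effect term descriptor.

    kind: 'linear' | 'quadratic' | 'categorical' | 'broken' (with knots)
          | 'firstyear' | 'age' (with an ``build_age_design`` variant)
    """

    field: str
    kind: str = "linear"
    knots: tuple = ()
    variant: str | None = None
    label: str | None = None

    @property
    def name(self) -> str:
        return self.label or (f"{self.field}:{self.kind}" + (f"({self.variant})" if self.variant else ""))

    def build(self, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        x = data[self.field].to_numpy()
        if self.kind == "linear":
            return np.asarray(x, float)[:, None], [self.field]
        if self.kind == "quadratic":
            xf = np.asarray(x, float)
            return np.column_stack([xf, xf**2]), [self.field, f"{self.field}^2"]
        if self.kind == "quadratic_only":
            xf = np.asarray(x, float)
            return (xf**2)[:, None], [f"{self.field}^2"]
        if self.kind == "categorical":
            d = pd.get_dummies(pd.Series(x), drop_first=True, dtype=float)
            return d.to_numpy(), [f"{self.field}[{c}]" for c in d.columns]
        if self.kind == "broken":
            if not self.knots or list(self.knots) != sorted(self.knots):
                raise ValueError("broken-line term needs strictly increasing knots")
            xf = np.asarray(x, float)
            cols = [xf] + [_hinge(xf, k) for k in self.knots]
            return np.column_stack(cols), [self.field] + [f"{self.field}-{k}+" for k in self.knots]
        if self.kind == "firstyear":
            return (np.asarray(x, float) == 1).astype(float)[:, None], [f"{self.field}==1"]
        if self.kind == "age":
            return build_age_design(np.asarray(x, float), self.variant or "linear")
        raise ValueError(f"unknown term kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Response + fixed terms + random intercept factors + family."""

    response: str
    fixed_terms: list[Term] = field(default_factory=list)
    random_terms: list[str] = field(default_factory=list)
    family: str = "gaussian"
    trials: str | None = None  # column of binomial trial counts

    def required_columns(self) -> list[str]:
        cols = [self.response] + [t.field for t in self.fixed_terms] + list(self.random_terms)
        if self.trials:
            cols.append(self.trials)
        return cols

    def with_terms(self, terms: Sequence[Term]) -> "ModelSpec":
        return replace(self, fixed_terms=list(terms))


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion, ``2k − 2 lnL``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * lnL


# ---------------------------------------------------------------------------
# families

class _Family:
    name: str

    @staticmethod
    def loglik(y, eta, trials):
        raise NotImplementedError

    @staticmethod
    def mu_weight(eta, trials):
        """(mean-scale fitted value used in the score, Newton weight)."""
        raise NotImplementedError


class _Gaussian(_Family):
    name = "gaussian"


class _Binomial(_Family):
    name = "binomial"

    @staticmethod
    def loglik(y, eta, trials):
        # y = successes, logit link; binomial coefficient constant included
        p_log = -np.logaddexp(0.0, -eta)
        q_log = -np.logaddexp(0.0, eta)
        const = special.gammaln(trials + 1) - special.gammaln(y + 1) - special.gammaln(trials - y + 1)
        return float(np.sum(const + y * p_log + (trials - y) * q_log))

    @staticmethod
    def mu_weight(eta, trials):
        p = special.expit(eta)
        return trials * p, trials * p * (1 - p)


class _Poisson(_Family):
    name = "poisson"

    @staticmethod
    def loglik(y, eta, trials):
        return float(np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1)))

    @staticmethod
    def mu_weight(eta, trials):
        mu = np.exp(eta)
        return mu, mu


_FAMILIES = {"gaussian": _Gaussian, "binomial": _Binomial, "poisson": _Poisson}

_LOGV_MIN, _LOGV_MAX = -12.0, 12.0


@dataclass
class FitResult:
    """Mixed-model fit: estimates at the reporting criterion, ML/REML
    log-likelihoods, AIC (ML) and variance components."""

    estimates: pd.DataFrame  # term, estimate, se, stat, p
    vc: dict  # variance per random factor (+ 'residual' for gaussian)
    loglik_ml: float
    loglik_reml: float
    aic: float
    k: int
    n_obs: int
    converged: bool
    family: str
    spec: ModelSpec | None = None

    @property
    def delta_vs(self):  # pragma: no cover - convenience
        return None


class LaplaceGLMM(BaseEstimator):
    """Random-intercept GLMM fitted by (Laplace-approximate) maximum likelihood.

    Gaussian responses use the exact marginal likelihood (ML or REML);
    binomial (logit) and Poisson (log) responses use the Laplace
    approximation, matching the standard single-quadrature GLMM likelihood.
    Supports any number of crossed random-intercept factors.

    Parameters follow the scikit-learn convention; fitted attributes carry a
    trailing underscore (``coef_``, ``vc_``, ``loglik_``, ...).
    """

    def __init__(self, family: str = "gaussian", reml: bool = False, max_inner: int = 200, tol: float = 1e-9):
        self.family = family
        self.reml = reml
        self.max_inner = max_inner
        self.tol = tol

    # -- internals ---------------------------------------------------------
    #
    # Random intercepts only, so every Z'Z-type product reduces to bincount
    # aggregation over the factor codes; nothing n x q is ever materialized.

    def _eta(self, X, delta, codes, q_per):
        p = X.shape[1]
        eta = X @ delta[:p]
        off = p
        for c, qg in zip(codes, q_per):
            eta += delta[off : off + qg][c]
            off += qg
        return eta

    def _assemble_H(self, X, wts, codes, q_per, P):
        """Joint negative Hessian of the penalized log-likelihood."""
        n, p = X.shape
        q = int(sum(q_per))
        H = np.zeros((p + q, p + q))
        Xw = X * wts[:, None]
        H[:p, :p] = Xw.T @ X
        offs = np.concatenate([[p], p + np.cumsum(q_per)]).astype(int)
        for a, (ca, qa) in enumerate(zip(codes, q_per)):
            # X x factor cross blocks
            blk = np.stack([np.bincount(ca, weights=Xw[:, j], minlength=qa) for j in range(p)])
            H[:p, offs[a] : offs[a] + qa] = blk
            H[offs[a] : offs[a] + qa, :p] = blk.T
            # factor diagonal
            H[offs[a] : offs[a] + qa, offs[a] : offs[a] + qa] = np.diag(
                np.bincount(ca, weights=wts, minlength=qa)
            )
            # factor x factor cross blocks
            for b in range(a + 1, len(codes)):
                cb, qb = codes[b], q_per[b]
                cross = np.zeros((qa, qb))
                np.add.at(cross, (ca, cb), wts)
                H[offs[a] : offs[a] + qa, offs[b] : offs[b] + qb] = cross
                H[offs[b] : offs[b] + qb, offs[a] : offs[a] + qa] = cross.T
        H[np.diag_indices_from(H)] += P
        return H

    def _inner_mode(self, logv, X, y, codes, q_per, trials, family):
        """Penalized Newton for the joint (beta, u) mode given log-variances."""
        n, p = X.shape
        q = int(sum(q_per))
        variances = np.exp(logv[: len(q_per)])
        prior_prec = (
            np.concatenate([np.full(qg, 1.0 / vg) for qg, vg in zip(q_per, variances)])
            if q
            else np.zeros(0)
        )
        delta = np.zeros(p + q)
        P = np.concatenate([np.zeros(p), prior_prec])
        obj = -np.inf
        H = None
        for _ in range(self.max_inner):
            eta = self._eta(X, delta, codes, q_per)
            mu, wts = family.mu_weight(eta, trials)
            resid = y - mu
            grad = np.concatenate(
                [X.T @ resid]
                + [np.bincount(c, weights=resid, minlength=qg) for c, qg in zip(codes, q_per)]
            ) - P * delta
            H = self._assemble_H(X, wts, codes, q_per, P)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = np.linalg.solve(H, grad)
            obj0 = family.loglik(y, eta, trials) - 0.5 * float(np.sum(P * delta**2))
            t = 1.0
            for _ in range(30):
                cand = delta + t * step
                eta_c = self._eta(X, cand, codes, q_per)
                obj = family.loglik(y, eta_c, trials) - 0.5 * float(np.sum(P * cand**2))
                if obj >= obj0 - 1e-12:
                    break
                t /= 2
            delta = delta + t * step
            if abs(obj - obj0) < self.tol * (1 + abs(obj)):
                break
        eta = self._eta(X, delta, codes, q_per)
        mu, wts = family.mu_weight(eta, trials)
        H = self._assemble_H(X, wts, codes, q_per, P)
        return delta, H, P, eta

    def _loglik_gaussian(self, logv, reml):
        """Exact Gaussian marginal likelihood from cached cross-products."""
        c = self._cache
        n, p = c["n"], c["p"]
        nvc = len(c["q_per"])
        variances = np.exp(logv[:nvc])
        s2r = np.exp(logv[-1])
        q = int(sum(c["q_per"]))
        if q:
            dinv = np.concatenate([np.full(qg, 1.0 / vg) for qg, vg in zip(c["q_per"], variances)])
            M = c["ZtZ"] / s2r + np.diag(dinv)
            cho = np.linalg.cholesky(M)
            logdetV = (
                n * np.log(s2r)
                + float(np.sum([qg * lv for qg, lv in zip(c["q_per"], logv[:nvc])]))
                + 2.0 * float(np.sum(np.log(np.diag(cho))))
            )
            ZtXy = np.column_stack([c["ZtX"], c["Zty"]])
            sol = np.linalg.solve(M, ZtXy / s2r)
            XtViX = (c["XtX"] - c["ZtX"].T @ sol[:, :p]) / s2r
            XtViy = (c["Xty"] - c["ZtX"].T @ sol[:, p]) / s2r
            ytViy = (c["yty"] - c["Zty"] @ sol[:, p]) / s2r
        else:
            logdetV = n * np.log(s2r)
            XtViX = c["XtX"] / s2r
            XtViy = c["Xty"] / s2r
            ytViy = c["yty"] / s2r
        # lstsq tolerates aliased (collinear) columns; AIC still counts them
        beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
        quad = float(ytViy - 2 * beta @ XtViy + beta @ XtViX @ beta)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdetV + quad)
        if reml:
            eig = np.linalg.eigvalsh(XtViX)
            ld = float(np.sum(np.log(eig[eig > 1e-10])))
            ll += -0.5 * ld + 0.5 * p * np.log(2 * np.pi)
        return ll, beta, XtViX

    def _loglik_laplace(self, logv, X, y, codes, q_per, trials, family):
        delta, H, P, eta = self._inner_mode(logv, X, y, codes, q_per, trials, family)
        p = X.shape[1]
        q = int(sum(q_per))
        u = delta[p:]
        ll_data = family.loglik(y, eta, trials)
        pen = 0.5 * float(np.sum(P[p:] * u**2))
        nvc = len(q_per)
        logdetD = float(np.sum([qg * lv for qg, lv in zip(q_per, logv[:nvc])]))
        if q:
            sign, ld = np.linalg.slogdet(H[p:, p:])
        else:
            ld = 0.0
        ll = ll_data - pen - 0.5 * logdetD - 0.5 * ld
        return ll, delta, H

    # -- public API --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, groups: dict[str, np.ndarray] | None = None,
            trials: np.ndarray | None = None, colnames: list[str] | None = None):
        """Fit the model.

        X includes the intercept column.  ``groups`` maps factor name →
        integer codes per observation.  ``trials`` is required for the
        binomial family.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        groups = groups or {}
        self.group_names_ = list(groups.keys())
        codes_list = []
        q_per = []
        self.group_levels_ = {}
        for gname, codes in groups.items():
            codes = np.asarray(codes)
            levels, inv = np.unique(codes, return_inverse=True)
            if len(levels) < 2:
                raise ValueError(f"grouping factor {gname!r} needs >= 2 levels")
            codes_list.append(inv)
            q_per.append(len(levels))
            self.group_levels_[gname] = levels
        q_per = tuple(q_per)

        # cached cross-products (random intercepts: Z columns are indicators)
        q = int(sum(q_per))
        offs = np.concatenate([[0], np.cumsum(q_per)]).astype(int)
        ZtZ = np.zeros((q, q))
        ZtX = np.zeros((q, p))
        Zty = np.zeros(q)
        ones = np.ones(n)
        for a, (ca, qa) in enumerate(zip(codes_list, q_per)):
            ZtZ[offs[a] : offs[a] + qa, offs[a] : offs[a] + qa] = np.diag(
                np.bincount(ca, minlength=qa).astype(float)
            )
            for b in range(a + 1, len(codes_list)):
                cb, qb = codes_list[b], q_per[b]
                cross = np.zeros((qa, qb))
                np.add.at(cross, (ca, cb), ones)
                ZtZ[offs[a] : offs[a] + qa, offs[b] : offs[b] + qb] = cross
                ZtZ[offs[b] : offs[b] + qb, offs[a] : offs[a] + qa] = cross.T
            ZtX[offs[a] : offs[a] + qa] = np.stack(
                [np.bincount(ca, weights=X[:, j], minlength=qa) for j in range(p)]
            ).T
            Zty[offs[a] : offs[a] + qa] = np.bincount(ca, weights=y, minlength=qa)
        self._cache = {
            "n": n, "p": p, "q_per": q_per,
            "XtX": X.T @ X, "Xty": X.T @ y, "yty": float(y @ y),
            "ZtZ": ZtZ, "ZtX": ZtX, "Zty": Zty,
        }
        self._codes = codes_list
        family = _FAMILIES[self.family]
        if self.family == "binomial":
            if trials is None:
                raise ValueError("binomial family requires trial counts")
            trials = np.asarray(trials, dtype=float)
        else:
            trials = np.zeros(n)

        n_vc = len(q_per)
        if self.family == "gaussian":
            y_var = max(np.var(y), 1e-6)
            x0 = np.concatenate([np.full(n_vc, np.log(y_var / (n_vc + 1.0) + 1e-8)), [np.log(y_var / 2 + 1e-8)]])

            def nll(logv):
                lv = np.clip(logv, _LOGV_MIN + np.log(y_var + 1e-12), _LOGV_MAX)
                try:
                    ll, *_ = self._loglik_gaussian(lv, reml=False)
                except np.linalg.LinAlgError:
                    return 1e12
                return -ll
        else:
            x0 = np.full(n_vc, np.log(0.5))

            def nll(logv):
                lv = np.clip(logv, _LOGV_MIN, _LOGV_MAX)
                try:
                    ll, *_ = self._loglik_laplace(lv, X, y, self._codes, q_per, trials, family)
                except np.linalg.LinAlgError:
                    return 1e12
                return -ll

        if len(x0):
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000})
            lo = _LOGV_MIN if self.family != "gaussian" else _LOGV_MIN + np.log(max(np.var(y), 1e-6) + 1e-12)
            logv_ml = np.clip(np.asarray(res.x, dtype=float), lo, _LOGV_MAX)
            self.converged_ = bool(res.success)
            if not res.success:
                logger.warning("variance optimization did not converge: %s", res.message)
        else:  # no random terms at all (gaussian would still have residual)
            logv_ml = x0
            self.converged_ = True

        # ML log-likelihood and estimates
        if self.family == "gaussian":
            lv = np.clip(logv_ml, _LOGV_MIN + np.log(max(np.var(y), 1e-6) + 1e-12), _LOGV_MAX)
            ll_ml, beta_ml, XtViX_ml = self._loglik_gaussian(lv, reml=False)
            # REML pass for reporting
            def nll_reml(logv):
                lvr = np.clip(logv, _LOGV_MIN + np.log(max(np.var(y), 1e-6) + 1e-12), _LOGV_MAX)
                try:
                    ll, *_ = self._loglik_gaussian(lvr, reml=True)
                except np.linalg.LinAlgError:
                    return 1e12
                return -ll

            res_r = optimize.minimize(nll_reml, logv_ml, method="Nelder-Mead",
                                      options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 4000})
            lv_r = np.clip(res_r.x, _LOGV_MIN + np.log(max(np.var(y), 1e-6) + 1e-12), _LOGV_MAX)
            ll_reml, beta_r, XtViX_r = self._loglik_gaussian(lv_r, reml=True)
            self.coef_ = beta_r
            cov = np.linalg.pinv(XtViX_r)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            stat = self.coef_ / se
            dof = max(n - p, 1)
            pvals = 2 * stats.t.sf(np.abs(stat), dof)
            self.vc_ = {g: float(np.exp(lv_r[i])) for i, g in enumerate(self.group_names_)}
            self.vc_["residual"] = float(np.exp(lv_r[-1]))
            self.loglik_reml_ = float(ll_reml)
            k = p + n_vc + 1
        else:
            ll_ml, delta, H = self._loglik_laplace(logv_ml, X, y, self._codes, q_per, trials, family)
            self.coef_ = delta[:p]
            cov = np.linalg.pinv(H)[:p, :p]
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
            stat = self.coef_ / se
            pvals = 2 * stats.norm.sf(np.abs(stat))
            self.u_ = delta[p:]
            self.vc_ = {g: float(np.exp(logv_ml[i])) for i, g in enumerate(self.group_names_)}
            self.loglik_reml_ = np.nan
            k = p + n_vc

        self.loglik_ml_ = float(ll_ml)
        self.k_ = k
        self.aic_ = aic(self.loglik_ml_, k)
        self.se_ = se
        self.stat_ = stat
        self.pvalues_ = pvals
        self.n_obs_ = n
        self.colnames_ = colnames or [f"x{i}" for i in range(p)]
        return self


def build_design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + term columns for a model spec."""
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in spec.fixed_terms:
        Xc, nm = term.build(data)
        cols.append(Xc)
        names.extend(nm)
    return np.column_stack(cols), names


def fit_mixed_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a model spec to a prepared table (listwise deletion, logged)."""
    need = spec.required_columns()
    sub = data[list(dict.fromkeys(need))].copy()
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        logger.info("listwise deletion of %d/%d rows with missing values for %s",
                    int((~complete).sum()), len(sub), spec.response)
    d = data.loc[complete].reset_index(drop=True)
    X, names = build_design(spec, d)
    groups = {g: d[g].to_numpy() for g in spec.random_terms}
    trials = d[spec.trials].to_numpy(dtype=float) if spec.trials else None
    y = d[spec.response].to_numpy(dtype=float)
    model = LaplaceGLMM(family=spec.family)
    model.fit(X, y, groups=groups, trials=trials, colnames=names)
    est = pd.DataFrame(
        {"term": names, "estimate": model.coef_, "se": model.se_, "stat": model.stat_, "p": model.pvalues_}
    )
    return FitResult(
        estimates=est,
        vc=model.vc_,
        loglik_ml=model.loglik_ml_,
        loglik_reml=model.loglik_reml_,
        aic=model.aic_,
        k=model.k_,
        n_obs=model.n_obs_,
        converged=model.converged_,
        family=spec.family,
        spec=spec,
    )


@dataclass
class StepwiseResult:
    selected: ModelSpec  # best inferential model (parsimony within dAIC < 2)
    best_predictive: ModelSpec
    trace: pd.DataFrame
    fits: dict


def aic_stepwise(
    candidate_terms: Sequence[Term],
    base_spec: ModelSpec,
    data: pd.DataFrame,
    delta: float = 2.0,
) -> StepwiseResult:
    """The AIC stepwise selection procedure.

    1. Each candidate is tested alone against the null model; candidates not
       improving AIC by more than ``delta`` are discarded.
    2. Survivors form a full model.
    3. Terms are dropped one by one; the best (lowest-AIC) model is adopted
       and the drop loop repeats until no drop improves the AIC.
    4. The best *inferential* model is the most parsimonious model within
       ``delta`` AIC of the best predictive model, among all models
       evaluated along the way.

    Deterministic given the data and candidate order; the full trace is
    returned.
    """
    rows = []
    fits: dict = {}

    def key_of(terms):
        return tuple(t.name for t in terms)

    def fit_terms(terms, stage):
        key = key_of(terms)
        if key not in fits:
            fits[key] = fit_mixed_model(base_spec.with_terms(terms), data)
        f = fits[key]
        rows.append({"stage": stage, "model": "+".join(key) or "(null)", "k": f.k,
                     "lnL": f.loglik_ml, "AIC": f.aic})
        return f

    null_fit = fit_terms([], "null")
    survivors = []
    for term in candidate_terms:
        f = fit_terms([term], "screen")
        if null_fit.aic - f.aic > delta:
            survivors.append(term)
        else:
            logger.info("stepwise: candidate %s not significant alone (dAIC=%.2f)",
                        term.name, null_fit.aic - f.aic)
    if not survivors:
        trace = pd.DataFrame(rows)
        trace["dAIC"] = trace["AIC"] - trace["AIC"].min()
        return StepwiseResult(base_spec.with_terms([]), base_spec.with_terms([]), trace, fits)

    current = list(survivors)
    current_fit = fit_terms(current, "full")
    while len(current) > 0:
        best_drop, best_fit = None, current_fit
        for i in range(len(current)):
            reduced = current[:i] + current[i + 1 :]
            f = fit_terms(reduced, "drop")
            if f.aic < best_fit.aic - 1e-9:
                best_drop, best_fit = i, f
        if best_drop is None:
            break
        dropped = current.pop(best_drop)
        logger.info("stepwise: dropped %s (AIC %.2f -> %.2f)", dropped.name, current_fit.aic, best_fit.aic)
        current_fit = best_fit

    best_aic = current_fit.aic
    # parsimony rule over every model evaluated
    cand = [(k, f) for k, f in fits.items() if f.aic <= best_aic + delta]
    cand.sort(key=lambda kf: (kf[1].k, list(fits).index(kf[0])))
    sel_key = cand[0][0]
    if len(cand) > 1 and cand[0][1].k == cand[1][1].k:
        logger.info("stepwise: parsimony tie between %s and %s; first evaluated retained",
                    cand[0][0], cand[1][0])
    by_name = {t.name: t for t in candidate_terms}
    selected_terms = [by_name[nm] for nm in sel_key]
    trace = pd.DataFrame(rows)
    trace["dAIC"] = trace["AIC"] - trace["AIC"].min()
    return StepwiseResult(
        base_spec.with_terms(selected_terms),
        base_spec.with_terms(current),
        trace,
        fits,
    )


def write_aic_trace(trace: pd.DataFrame, path) -> None:
    trace.to_csv(path, sep="\t", index=False)
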
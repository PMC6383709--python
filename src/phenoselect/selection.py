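"""Phenotypic selection statistics on lay date.

Robertson's selection differential (covariance between the trait and
relative fitness), its trait-SD-standardized version, Lande–Arnold
directional and quadratic selection gradients from a least-squares
regression of relative fitness on the standardized trait and its square,
and non-parametric bootstrap standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def relative_fitness(W: np.ndarray) -> np.ndarray:
    """Relative fitness ``w_i = W_i / mean(W)`` (mean exactly 1)."""
    W = np.asarray(W, dtype=float)
    m = W.mean()
    if m <= 0:
        raise ValueError("mean fitness must be positive to compute relative fitness")
    return W / m


def _cov(x, y, ddof=1):
    return float(np.cov(x, y, ddof=ddof)[0, 1])


def selection_differential(
    trait: np.ndarray,
    W: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    ddof: int = 1,
) -> tuple[float, float]:
    """Robertson selection differential ``S = cov(trait, w)`` ± bootstrap SE.

    ``S`` is in trait units (days); the covariance uses the sample (n−1)
    denominator by default.  The SE comes from a non-parametric bootstrap
    over records.
    """
    trait = np.asarray(trait, dtype=float)
    W = np.asarray(W, dtype=float)
    if trait.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(trait) == 0:
        logger.warning("zero trait variance; selection differential is 0")
        return 0.0, 0.0
    w = relative_fitness(W)
    S = _cov(trait, w, ddof=ddof)
    se = bootstrap_se(
        lambda t, f: _cov(t, relative_fitness(f), ddof=ddof),
        (trait, W),
        B=n_boot,
        seed=seed,
    )
    return S, se


def standardized_differential(trait, W, ddof: int = 1) -> float:
    """Differential in trait standard-deviation units."""
    trait = np.asarray(trait, dtype=float)
    w = relative_fitness(np.asarray(W, dtype=float))
    return _cov(trait, w, ddof=ddof) / float(np.std(trait, ddof=ddof))


def selection_gradients(
    trait: np.ndarray,
    W: np.ndarray,
    double_quadratic: bool = True,
) -> dict:
    """Lande–Arnold standardized selection gradients.

    Relative fitness is regressed on the standardized trait ``z`` and
    ``z²``; ``beta`` is the linear coefficient and ``gamma`` is, by the
    Lande–Arnold convention, twice the quadratic regression coefficient
    (``double_quadratic=False`` reports the raw coefficient).  SEs come
    from the regression (scaled accordingly for gamma).
    """
    trait = np.asarray(trait, dtype=float)
    W = np.asarray(W, dtype=float)
    sd = np.std(trait, ddof=1)
    if sd == 0:
        raise ValueError("constant trait: gradients undefined")
    z = (trait - trait.mean()) / sd
    w = relative_fitness(W)
    X = np.column_stack([np.ones_like(z), z, z**2])
    coef, res, rank, _ = np.linalg.lstsq(X, w, rcond=None)
    fitted = X @ coef
    dof = max(len(w) - X.shape[1], 1)
    s2 = float(np.sum((w - fitted) ** 2)) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    mult = 2.0 if double_quadratic else 1.0
    return {
        "beta": float(coef[1]),
        "beta_se": float(se[1]),
        "gamma": float(mult * coef[2]),
        "gamma_se": float(mult * se[2]),
        "n_obs": int(len(w)),
        "double_quadratic": double_quadratic,
    }


def bootstrap_se(statistic, data: tuple, B: int = 2000, seed: int | None = None) -> float:
    """Non-parametric bootstrap SE of a statistic of paired record vectors.

    Resamples records with replacement; degenerate resamples (on which the
    statistic raises or returns non-finite) are skipped and counted.
    """
    if B < 200:
        raise ValueError("use at least 200 bootstrap replicates")
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].size
    vals = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            v = statistic(*(a[idx] for a in arrays))
        except (ValueError, ZeroDivisionError):
            skipped += 1
            continue
        if not np.isfinite(v):
            skipped += 1
            continue
        vals.append(v)
    if skipped:
        logger.info("bootstrap: skipped %d/%d degenerate resamples", skipped, B)
    if len(vals) < 2:
        return 0.0
    return float(np.std(vals, ddof=1))


@dataclass
class SelectionStats:
    """Bundle of selection statistics for one trait/fitness pairing."""

    S: float
    S_se: float
    S_std: float
    beta: float
    beta_se: float
    gamma: float
    gamma_se: float
    n_obs: int
    n_boot: int
    seed: int | None
    double_quadratic: bool = True

    @classmethod
    def compute(cls, trait, W, n_boot: int = 2000, seed: int | None = None,
                double_quadratic: bool = True) -> "SelectionStats":
        S, S_se = selection_differential(trait, W, n_boot=n_boot, seed=seed)
        grads = selection_gradients(trait, W, double_quadratic=double_quadratic)
        return cls(
            S=S,
            S_se=S_se,
            S_std=standardized_differential(trait, W),
            beta=grads["beta"],
            beta_se=grads["beta_se"],
            gamma=grads["gamma"],
            gamma_se=grads["gamma_se"],
            n_obs=grads["n_obs"],
            n_boot=n_boot,
            seed=seed,
            double_quadratic=double_quadratic,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"statistic": "selection_differential_days", "estimate": self.S, "se": self.S_se},
                {"statistic": "standardized_differential", "estimate": self.S_std, "se": np.nan},
                {"statistic": "beta", "estimate": self.beta, "se": self.beta_se},
                {"statistic": "gamma", "estimate": self.gamma, "se": self.gamma_se},
            ]
        ).assign(n=self.n_obs, n_boot=self.n_boot, seed=self.seed)
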
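"""MCMC diagnostics and posterior summaries.

Shared machinery for the samplers in this package: classic split-chain
Gelman–Rubin potential scale reduction factor (PSRF), Heidelberger–Welch
stationarity and half-width tests, effective sample size, kernel-density
posterior modes, highest-density intervals and the Bayesian two-sided
sign test (pMCMC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def gelman_rubin_psrf(chains: np.ndarray, split: bool = True) -> float:
    """Classic (non rank-normalized) potential scale reduction factor.

    ``chains`` is ``(n_chains, n_draws)``.  Each chain is split in half by
    default so within-chain drift also inflates the factor.  Identical
    chains give ``sqrt((n-1)/n)``; diverging chains give values ≫ 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2:
        raise ValueError("chains must be 2-D (n_chains, n_draws)")
    if split:
        half = c.shape[1] // 2
        c = np.concatenate([c[:, :half], c[:, half : 2 * half]], axis=0)
    m, n = c.shape
    if m < 2:
        raise ValueError("PSRF needs at least 2 (split) chains")
    means = c.mean(axis=1)
    W = c.var(axis=1, ddof=1).mean()
    B_over_n = np.var(means, ddof=1)
    if W == 0:
        return np.nan if B_over_n > 0 else 1.0
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def psrf_table(draws: dict[str, np.ndarray] | pd.DataFrame, n_chains: int) -> pd.DataFrame:
    """Per-parameter PSRF for draws stored as stacked chains.

    Each parameter's draws are a 1-D vector of ``n_chains`` consecutive
    chains of equal length.
    """
    if isinstance(draws, pd.DataFrame):
        draws = {c: draws[c].to_numpy() for c in draws.columns}
    rows = []
    for name, v in draws.items():
        v = np.asarray(v, dtype=float)
        n = v.size // n_chains
        c = v[: n * n_chains].reshape(n_chains, n)
        rows.append({"parameter": name, "psrf": gelman_rubin_psrf(c), "converged": gelman_rubin_psrf(c) <= 1.1})
    return pd.DataFrame(rows)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial monotone positive sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    # pair sums Gamma_k = rho_{2k} + rho_{2k+1}; truncate at first negative, enforce monotone
    max_pairs = (n - 1) // 2
    gammas = []
    for k in range(max_pairs):
        g = acf[2 * k] + acf[2 * k + 1]
        if g <= 0:
            break
        gammas.append(g)
    if not gammas:
        return float(n)
    gammas = np.minimum.accumulate(gammas)
    tau = -1.0 + 2.0 * np.sum(gammas)
    return float(min(n, n / max(tau, 1e-12)))


# --- Heidelberger & Welch ---------------------------------------------------

_CVM_CRIT_5PCT = 0.46136  # 5% critical value of the Cramer–von Mises statistic


def _spectral0(x: np.ndarray) -> float:
    """Spectral density of the chain at frequency zero, by batch means."""
    n = x.size
    nb = max(int(np.sqrt(n)), 2)
    bs = n // nb
    if bs < 1:
        return float(np.var(x, ddof=1))
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    return float(bs * np.var(means, ddof=1))


@dataclass
class HeidelbergerWelchResult:
    stationary: bool
    start_iteration: int
    cvm_statistic: float
    halfwidth_passed: bool
    mean: float
    halfwidth: float
    degenerate: bool = False


def heidelberger_welch(x: np.ndarray, eps: float = 0.1, pvalue: float = 0.05) -> HeidelbergerWelchResult:
    """Heidelberger–Welch stationarity + half-width test for one chain.

    The stationarity test applies a Cramér–von Mises test to the Brownian
    bridge of cumulative sums, discarding initial 10% chunks (up to 50%)
    until it passes.  The half-width test requires the 95% CI half-width of
    the mean (from the spectral density at zero) to be below ``eps`` times
    the absolute mean.
    """
    x = np.asarray(x, dtype=float)
    n0 = x.size
    if n0 < 10 or np.allclose(x, x[0]):
        return HeidelbergerWelchResult(False, 0, np.nan, False, float(np.mean(x)), 0.0, degenerate=True)

    stationary, start = False, 0
    stat = np.nan
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        start = int(frac * n0)
        y = x[start:]
        n = y.size
        s0 = _spectral0(y)
        if s0 <= 0:
            return HeidelbergerWelchResult(False, start, np.nan, False, float(np.mean(y)), 0.0, degenerate=True)
        csum = np.cumsum(y)
        t = np.arange(1, n + 1)
        bridge = (csum - t * y.mean()) / np.sqrt(n * s0)
        stat = float(np.sum(bridge**2) / n)
        if stat < _CVM_CRIT_5PCT:
            stationary = True
            break
    y = x[start:]
    s0 = _spectral0(y)
    hw = 1.96 * np.sqrt(s0 / y.size)
    mean = float(y.mean())
    hw_ok = bool(stationary and abs(mean) > 0 and hw / abs(mean) < eps)
    return HeidelbergerWelchResult(stationary, start, stat, hw_ok, mean, float(hw))


def heidelberger_welch_table(draws: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in draws.columns:
        r = heidelberger_welch(draws[col].to_numpy())
        rows.append(
            {
                "parameter": col,
                "stationary": r.stationary,
                "cvm_statistic": r.cvm_statistic,
                "halfwidth_passed": r.halfwidth_passed,
                "ess": effective_sample_size(draws[col].to_numpy()),
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


# --- posterior summaries ----------------------------------------------------

def kde_mode(draws: np.ndarray, bw_method: str | float = "silverman", gridsize: int = 4096) -> float:
    """Posterior mode as the argmax of a Gaussian kernel density estimate.

    The density is evaluated on a fine binned grid (numerically equivalent
    to a direct KDE at grid precision, but O(n + grid) rather than
    O(n * grid)) and the peak is refined by quadratic interpolation.
    ``bw_method`` is 'silverman' or a float multiplier of the robust spread
    (mode estimates depend on the bandwidth, so it is configurable).
    """
    from scipy.ndimage import gaussian_filter1d

    d = np.asarray(draws, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return np.nan
    if np.ptp(d) == 0:
        return float(d[0])
    sd = np.std(d, ddof=1)
    iqr = np.subtract(*np.percentile(d, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if bw_method == "silverman":
        bw = 0.9 * spread * d.size ** (-1 / 5)
    elif isinstance(bw_method, (int, float)):
        bw = float(bw_method) * spread
    else:
        raise ValueError("bw_method must be 'silverman' or a float")
    lo, hi = d.min(), d.max()
    pad = max(0.05 * (hi - lo), 3 * bw)
    grid = np.linspace(lo - pad, hi + pad, gridsize)
    step = grid[1] - grid[0]
    hist, _ = np.histogram(d, bins=gridsize, range=(grid[0] - step / 2, grid[-1] + step / 2))
    dens = gaussian_filter1d(hist.astype(float), sigma=max(bw / step, 1e-9), mode="constant")
    i = int(np.argmax(dens))
    if 0 < i < gridsize - 1:  # quadratic refinement of the peak
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return float(grid[i] + 0.5 * step * (y0 - y2) / denom)
    return float(grid[i])


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval (shortest interval of given mass)."""
    d = np.sort(np.asarray(draws, dtype=float))
    n = d.size
    k = max(int(np.floor(prob * n)), 1)
    if k >= n:
        return float(d[0]), float(d[-1])
    widths = d[k:] - d[: n - k]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + k])


def equal_tail_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    a = (1 - prob) / 2
    lo, hi = np.quantile(np.asarray(draws, dtype=float), [a, 1 - a])
    return float(lo), float(hi)


def posterior_point_and_interval(
    draws: np.ndarray,
    prob: float = 0.95,
    interval: str = "hpd",
    bw_method: str | float = "silverman",
) -> dict:
    """Posterior (mode, median, 95% interval) in the reporting convention
    posterior mode (posterior median) [credible interval]."""
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("no draws")
    if np.ptp(d) == 0:
        c = float(d[0])
        return {"mode": c, "median": c, "lower": c, "upper": c}
    lo, hi = hpd_interval(d, prob) if interval == "hpd" else equal_tail_interval(d, prob)
    return {"mode": kde_mode(d, bw_method=bw_method), "median": float(np.median(d)), "lower": lo, "upper": hi}


def pmcmc(draws: np.ndarray) -> float:
    """Bayesian two-sided sign test: twice the fraction of draws whose sign
    differs from the sign of the posterior median (capped at 1)."""
    d = np.asarray(draws, dtype=float)
    med = np.median(d)
    if med == 0:
        return 1.0
    frac = np.mean(np.sign(d) != np.sign(med))
    return float(min(1.0, 2.0 * frac))


def truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size=None):
    """Draw from a truncated normal via the scipy parametrization."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
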
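"""Superpopulation models for visibilities.

The finite population's visibilities u_1..u_N are treated as i.i.d. draws
from an infinite superpopulation distribution on {1, 2, ...} (zero-truncated
support — a member of the population is visible to at least one other).
Two families are supported, both parameterized by their zero-truncated mean
``mu`` and standard deviation ``sigma``:

* ``cmp`` (default): zero-truncated Conway-Maxwell-Poisson, flexible over-
  and underdispersion;
* ``negbinom``: zero-truncated negative binomial (overdispersed only).

Internally a family works on a finite support grid 1..umax with raw
parameters on an unconstrained scale, which is what the MCMC samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import nbinom


@dataclass(frozen=True)
class SuperpopParams:
    """Moment parameterization of the visibility distribution.

    ``mu``/``sigma`` are the mean and SD of the zero-truncated distribution,
    so ``mu`` must exceed 1.
    """

    mu: float = 10.0
    sigma: float = 5.0
    family: str = "cmp"

    def __post_init__(self) -> None:
        if self.mu < 1.0:
            raise ValueError(
                f"superpopulation mean mu={self.mu} infeasible: the zero-"
                "truncated support {1,2,...} forces a mean above 1"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative (0 = point mass)")
        if self.family not in ("cmp", "negbinom"):
            raise ValueError(f"unknown superpopulation family {self.family!r}")


def _grid_stats(logw: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Normalize log weights over support 1..umax; return (logpmf, mean, sd).

    ``logw`` indexed 0..umax with index 0 ignored (set to -inf).
    """
    logw = np.asarray(logw, dtype=np.float64).copy()
    logw[0] = -np.inf
    m = np.max(logw[1:])
    if not np.isfinite(m):
        raise ValueError("degenerate superpopulation weights (all zero)")
    p = np.exp(logw - m)
    p[0] = 0.0
    tot = p.sum()
    p /= tot
    x = np.arange(logw.size, dtype=np.float64)
    mean = float(p @ x)
    var = float(p @ (x * x) - mean * mean)
    logpmf = logw - (m + np.log(tot))
    return logpmf, mean, float(np.sqrt(max(var, 0.0)))


def _cmp_logw(raw: np.ndarray, umax: int) -> np.ndarray:
    loglam, lognu = raw
    nu = np.exp(lognu)
    x = np.arange(umax + 1, dtype=np.float64)
    return loglam * x - nu * gammaln(x + 1.0)


def _nb_logw(raw: np.ndarray, umax: int) -> np.ndarray:
    logm, logr = raw
    m, r = np.exp(logm), np.exp(logr)
    x = np.arange(umax + 1)
    return nbinom.logpmf(x, r, r / (r + m))


_FAMILY_LOGW = {"cmp": _cmp_logw, "negbinom": _nb_logw}


def family_logpmf(family: str, raw: np.ndarray, umax: int):
    """Zero-truncated log pmf over 0..umax (index 0 = -inf) plus (mean, sd)."""
    return _grid_stats(_FAMILY_LOGW[family](np.asarray(raw, float), umax))


def raw_init(family: str, mu: float, sigma: float) -> np.ndarray:
    """Cheap moment-based starting point for the raw parameters."""
    mu = max(mu, 1.2)
    var = max(sigma, 0.3) ** 2
    if family == "cmp":
        nu0 = float(np.clip(mu / var, 0.02, 30.0))
        return np.array([nu0 * np.log(mu), np.log(nu0)])
    r0 = mu * mu / max(var - mu, mu / 10.0)
    return np.array([np.log(mu), np.log(r0)])


def solve_raw_from_moments(params: SuperpopParams, umax: int | None = None) -> np.ndarray:
    """Solve raw family parameters so the zero-truncated (mean, sd) match.

    Raises ValueError when the target moments are unattainable for the
    family (e.g. an underdispersed negative binomial).
    """
    if umax is None:
        umax = int(params.mu + 14 * params.sigma + 40)

    def resid(raw):
        _, m, s = family_logpmf(params.family, raw, umax)
        return [m - params.mu, s - params.sigma]

    sol = optimize.root(resid, raw_init(params.family, params.mu, params.sigma),
                        method="hybr")
    _, m, s = family_logpmf(params.family, sol.x, umax)
    if abs(m - params.mu) > 1e-6 * params.mu or abs(s - params.sigma) > 1e-4 * params.sigma:
        raise ValueError(
            f"cannot match mean={params.mu}, sd={params.sigma} with the "
            f"{params.family!r} family (reached mean={m:.4f}, sd={s:.4f})"
        )
    return sol.x


def superpop_pmf(params: SuperpopParams, umax: int | None = None) -> np.ndarray:
    """Probability mass over 1..umax (index = visibility; entry 0 is zero)."""
    if umax is None:
        umax = int(params.mu + 14 * params.sigma + 40)
    if params.sigma == 0.0:  # point mass at round(mu)
        p = np.zeros(umax + 1)
        p[int(round(params.mu))] = 1.0
        return p
    raw = solve_raw_from_moments(params, umax)
    logpmf, _, _ = family_logpmf(params.family, raw, umax)
    return np.exp(logpmf)


def draw_visibilities(rng: np.random.Generator, pmf: np.ndarray, size: int) -> np.ndarray:
    """i.i.d. draws from a support-grid pmf (index = value)."""
    cdf = np.cumsum(pmf)
    return np.searchsorted(cdf, rng.random(size) * cdf[-1], side="right").astype(np.int64)
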
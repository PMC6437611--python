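"""Conway-Maxwell-Poisson (CMP) distribution utilities.

The CMP pmf is ``P(x) = lambda^x / (x!)^nu / Z(lambda, nu)`` with the
normalizer ``Z`` an infinite series, truncated here when the relative term
falls below 1e-12.  ``nu = 1`` recovers the Poisson distribution; ``nu > 1``
is underdispersed, ``nu < 1`` overdispersed.  A zero-truncated variant
(support starting at 1) models visibilities; the untruncated variant models
reported degrees around an inflated visibility.

All internal computations are in log space (``log_lambda``) so that the
near-deterministic regime (large ``nu``, ``lambda = m^nu`` astronomically
large) stays finite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

_LOG_EPS = np.log(1e-12)


def _check_nu(nu: float) -> None:
    if not np.isfinite(nu) or nu <= 0:
        raise ValueError(f"CMP dispersion nu must be positive (got {nu!r}); "
                         "the normalizing series does not converge otherwise")


def _grid_size(log_lambda, nu: float) -> int:
    """Support length guaranteeing the dropped tail term is < 1e-12 relative."""
    mode = np.exp(np.max(np.atleast_1d(log_lambda)) / nu)
    if not np.isfinite(mode):
        raise ValueError("lambda too large for CMP series")
    width = 12.0 * np.sqrt(mode / nu + 1.0) + 30.0
    return int(min(mode + width, 100_000)) + 1


def cmp_log_terms(log_lambda, nu: float, xmax: int) -> np.ndarray:
    """Unnormalized log terms x*log(lambda) - nu*lgamma(x+1) for x = 0..xmax.

    ``log_lambda`` may be a scalar or a 1-d array; the result has shape
    ``(len(log_lambda), xmax + 1)`` in the array case.
    """
    x = np.arange(xmax + 1, dtype=np.float64)
    ll = np.atleast_1d(np.asarray(log_lambda, dtype=np.float64))
    t = ll[:, None] * x[None, :] - nu * gammaln(x + 1.0)[None, :]
    return t if np.ndim(log_lambda) else t[0]


def cmp_logZ(log_lambda, nu: float) -> np.ndarray | float:
    """log of the CMP normalizer Z(lambda, nu), series truncated at 1e-12."""
    _check_nu(nu)
    t = cmp_log_terms(log_lambda, nu, _grid_size(log_lambda, nu))
    return logsumexp(t, axis=-1)


def cmp_logpmf(x, lam, nu: float, truncated: bool = False):
    """Log pmf at ``x`` for CMP(lambda, nu); zero-truncated variant if asked."""
    _check_nu(nu)
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("lambda must be positive")
    log_lambda = np.log(lam)
    x = np.asarray(x, dtype=np.float64)
    logZ = cmp_logZ(log_lambda, nu)
    lp = x * log_lambda - nu * gammaln(x + 1.0) - logZ
    if truncated:
        log_p0 = -np.asarray(logZ)  # term at x=0 is 1
        lp = lp - np.log1p(-np.exp(log_p0))
        lp = np.where(x < 1, -np.inf, lp)
    return lp


def cmp_pmf(x, lam, nu: float, truncated: bool = False):
    """CMP probability mass at ``x`` (vectorized)."""
    return np.exp(cmp_logpmf(x, lam, nu, truncated=truncated))


def cmp_pmf_grid(log_lambda: float, nu: float, xmax: int | None = None,
                 truncated: bool = False) -> np.ndarray:
    """Normalized pmf over x = 0..xmax (index = x).  Entry 0 is zero when
    truncated.  ``xmax`` defaults to the 1e-12 series cutoff."""
    _check_nu(nu)
    full = _grid_size(log_lambda, nu)
    t = cmp_log_terms(log_lambda, nu, max(full, xmax or 0))
    p = np.exp(t - logsumexp(t))
    if truncated:
        p0 = p[0]
        p = p / (1.0 - p0)
        p[0] = 0.0
    if xmax is not None:
        if xmax + 1 < p.size:
            p = p[: xmax + 1]
        elif xmax + 1 > p.size:
            p = np.pad(p, (0, xmax + 1 - p.size))
    return p


def cmp_mean_var(log_lambda, nu: float, truncated: bool = False):
    """Mean and variance of CMP (scalar or vectorized over log_lambda)."""
    _check_nu(nu)
    xmax = _grid_size(log_lambda, nu)
    t = cmp_log_terms(log_lambda, nu, xmax)
    t = np.atleast_2d(t)
    p = np.exp(t - logsumexp(t, axis=1, keepdims=True))
    if truncated:
        p[:, 0] = 0.0
        p = p / p.sum(axis=1, keepdims=True)
    x = np.arange(xmax + 1, dtype=np.float64)
    m = p @ x
    v = p @ (x * x) - m * m
    if np.ndim(log_lambda) == 0:
        return float(m[0]), float(v[0])
    return m, v


def cmp_mean(log_lambda, nu: float, truncated: bool = False):
    return cmp_mean_var(log_lambda, nu, truncated=truncated)[0]


def mean_to_lambda(mu: float, nu: float, truncated: bool = False) -> float:
    """Solve for lambda such that the CMP(lambda, nu) mean equals ``mu``.

    Monotone bisection on log(lambda) to tolerance 1e-8.  Raises on
    unattainable means (mu <= 0, or mu <= 1 for the zero-truncated variant
    whose mean approaches 1 from above as lambda -> 0).
    """
    _check_nu(nu)
    lo_limit = 1.0 if truncated else 0.0
    if not np.isfinite(mu) or mu <= lo_limit:
        raise ValueError(
            f"target mean {mu} is unattainable for "
            f"{'zero-truncated ' if truncated else ''}CMP (must exceed {lo_limit})"
        )
    # bracket in log-lambda; Poisson-ish initial guess lambda ~ mu^nu
    center = nu * np.log(max(mu, 1e-6))
    lo, hi = center - 5.0, center + 5.0
    while cmp_mean(lo, nu, truncated) > mu:
        lo -= 10.0
        if lo < -400:
            raise ValueError(f"target mean {mu} unattainable (lambda underflow)")
    while cmp_mean(hi, nu, truncated) < mu:
        hi += 10.0
        if hi > 5000:
            raise ValueError(f"target mean {mu} unattainable (lambda overflow)")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if cmp_mean(mid, nu, truncated) < mu:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8:
            break
    return float(np.exp(0.5 * (lo + hi)))


def mean_to_loglam_vec(means: np.ndarray, nu: float, xmax: int,
                       return_logZ: bool = False):
    """Vectorized damped-Newton solve of log(lambda) for an array of target means.

    Untruncated CMP.  Uses d(mean)/d(log lambda) = variance; the common
    support grid 0..xmax must cover all targets.  Intended for the MCMC inner
    loop (nu bounded away from the deterministic limit).  With
    ``return_logZ`` also returns the log normalizer at the solution.
    """
    _check_nu(nu)
    means = np.asarray(means, dtype=np.float64)
    x = np.arange(xmax + 1, dtype=np.float64)
    lgam = nu * gammaln(x + 1.0)
    # asymptotic mean-matching start: mean ~ lambda^(1/nu) - (nu-1)/(2 nu)
    ll = nu * np.log(np.maximum(means + (nu - 1.0) / (2.0 * nu), 1e-3))
    tol = 1e-8 * max(1.0, float(means.max()))
    tmax = logs = m = None
    for _ in range(60):
        t = ll[:, None] * x[None, :] - lgam[None, :]
        tmax = t.max(axis=1)
        np.subtract(t, tmax[:, None], out=t)
        np.exp(t, out=t)
        logs = np.log(t.sum(axis=1))
        w = t / np.exp(logs)[:, None]
        m = w @ x
        if np.max(np.abs(means - m)) < tol:
            break
        v = np.maximum(w @ (x * x) - m * m, 1e-12)
        ll += np.clip((means - m) / v, -2.0, 2.0)
    if return_logZ:
        return ll, tmax + logs
    return ll


def cmp_rvs(rng: np.random.Generator, lam: float, nu: float, size: int,
            truncated: bool = False) -> np.ndarray:
    """Draw CMP variates by inverse-cdf lookup on the truncated-series grid."""
    p = cmp_pmf_grid(np.log(lam), nu, truncated=truncated)
    cdf = np.cumsum(p)
    u = rng.random(size)
    return np.searchsorted(cdf, u * cdf[-1], side="right").astype(np.int64)
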
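"""Successive-sampling (PPS without replacement) order likelihood.

The probability of observing units with visibilities u_(1)..u_(n) in that
order, from a population whose unsampled units have total visibility W, is

    prod_k  u_(k) / (W + sum_{j>=k} u_(j))

— at step k every not-yet-sampled unit competes with weight proportional to
its visibility, and the unsampled units enter only through their total W.
The log of this product is the core likelihood of SS-PSE.

When the n sampled units are an anonymous subset of N exchangeable
population units, the marginal likelihood for N additionally carries the
exchangeability factor N!/(N-n)! (``log_falling_factorial``): any of the
(N)_n ordered assignments of population units to sample positions yields the
same observation.  Without it the order probability alone would always favor
the smallest N.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln


def ss_log_likelihood(ordered_visibilities, W: float) -> float:
    """Log probability of the observed selection order given unsampled total W.

    ``ordered_visibilities`` are the (true or imputed) visibilities in
    enrollment order, each >= 1; ``W >= 0`` is the summed visibility of the
    N - n unsampled units.
    """
    u = np.asarray(ordered_visibilities, dtype=np.float64)
    if u.size == 0:
        raise ValueError("need at least one sampled unit")
    if np.any(u < 1):
        raise ValueError("visibilities must be >= 1")
    if W < 0:
        raise ValueError("unsampled total W must be >= 0")
    denom = W + np.cumsum(u[::-1])[::-1]
    if np.any(denom <= 0):
        raise ZeroDivisionError("zero denominator in successive-sampling product")
    return float(np.sum(np.log(u)) - np.sum(np.log(denom)))


def log_falling_factorial(N, n: int):
    """log N!/(N-n)! — the exchangeability factor of the SS-PSE likelihood."""
    N = np.asarray(N, dtype=np.float64)
    return gammaln(N + 1.0) - gammaln(N - n + 1.0)


@njit(cache=True)
def visibility_sweep(u, D, d, logf_sup, loglam, logZ, deltas, log_accept_u):
    """One Metropolis sweep over the imputed visibilities.

    In-place update of ``u`` (visibilities in enrollment order, int64) and
    ``D`` (denominators D_k = W + sum_{j>=k} u_j, float64).  ``d`` holds the
    reported degrees (-1.0 = missing, measurement term skipped).
    ``logf_sup[v]`` is the superpopulation log pmf at v; ``loglam[v]`` /
    ``logZ[v]`` parameterize the reporting CMP for a candidate visibility v
    (measurement log pmf at d is d*loglam[v] - logZ[v] up to a term constant
    in v).  ``deltas`` are the proposed integer steps, ``log_accept_u`` the
    log acceptance uniforms; both length n.  Proposals outside [1, umax] are
    rejected (symmetric step kernel).  Returns the number of acceptances.
    """
    n = u.shape[0]
    umax = logf_sup.shape[0] - 1
    accepted = 0
    for p in range(n):
        delta = deltas[p]
        if delta == 0:
            continue
        v_old = u[p]
        v_new = v_old + delta
        if v_new < 1 or v_new > umax:
            continue
        dlp = np.log(v_new / float(v_old))  # SS numerator at own position
        dlp += logf_sup[v_new] - logf_sup[v_old]
        if d[p] >= 0.0:
            dlp += d[p] * (loglam[v_new] - loglam[v_old]) - (logZ[v_new] - logZ[v_old])
        fd = float(delta)
        for k in range(p + 1):  # denominators for steps 1..p contain u_p
            dlp += np.log(D[k]) - np.log(D[k] + fd)
        if dlp >= 0.0 or log_accept_u[p] < dlp:
            u[p] = v_new
            for k in range(p + 1):
                D[k] += fd
            accepted += 1
    return accepted

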
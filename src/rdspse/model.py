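"""Imputed-visibility SS-PSE: priors, MCMC, and posterior summaries.

The model treats the hidden population size N as unknown with an expert-
informed prior, the N visibilities as i.i.d. draws from a superpopulation
distribution (unknown mean ``mu`` and SD ``sigma``), and each self-reported
degree d_i as a Conway-Maxwell-Poisson perturbation of the true visibility
u_i with mean ``tau * u_i`` (proportional misreporting) and relative
dispersion ``rho`` (CMP dispersion ``nu = 1/rho``; ``rho -> 0`` is the
deterministic limit).  The enrollment order enters through the successive-
sampling likelihood of :mod:`rdspse.likelihood`; the unsampled units enter
only through their total visibility W, carried as a single latent scalar.

Sampling is Metropolis-within-Gibbs over five blocks: (1) per-participant
imputed visibilities; (2) superpopulation parameters; (3) measurement
parameters (tau, rho); (4) the latent unsampled total W, re-proposed from
its conditional distribution given (N, theta) — a sum of N - n
superpopulation draws, or a normal approximation when N - n > 1000; and
(5) N itself, a random walk on the discrete prior grid with W refreshed
jointly so the W-proposal density cancels from the acceptance ratio.
Setting ``impute_visibility=False`` pins u_i = d_i and skips blocks (1) and
(3), recovering SS-PSE without visibility imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cmp import mean_to_loglam_vec
from .data import MISSING_DEGREE, RDSSample
from .errors import ModelError, PriorInfeasibleError
from .likelihood import log_falling_factorial, visibility_sweep
from .superpop import SuperpopParams, family_logpmf, raw_init

logger = logging.getLogger(__name__)

#: Lower support bound for the reporting dispersion rho during MCMC; keeps
#: the CMP mean->lambda solve on the smooth part of the mean function
#: (nu = 1/rho <= 50).
RHO_MIN = 0.02

_QUANTILE_LEVELS = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class MeasErrParams:
    """Degree-misreporting model: reported d ~ CMP with mean tau*u, dispersion rho.

    ``tau`` is the proportional inflation of reports relative to visibility;
    ``rho`` scales the relative error around the inflated value
    (Var(d|u) ~ rho * tau * u; rho = 1 is Poisson-level noise, rho = 0 the
    deterministic limit d = round(tau*u)).
    """

    tau: float = 1.0
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"inflation factor tau must be positive, got {self.tau}")
        if self.rho < 0:
            raise ValueError(f"dispersion rho must be >= 0, got {self.rho}")


@dataclass(frozen=True)
class PriorSpec:
    """Prior on the population size N plus hyperpriors for the other unknowns.

    ``median_N`` is the expert prior median (in practice the average of two
    expert medians).  ``family_N`` chooses how the prior spreads around it:

    * ``beta_sample_fraction`` (default): a Beta(1, beta) law on the sample
      fraction n/N, with beta solved so the induced prior median over
      {n..max_N} equals ``median_N``; heavy right tail, matching how expert
      priors for hidden populations are usually elicited;
    * ``flat``: uniform on {n..max_N};
    * ``lognormal``: discretized log-normal with median ``median_N`` and
      log-scale ``lognormal_sdlog``.

    Hyperpriors (all weakly informative): ``hyper_mu`` is (location, scale)
    of a log-normal on the superpopulation mean — default centered at the
    sample mean reported degree; ``hyper_sigma`` the scale of a half-normal
    on the superpopulation SD — default 2x the sample SD; ``hyper_tau``
    (location, scale) of a log-normal on tau — centered at 1 (no
    misreporting); ``hyper_rho`` the scale of a half-normal on rho.
    """

    median_N: int
    family_N: str = "beta_sample_fraction"
    max_N: Optional[int] = None
    lognormal_sdlog: float = 1.0
    hyper_mu: Optional[tuple[float, float]] = None
    hyper_sigma: Optional[float] = None
    hyper_tau: tuple[float, float] = (0.0, 0.5)
    hyper_rho: float = 1.0

    def __post_init__(self) -> None:
        if self.median_N < 1:
            raise PriorInfeasibleError("prior median_N must be >= 1")
        if self.max_N is not None and self.max_N <= self.median_N:
            raise PriorInfeasibleError("max_N must exceed median_N")
        if self.family_N not in ("beta_sample_fraction", "flat", "lognormal"):
            raise ValueError(f"unknown prior family {self.family_N!r}")

    def resolved_max_N(self, n: int) -> int:
        if self.max_N is not None:
            return self.max_N
        return max(20 * self.median_N, 10 * n)


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings.  ``samples`` draws are retained after ``burnin``
    sweeps, keeping every ``thin``-th.  Proposal scales adapt toward a 30%
    acceptance rate during burn-in only."""

    burnin: int = 2000
    samples: int = 5000
    thin: int = 2
    rng_seed: int = 0
    scale_theta: float = 0.08
    scale_meas: float = 0.08
    scale_N: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.burnin, self.samples, self.thin) < 1:
            raise ValueError("burnin, samples and thin must all be positive")


@dataclass
class PosteriorResult:
    """MCMC output: draws of N and parameters, imputed-visibility summaries,
    the evaluated prior over the N grid, and the five posterior quantiles
    (type-7 linear interpolation) used for reporting."""

    N_draws: np.ndarray
    param_draws: pd.DataFrame
    visibility_mean: np.ndarray
    visibility_sd: np.ndarray
    quantiles: dict[int, float]
    N_grid: np.ndarray
    prior_pmf: np.ndarray
    n: int
    label: str = ""
    rng_seed: int = 0
    impute_visibility: bool = True
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def median(self) -> float:
        return self.quantiles[50]

    def credible_interval(self, level: float = 0.90) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.N_draws, [a, 1.0 - a])
        return float(lo), float(hi)


def prior_pmf_N(spec: PriorSpec, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized prior pmf for N over the grid {n..max_N}.

    Raises :class:`PriorInfeasibleError` when the prior median is not above
    the sample size (revise median_N or max_N).
    """
    if spec.median_N < n or (spec.family_N == "beta_sample_fraction" and spec.median_N <= n):
        raise PriorInfeasibleError(
            f"prior median_N={spec.median_N} is not above the sample size n={n}; "
            "revise median_N (and max_N) so the prior places its median beyond "
            "the observed sample"
        )
    max_N = spec.resolved_max_N(n)
    if max_N <= spec.median_N:
        raise PriorInfeasibleError("max_N must exceed median_N")
    grid = np.arange(n, max_N + 1, dtype=np.int64)
    if spec.family_N == "flat":
        pmf = np.full(grid.size, 1.0 / grid.size)
    elif spec.family_N == "lognormal":
        z = (np.log(grid) - np.log(spec.median_N)) / spec.lognormal_sdlog
        w = np.exp(-0.5 * z * z) / grid
        pmf = w / w.sum()
    else:
        pmf = _beta_fraction_pmf(grid, n, spec.median_N)
    return grid, pmf


def _beta_fraction_pmf(grid: np.ndarray, n: int, median_N: int) -> np.ndarray:
    """Prior on N induced by n/N ~ Beta(1, beta), exactly discretized:
    P(N) proportional to P(n/x in (n/(N+1), n/N]) = (1-n/(N+1))^beta - (1-n/N)^beta,
    with beta bisected so the truncated grid median equals median_N."""
    gN = grid.astype(np.float64)
    med_idx = int(median_N - n)

    def cdf_at_median(log_beta: float) -> float:
        b = np.exp(log_beta)
        w = np.power(1.0 - n / (gN + 1.0), b) - np.power(np.maximum(1.0 - n / gN, 0.0), b)
        c = np.cumsum(w)
        return c[med_idx] / c[-1]

    lo, hi = -12.0, 12.0  # cdf_at_median is decreasing in beta
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if cdf_at_median(mid) > 0.5:
            lo = mid
        else:
            hi = mid
    b = np.exp(0.5 * (lo + hi))
    w = np.power(1.0 - n / (gN + 1.0), b) - np.power(np.maximum(1.0 - n / gN, 0.0), b)
    return w / w.sum()


def prior_quantile(grid: np.ndarray, pmf: np.ndarray, q: float) -> int:
    """Smallest grid value whose cumulative prior mass reaches q."""
    c = np.cumsum(pmf)
    return int(grid[np.searchsorted(c, q * c[-1])])


def _meas_tables(tau: float, rho: float, umax: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Reporting-CMP tables for candidate visibilities 1..umax.

    Returns (loglam, logZ) indexed by visibility (index 0 unused) and nu.
    loglam[v] solves CMP mean = tau * v at dispersion nu = 1/rho.
    """
    nu = 1.0 / max(rho, RHO_MIN)
    top = tau * umax
    xmax = int(top + 12.0 * np.sqrt(top / nu + 1.0) + 30)
    ll, logZ = mean_to_loglam_vec(tau * np.arange(1, umax + 1, dtype=np.float64),
                                  nu, xmax, return_logZ=True)
    return (
        np.concatenate(([0.0], ll)),
        np.concatenate(([np.inf], logZ)),
        nu,
    )


def _meas_loglik(d: np.ndarray, obs: np.ndarray, u: np.ndarray,
                 loglam: np.ndarray, logZ: np.ndarray, nu: float) -> float:
    dd = d[obs].astype(np.float64)
    uu = u[obs]
    return float(np.sum(dd * loglam[uu] - nu * gammaln(dd + 1.0) - logZ[uu]))


def _lognormal_lp(x: float, loc: float, scale: float) -> float:
    z = (np.log(x) - loc) / scale
    return -0.5 * z * z - np.log(x)


def _halfnormal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


#: Number of candidate draws of the latent unsampled total W per
#: multiple-try update in the exact (small-grid) regime.  The W-proposal is
#: its conditional distribution given (N, theta), whose density need never
#: be evaluated; averaging the successive-sampling likelihood over K
#: candidates Rao-Blackwellizes the W noise out of the N acceptance ratio.
K_MTM = 25

#: Grid width (max_N - n) above which the latent unsampled total W is
#: handled through its CLT normal approximation in a non-centered
#: parameterization: the chain carries Z = (W - (N-n)*mu) / (sqrt(N-n)*sigma)
#: ~ N(0,1) independent of (N, theta), so moves in N or theta slide W along
#: the (N, W) ridge automatically.  Below this width the exact discrete sum
#: distribution is used (the regime of the exact-enumeration checks, where
#: independence proposals mix well).
DISCRETE_W_LIMIT = 60

#: Support bound for the standardized residual Z in the normal regime: W is
#: modeled as a normal truncated to +/- Z_CAP conditional SDs of its mean.
#: The exact sum of m >= 1 visibilities keeps |Z| below 6 with probability
#: ~1 - 1e-9 but has far lighter tails than the Gaussian; without the
#: truncation the Gaussian left tail lets W drift to values impossible for
#: a sum of m visibilities that are each >= 1.
Z_CAP = 6.0


class _WSampler:
    """Draws of the unsampled visibility total W ~ sum of (N - n) i.i.d.
    superpopulation variates; exact inverse-cdf sums up to 1000 units, a
    moment-matched normal approximation (floored at N - n, since every
    visibility is >= 1) beyond that."""

    def __init__(self, pmf: np.ndarray):
        self.set_pmf(pmf)

    def set_pmf(self, pmf: np.ndarray) -> None:
        self.cdf = np.cumsum(pmf)
        x = np.arange(pmf.size, dtype=np.float64)
        self.mean = float(pmf @ x)
        self.var = float(pmf @ (x * x) - self.mean**2)

    def draw(self, rng: np.random.Generator, m: int) -> float:
        return float(self.draw_batch(rng, m, 1)[0])

    def draw_batch(self, rng: np.random.Generator, m: int, k: int) -> np.ndarray:
        """k independent realizations of the unsampled total for m units."""
        if m <= 0:
            return np.zeros(k)
        if m <= 1000:
            vals = np.searchsorted(self.cdf, rng.random((k, m)) * self.cdf[-1],
                                   side="right")
            return vals.sum(axis=1).astype(np.float64)
        w = rng.normal(m * self.mean, np.sqrt(m * self.var), size=k)
        return np.maximum(w, float(m))


def _ss_denom_loglik(S: np.ndarray, W: np.ndarray) -> np.ndarray:
    """-sum_k log(W + S_k) for each candidate W (the W-dependent part of the
    successive-sampling log likelihood)."""
    return -np.sum(np.log(S[None, :] + np.asarray(W)[:, None]), axis=1)


def _w_from_z(m: int, wsamp: "_WSampler", z: float) -> float:
    """Unsampled total implied by the standardized residual z under the
    normal approximation: W = m*mu + sqrt(m*var)*z."""
    return m * wsamp.mean + np.sqrt(m * wsamp.var) * z


def _mtm_select(rng: np.random.Generator, logw: np.ndarray) -> int:
    """Sample an index proportional to exp(logw) (Gumbel-max)."""
    return int(np.argmax(logw + rng.gumbel(size=logw.size)))


def fit_sspse(
    sample: RDSSample,
    prior: PriorSpec,
    mcmc: Optional[MCMCConfig] = None,
    impute_visibility: bool = True,
    *,
    superpop_family: str = "cmp",
    fixed_superpop_pmf: Optional[np.ndarray] = None,
    fixed_meas: Optional[MeasErrParams] = None,
    min_n: int = 20,
) -> PosteriorResult:
    """Fit imputed-visibility SS-PSE to an RDS sample.

    Parameters
    ----------
    sample
        The observed recruitment data (order + reported degrees).
    prior
        Prior on N and hyperpriors; see :class:`PriorSpec`.
    mcmc
        Chain settings (defaults: burnin 2000, 5000 draws, thin 2).
    impute_visibility
        If False, visibilities are pinned at the reported degrees
        (clipped to >= 1) and the measurement-error block is skipped —
        classic SS-PSE without imputation.
    superpop_family
        ``"cmp"`` or ``"negbinom"`` superpopulation for the visibilities.
    fixed_superpop_pmf
        Optional known visibility pmf (index = visibility); fixes theta and
        skips its block.  Used for oracle checks and sensitivity studies.
    fixed_meas
        Optional fixed (tau, rho); skips the measurement block.
    min_n
        Smallest sample size accepted (warning below 50).

    Returns
    -------
    PosteriorResult with draws of N, (mu, sigma, tau, rho, W), imputed
    visibility summaries, posterior quantiles and the evaluated prior.
    """
    mcmc = mcmc or MCMCConfig()
    n = sample.n
    if n < min_n:
        raise ModelError(f"sample size {n} is below the minimum {min_n}")
    if n < 50:
        logger.warning("sample size %d < 50: SS-PSE estimates will be imprecise", n)

    d = sample.effective_degrees()
    obs = d != MISSING_DEGREE
    if not obs.any():
        raise ModelError("all reported degrees are missing; nothing to fit")
    d_obs = d[obs].astype(np.float64)
    mean_d = float(max(d_obs.mean(), 1.1))
    sd_d = float(max(d_obs.std(), 0.3))

    if fixed_superpop_pmf is not None:
        umax = int(len(fixed_superpop_pmf) - 1)
    else:
        umax = int(min(max(3 * d_obs.max(), 60), 1000))

    grid_N, prior_pmf = prior_pmf_N(prior, n)
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior_pmf)
    lff = log_falling_factorial(grid_N, n)
    max_N = int(grid_N[-1])

    hyper_mu = prior.hyper_mu or (np.log(mean_d), 0.7)
    hyper_sigma = prior.hyper_sigma or (2.0 * sd_d + 1.0)

    rng = np.random.default_rng(mcmc.rng_seed)

    # --- initial state ------------------------------------------------
    u = np.where(obs, np.maximum(d, 1), int(round(mean_d))).astype(np.int64)
    u = np.minimum(u, umax)
    if impute_visibility and (~obs).any():
        logger.info("%d missing degrees will be imputed from order information",
                    int((~obs).sum()))

    theta_fixed = fixed_superpop_pmf is not None
    if theta_fixed:
        pmf_sup = np.asarray(fixed_superpop_pmf, dtype=np.float64)
        pmf_sup = pmf_sup / pmf_sup.sum()
        with np.errstate(divide="ignore"):
            logf_sup = np.log(pmf_sup)
        xg = np.arange(pmf_sup.size, dtype=np.float64)
        sup_mean = float(pmf_sup @ xg)
        sup_sd = float(np.sqrt(max(pmf_sup @ (xg * xg) - sup_mean**2, 0.0)))
        raw = None
    else:
        raw = raw_init(superpop_family, float(u.mean()), float(max(u.std(), 0.5)))
        logf_sup, sup_mean, sup_sd = family_logpmf(superpop_family, raw, umax)
        pmf_sup = np.exp(logf_sup)

    meas_fixed = (not impute_visibility) or (fixed_meas is not None)
    if impute_visibility:
        tau = fixed_meas.tau if fixed_meas else 1.0
        rho = max(fixed_meas.rho, RHO_MIN) if fixed_meas else 0.5
        loglam, logZ, nu_meas = _meas_tables(tau, rho, umax)
    else:
        tau, rho = 1.0, 0.0
        loglam = logZ = None
        nu_meas = np.inf

    continuous_W = (max_N - n) > DISCRETE_W_LIMIT
    wsamp = _WSampler(pmf_sup)
    N = prior_quantile(grid_N, prior_pmf, 0.5)
    Z = 0.0
    W = _w_from_z(N - n, wsamp, Z) if continuous_W else wsamp.draw(rng, N - n)
    D = W + np.cumsum(u[::-1].astype(np.float64))[::-1]
    d_f = np.where(obs, d, -1).astype(np.float64)

    step_u = np.maximum(1, np.round(0.6 * np.sqrt(np.maximum(d_f, 1.0))).astype(np.int64))

    s_theta = mcmc.scale_theta
    s_meas = mcmc.scale_meas
    s_N = mcmc.scale_N or max(2.0, 0.15 * prior.median_N)
    s_W = 0.5

    n_keep = mcmc.samples
    total = mcmc.burnin + n_keep * mcmc.thin
    N_draws = np.empty(n_keep, dtype=np.int64)
    pdraws = np.empty((n_keep, 5), dtype=np.float64)
    u_sum = np.zeros(n, dtype=np.float64)
    u_sq = np.zeros(n, dtype=np.float64)
    acc = {"u": 0.0, "theta": 0.0, "meas": 0.0, "W": 0.0, "N": 0.0}
    tries = {k: 0.0 for k in acc}

    if impute_visibility:
        meas_ll = _meas_loglik(d_f, obs, u, loglam, logZ, nu_meas)

    keep = 0
    for it in range(total):
        adapting = it < mcmc.burnin
        astep = min(0.25, 4.0 / np.sqrt(it + 10.0))

        # (1) imputed visibilities
        if impute_visibility:
            deltas = rng.integers(-step_u, step_u + 1)
            logau = np.log(rng.random(n))
            na = visibility_sweep(u, D, d_f, logf_sup, loglam, logZ, deltas, logau)
            acc["u"] += na
            tries["u"] += n
            meas_ll = _meas_loglik(d_f, obs, u, loglam, logZ, nu_meas)

        counts = np.bincount(u, minlength=umax + 1)

        # (2) superpopulation parameters — a joint (theta, W) multiple-try
        # move with W candidates from the conditional p(W | N, theta'), whose
        # density cancels from the weights
        if not theta_fixed:
            tries["theta"] += 1
            raw_p = raw + s_theta * rng.standard_normal(2)
            logf_p, mean_p, sd_p = family_logpmf(superpop_family, raw_p, umax)
            if sd_p > 1e-6:
                cur = counts[1:] @ logf_sup[1:] + _lognormal_lp(sup_mean, *hyper_mu) \
                    + _halfnormal_lp(sup_sd, hyper_sigma)
                prop = counts[1:] @ logf_p[1:] + _lognormal_lp(mean_p, *hyper_mu) \
                    + _halfnormal_lp(sd_p, hyper_sigma)
                if np.isfinite(prop):
                    ws_p = _WSampler(np.exp(logf_p))
                    S = D - W
                    if continuous_W:
                        # Z held fixed: W slides with the new (mu, sigma)
                        W_p = _w_from_z(N - n, ws_p, Z)
                        dlp = (prop - cur + float(_ss_denom_loglik(S, [W_p])[0])
                               - float(_ss_denom_loglik(S, [W])[0])) \
                            if W_p >= 0 else -np.inf
                        if dlp >= 0 or np.log(rng.random()) < dlp:
                            raw, logf_sup = raw_p, logf_p
                            sup_mean, sup_sd = mean_p, sd_p
                            wsamp = ws_p
                            W, D = W_p, S + W_p
                            acc["theta"] += 1
                    else:
                        W_cand = ws_p.draw_batch(rng, N - n, K_MTM)
                        logw_new = prop + _ss_denom_loglik(S, W_cand)
                        W_ref = wsamp.draw_batch(rng, N - n, K_MTM)
                        W_ref[-1] = W
                        logw_ref = cur + _ss_denom_loglik(S, W_ref)
                        dlp = logsumexp(logw_new) - logsumexp(logw_ref)
                        if dlp >= 0 or np.log(rng.random()) < dlp:
                            j = _mtm_select(rng, logw_new)
                            raw, logf_sup = raw_p, logf_p
                            sup_mean, sup_sd = mean_p, sd_p
                            wsamp = ws_p
                            W = float(W_cand[j])
                            D = S + W
                            acc["theta"] += 1
            if adapting:
                s_theta *= np.exp(astep * ((acc["theta"] / tries["theta"]) - 0.3))

        # (3) measurement parameters (tau, rho)
        if impute_visibility and not meas_fixed:
            tries["meas"] += 1
            lt, lr = np.log(tau) + s_meas * rng.standard_normal(), \
                np.log(rho) + s_meas * rng.standard_normal()
            tau_p, rho_p = float(np.exp(lt)), float(np.exp(lr))
            if rho_p >= RHO_MIN and tau_p * umax < 5000:
                loglam_p, logZ_p, nu_p = _meas_tables(tau_p, rho_p, umax)
                ll_p = _meas_loglik(d_f, obs, u, loglam_p, logZ_p, nu_p)
                dlp = (ll_p - meas_ll
                       + _lognormal_lp(tau_p, *prior.hyper_tau)
                       - _lognormal_lp(tau, *prior.hyper_tau)
                       + _halfnormal_lp(rho_p, prior.hyper_rho)
                       - _halfnormal_lp(rho, prior.hyper_rho)
                       + lt - np.log(tau) + lr - np.log(rho))  # log-scale Jacobian
                if np.isfinite(dlp) and (dlp >= 0 or np.log(rng.random()) < dlp):
                    tau, rho = tau_p, rho_p
                    loglam, logZ, nu_meas = loglam_p, logZ_p, nu_p
                    meas_ll = ll_p
                    acc["meas"] += 1
            if adapting:
                s_meas *= np.exp(astep * ((acc["meas"] / tries["meas"]) - 0.3))

        # (4) latent unsampled total W: random walk on the standardized
        # residual Z in the normal regime, multiple-try independence redraw
        # from the exact sum distribution on small grids
        tries["W"] += 1
        S = D - W
        if continuous_W:
            Z_p = Z + s_W * rng.standard_normal()
            W_p = _w_from_z(N - n, wsamp, Z_p)
            if abs(Z_p) <= Z_CAP and W_p >= 0:
                dlp = (0.5 * (Z * Z - Z_p * Z_p)
                       + float(_ss_denom_loglik(S, [W_p])[0])
                       - float(_ss_denom_loglik(S, [W])[0]))
                if dlp >= 0 or np.log(rng.random()) < dlp:
                    Z, W, D = Z_p, W_p, S + W_p
                    acc["W"] += 1
            if adapting:
                s_W *= np.exp(astep * ((acc["W"] / tries["W"]) - 0.4))
        else:
            W_cand = wsamp.draw_batch(rng, N - n, K_MTM)
            logw_new = _ss_denom_loglik(S, W_cand)
            W_ref = wsamp.draw_batch(rng, N - n, K_MTM)
            W_ref[-1] = W
            dlp = logsumexp(logw_new) - logsumexp(_ss_denom_loglik(S, W_ref))
            if dlp >= 0 or np.log(rng.random()) < dlp:
                W = float(W_cand[_mtm_select(rng, logw_new)])
                D = S + W
                acc["W"] += 1

        # (5) population size N: random walk; in the normal regime W slides
        # along the (N, W) ridge at fixed Z, on small grids W is re-proposed
        # from its conditional sum distribution (multiple-try)
        for _ in range(2):
            tries["N"] += 1
            N_p = int(round(N + s_N * rng.standard_normal()))
            n_floor = n + 1 if continuous_W else n  # W=0 only on the exact grid
            if N_p < n_floor or N_p > max_N or N_p == N:
                continue
            S = D - W
            i_new, i_old = N_p - n, N - n
            r_new = log_prior[i_new] + lff[i_new]
            r_old = log_prior[i_old] + lff[i_old]
            if not np.isfinite(r_new):
                continue
            if continuous_W:
                W_p = _w_from_z(N_p - n, wsamp, Z)
                if W_p < 0:
                    continue
                dlp = (r_new - r_old + float(_ss_denom_loglik(S, [W_p])[0])
                       - float(_ss_denom_loglik(S, [W])[0]))
                if dlp >= 0 or np.log(rng.random()) < dlp:
                    N, W, D = N_p, W_p, S + W_p
                    acc["N"] += 1
            else:
                W_cand = wsamp.draw_batch(rng, N_p - n, K_MTM)
                logw_new = r_new + _ss_denom_loglik(S, W_cand)
                W_ref = wsamp.draw_batch(rng, N - n, K_MTM)
                W_ref[-1] = W
                logw_ref = r_old + _ss_denom_loglik(S, W_ref)
                dlp = logsumexp(logw_new) - logsumexp(logw_ref)
                if dlp >= 0 or np.log(rng.random()) < dlp:
                    N = N_p
                    W = float(W_cand[_mtm_select(rng, logw_new)])
                    D = S + W
                    acc["N"] += 1
        if adapting:
            s_N *= np.exp(astep * ((acc["N"] / tries["N"]) - 0.3))
            s_N = min(max(s_N, 1.0), 0.5 * (max_N - n) + 1.0)

        if not adapting and (it - mcmc.burnin + 1) % mcmc.thin == 0 and keep < n_keep:
            N_draws[keep] = N
            pdraws[keep] = (sup_mean, sup_sd, tau, rho, W)
            u_sum += u
            u_sq += u.astype(np.float64) ** 2
            keep += 1

    if not np.all(np.isfinite(pdraws)):
        raise ModelError("non-finite parameter draws; the likelihood degenerated")

    vis_mean = u_sum / keep
    vis_sd = np.sqrt(np.maximum(u_sq / keep - vis_mean**2, 0.0))
    quant = {q: float(np.quantile(N_draws, q / 100.0)) for q in _QUANTILE_LEVELS}
    return PosteriorResult(
        N_draws=N_draws,
        param_draws=pd.DataFrame(pdraws, columns=["mu", "sigma", "tau", "rho", "W"]),
        visibility_mean=vis_mean,
        visibility_sd=vis_sd,
        quantiles=quant,
        N_grid=grid_N,
        prior_pmf=prior_pmf,
        n=n,
        label=sample.label,
        rng_seed=mcmc.rng_seed,
        impute_visibility=impute_visibility,
        acceptance={k: (acc[k] / tries[k] if tries[k] else float("nan")) for k in acc},
    )


def posterior_summary(result: PosteriorResult) -> dict[int, float]:
    """Quantile table {5, 25, 50, 75, 95}% of the N draws.

    Uses type-7 (linear interpolation) quantiles, numpy's default; the
    median (50%) is the point estimate of the population size.
    """
    if result.N_draws.size == 0:
        raise ValueError("no posterior draws to summarize")
    if result.N_draws.size < 100:
        logger.warning("only %d retained draws; quantiles will be noisy",
                       result.N_draws.size)
    return {q: float(np.quantile(result.N_draws, q / 100.0)) for q in _QUANTILE_LEVELS}


def sensitivity_fit(
    sample: RDSSample,
    expert_medians: tuple[float, float],
    prior_template: PriorSpec,
    mcmc: Optional[MCMCConfig] = None,
    **fit_kwargs,
) -> dict[str, PosteriorResult]:
    """Refit with each expert's prior median and with their average.

    Returns fits keyed ``"expert1"``, ``"expert2"``, ``"average"`` (the
    average-median fit is the headline analysis), for superimposed plotting
    of the sensitivity of the posterior to the prior median.
    """
    m1, m2 = expert_medians
    if m1 <= 0 or m2 <= 0:
        raise ValueError("expert prior medians must be positive")
    mcmc = mcmc or MCMCConfig()
    out: dict[str, PosteriorResult] = {}
    for off, (key, m) in enumerate(
        [("expert1", m1), ("expert2", m2), ("average", 0.5 * (m1 + m2))]
    ):
        prior = replace(prior_template, median_N=int(round(m)))
        cfg = replace(mcmc, rng_seed=mcmc.rng_seed + off)
        out[key] = fit_sspse(sample, prior, cfg, **fit_kwargs)
    return out
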
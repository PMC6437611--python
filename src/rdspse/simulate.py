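"""Synthetic RDS generator with known ground truth.

Recruitment is simulated at the successive-sampling approximation level:
units are drawn sequentially without replacement with probability
proportional to their latent visibility.  This is exactly the sampling model
SS-PSE assumes, making the simulator the correct null case for the
estimator; no explicit social graph is built.  Recruiter links are attached
afterwards (uniformly among earlier participants with open coupons) so that
recruitment-chain plots and wave statistics work — the SS-PSE likelihood
itself ignores who recruited whom.

Reported degrees are inflated/noisy/heaped versions of the true
visibilities via the same Conway-Maxwell-Poisson reporting model the
estimator assumes (mean tau*u, dispersion rho), optionally heaped to
multiples of 5 or 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .cmp import cmp_pmf_grid, mean_to_lambda
from .data import Participant, RDSSample
from .model import MeasErrParams
from .superpop import SuperpopParams, draw_visibilities, superpop_pmf

logger = logging.getLogger(__name__)

HEAPING_RULES = ("none", "round5", "round10")


@dataclass
class Population:
    """Ground-truth hidden population: N units with integer visibilities
    u_1..u_N >= 1 and an optional component label (for bottleneck scenarios)."""

    N: int
    visibilities: np.ndarray
    component_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.visibilities = np.asarray(self.visibilities, dtype=np.int64)
        if self.visibilities.size != self.N:
            raise ValueError("visibilities must have length N")
        if np.any(self.visibilities < 1):
            raise ValueError("all visibilities must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Study design + misreporting settings for one simulated RDS survey.

    Defaults mirror a small-city survey: target sample 100 from a few
    well-networked seeds with three coupons each; reports unbiased
    (tau = 1) with Poisson-level noise (rho = 1) and no heaping.
    """

    N: int
    target_n: int = 100
    superpop: SuperpopParams = field(default_factory=SuperpopParams)
    n_seeds: int = 4
    coupons: int = 3
    meas_err: MeasErrParams = field(default_factory=MeasErrParams)
    heaping_rule: str = "none"
    rng_seed: int = 0
    n_components: int = 1
    cross_component_rate: float = 0.0
    seed_mode: str = "pps"  # or "top_k": seeds are the k most visible units

    def __post_init__(self) -> None:
        if self.target_n > self.N:
            raise ValueError(f"target_n={self.target_n} exceeds N={self.N}")
        if not 0.0 <= self.cross_component_rate <= 1.0:
            raise ValueError("cross_component_rate must be in [0, 1]")
        if self.heaping_rule not in HEAPING_RULES:
            raise ValueError(f"heaping_rule must be one of {HEAPING_RULES}")
        if self.n_components < 1 or self.n_seeds < 1 or self.coupons < 1:
            raise ValueError("n_components, n_seeds and coupons must be >= 1")
        if self.seed_mode not in ("pps", "top_k"):
            raise ValueError("seed_mode must be 'pps' or 'top_k'")


def small_city_config(N: int, **kw) -> SimConfig:
    """Preset for a small-city survey (target n = 100)."""
    return SimConfig(N=N, target_n=100, **kw)


def capital_config(N: int, **kw) -> SimConfig:
    """Preset for a capital-city survey (target n = 300)."""
    return SimConfig(N=N, target_n=300, **kw)


def generate_population(config: SimConfig) -> Population:
    """Draw N i.i.d. visibilities from the configured zero-truncated
    superpopulation; deterministic under the config's rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    pmf = superpop_pmf(config.superpop)
    vis = draw_visibilities(rng, pmf, config.N)
    comp = None
    if config.n_components > 1:
        comp = np.sort(np.arange(config.N) % config.n_components)
    return Population(N=config.N, visibilities=vis, component_id=comp)


def simulate_rds(pop: Population, config: SimConfig) -> tuple[RDSSample, dict[int, str]]:
    """Simulate one RDS survey from a known population.

    Sequential probability-proportional-to-size draws without replacement;
    the first ``n_seeds`` draws are flagged as seeds (drawn PPS like
    everyone else by default — seeds are well networked — or as the top-k
    most visible units under ``seed_mode="top_k"``).  In multi-component
    populations, recruitment after the seeds stays within already-reached
    components except with probability ``cross_component_rate``.  Recruits
    attach to a uniformly chosen earlier participant with open coupons,
    preferring the same component.  Stops at ``target_n``, or earlier with a
    logged warning if recruitment dies out (no reachable units, or no open
    coupons) — as happens in real RDS.

    Returns the sample and the ground-truth map {population unit index ->
    participant id}.
    """
    vis = pop.visibilities.astype(np.float64)
    comp = pop.component_id if pop.component_id is not None else np.zeros(pop.N, np.int64)
    rng = np.random.default_rng(config.rng_seed + 1)

    order = _sample_order(vis, comp, config, rng)
    truth = {int(unit): f"P{k + 1:04d}" for k, unit in enumerate(order)}

    recruiters, kept = _attach_recruiters(order, comp, config, rng)
    if kept < len(order):
        logger.warning("recruitment died out at n=%d (< target %d): no open coupons",
                       kept, config.target_n)
        order = order[:kept]
        truth = {int(unit): f"P{k + 1:04d}" for k, unit in enumerate(order)}

    u_sampled = pop.visibilities[order]
    d = apply_measurement_error(u_sampled, config.meas_err, config.heaping_rule,
                                config.rng_seed + 2)
    extra = rng.poisson(0.3 * d)  # alters known but not seen in the past month

    participants = []
    for k in range(len(order)):
        rid = None if recruiters[k] < 0 else f"P{recruiters[k] + 1:04d}"
        participants.append(Participant(
            participant_id=f"P{k + 1:04d}",
            recruiter_id=rid,
            enrollment_index=k + 1,
            degree_known=int(d[k] + extra[k]),
            degree_seen=int(d[k]),
            coupons_issued=config.coupons,
        ))
    label = f"sim(N={pop.N},seed={config.rng_seed})"
    return RDSSample(participants=participants, label=label), truth


def _sample_order(vis: np.ndarray, comp: np.ndarray, config: SimConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Successive-sampling order (unit indices), respecting components."""
    N = vis.size
    n_comp = int(comp.max()) + 1
    if config.seed_mode == "top_k":
        seeds = np.argsort(-vis, kind="stable")[: config.n_seeds]
        rest = np.setdiff1d(np.arange(N), seeds)
        keys = rng.exponential(size=rest.size) / vis[rest]
        base_order = np.concatenate([seeds, rest[np.argsort(keys)]])
    else:
        keys = rng.exponential(size=N) / vis  # PPS-wor via exponential races
        base_order = np.argsort(keys)
    if n_comp == 1:
        return base_order[: config.target_n]

    # multi-component: after the seeds, draws are restricted to components
    # already reached unless a cross-component event occurs
    remaining = np.ones(N, dtype=bool)
    reached = np.zeros(n_comp, dtype=bool)
    out = []
    base_iter = list(base_order)
    for t in range(config.target_n):
        if t < config.n_seeds:
            cand = np.flatnonzero(remaining)
        else:
            cross = rng.random() < config.cross_component_rate
            mask = remaining if cross else (remaining & reached[comp])
            cand = np.flatnonzero(mask)
            if cand.size == 0 and config.cross_component_rate > 0:
                cand = np.flatnonzero(remaining)
        if cand.size == 0:
            logger.warning("recruitment died out at n=%d: no reachable units", t)
            break
        if t < config.n_seeds and config.seed_mode == "top_k":
            unit = next(i for i in base_iter if remaining[i])
        else:
            w = vis[cand]
            unit = int(rng.choice(cand, p=w / w.sum()))
        out.append(unit)
        remaining[unit] = False
        reached[comp[unit]] = True
    return np.asarray(out, dtype=np.int64)


def _attach_recruiters(order: np.ndarray, comp: np.ndarray, config: SimConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Assign each non-seed a recruiter among earlier enrollees with open
    coupons (-1 = seed).  Returns (recruiter positions, usable length)."""
    n = len(order)
    recruiters = np.full(n, -1, dtype=np.int64)
    open_coupons = np.zeros(n, dtype=np.int64)
    for k in range(n):
        open_coupons[k] = config.coupons
        if k < config.n_seeds:
            continue
        elig = np.flatnonzero(open_coupons[:k] > 0)
        if elig.size == 0:
            return recruiters, k
        same = elig[comp[order[elig]] == comp[order[k]]]
        pool = same if (same.size and rng.random() >= config.cross_component_rate) else elig
        r = int(rng.choice(pool))
        recruiters[k] = r
        open_coupons[r] -= 1
    return recruiters, n


@lru_cache(maxsize=4096)
def _reporting_cdf(mean: float, nu: float) -> np.ndarray:
    lam = mean_to_lambda(mean, nu)
    return np.cumsum(cmp_pmf_grid(np.log(lam), nu))


def apply_measurement_error(u, meas_err: MeasErrParams, heaping_rule: str = "none",
                            rng_seed: int = 0) -> np.ndarray:
    """Reported degrees for true visibilities ``u``.

    Each report is a CMP draw with mean ``tau * u_i`` and dispersion
    ``nu = 1/rho`` (``rho = 0``: deterministic ``round(tau * u_i)``), then
    heaped to the nearest multiple of 5 or 10 if requested.
    """
    u = np.asarray(u, dtype=np.int64)
    if np.any(u < 1):
        raise ValueError("true visibilities must be >= 1")
    if heaping_rule not in HEAPING_RULES:
        raise ValueError(f"heaping_rule must be one of {HEAPING_RULES}")
    tau, rho = meas_err.tau, meas_err.rho
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(rng_seed)
    if rho == 0.0:
        d = np.round(tau * u).astype(np.int64)
    else:
        nu = 1.0 / rho
        d = np.empty(u.size, dtype=np.int64)
        for val in np.unique(u):
            idx = np.flatnonzero(u == val)
            cdf = _reporting_cdf(float(tau * val), float(nu))
            d[idx] = np.searchsorted(cdf, rng.random(idx.size) * cdf[-1], side="right")
    if heaping_rule == "round5":
        d = (np.round(d / 5.0) * 5).astype(np.int64)
    elif heaping_rule == "round10":
        d = (np.round(d / 10.0) * 10).astype(np.int64)
    return d
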
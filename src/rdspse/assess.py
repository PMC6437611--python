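"""Fit classification against expert benchmarks and recruitment diagnostics.

Experts provide, per population, a lowest and highest plausible size (two
experts each).  A posterior median is *Great* if it lies between the
maximum expert low and the minimum expert high, *Good* if between the
average low and average high, *Okay* if between the minimum low and maximum
high, and *Bad* outside that widest range.  "Between" is inclusive at both
endpoints (a tie gets the better verdict).  When the maximum expert low
exceeds the minimum expert high the experts are mutually inconsistent and a
Great fit is impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import MISSING_DEGREE, RDSSample

VERDICTS = ("Great", "Good", "Okay", "Bad")


@dataclass(frozen=True)
class ExpertBounds:
    """Two experts' (low, median, high) population-size benchmarks."""

    lows: tuple[float, float]
    medians: tuple[float, float]
    highs: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, md, hi in zip(self.lows, self.medians, self.highs):
            if not (0 < lo <= md <= hi):
                raise ValueError(
                    f"each expert needs 0 < low <= median <= high, got ({lo}, {md}, {hi})"
                )

    @property
    def cutpoints(self) -> dict[str, float]:
        return {
            "min_low": min(self.lows),
            "avg_low": float(np.mean(self.lows)),
            "max_low": max(self.lows),
            "min_high": min(self.highs),
            "avg_high": float(np.mean(self.highs)),
            "max_high": max(self.highs),
        }

    @property
    def prior_median(self) -> float:
        """The average of the two expert medians — the model's prior median."""
        return float(np.mean(self.medians))


@dataclass(frozen=True)
class FitAssessment:
    verdict: str
    posterior_median: float
    bounds_used: dict[str, float]


def classify_fit(posterior_median: float, bounds: ExpertBounds) -> FitAssessment:
    """Great/Good/Okay/Bad verdict for a posterior median (first matching
    rule wins, all comparisons inclusive)."""
    c = bounds.cutpoints
    m = posterior_median
    if c["max_low"] <= m <= c["min_high"]:
        verdict = "Great"
    elif c["avg_low"] <= m <= c["avg_high"]:
        verdict = "Good"
    elif c["min_low"] <= m <= c["max_high"]:
        verdict = "Okay"
    else:
        verdict = "Bad"
    return FitAssessment(verdict=verdict, posterior_median=m, bounds_used=c)


def is_bad_from_range(posterior_median: float, min_low: float, max_high: float) -> bool:
    """True iff the posterior median falls outside the widest expert range
    [minimum expert low, maximum expert high]."""
    if min_low > max_high:
        raise ValueError("min_low must not exceed max_high")
    return posterior_median < min_low or posterior_median > max_high


def great_fit_feasible(bounds: ExpertBounds) -> bool:
    """Whether a Great verdict is attainable at all: the experts' ranges
    must overlap (max low <= min high)."""
    return max(bounds.lows) <= min(bounds.highs)


def assess_table(rows: Iterable[tuple[str, float, float, float]]) -> dict:
    """Bad / not-Bad tally for (label, posterior_median, min_low, max_high)
    rows — the only split recomputable when individual expert values are
    unpublished and only the pooled range is printed."""
    rows = list(rows)
    if not rows:
        raise ValueError("assess_table needs at least one row")
    per_row = [
        {"label": lab, "posterior_median": m, "min_low": lo, "max_high": hi,
         "bad": is_bad_from_range(m, lo, hi)}
        for lab, m, lo, hi in rows
    ]
    n_bad = sum(r["bad"] for r in per_row)
    return {
        "rows": per_row,
        "n": len(per_row),
        "n_bad": n_bad,
        "pct_bad": round(100.0 * n_bad / len(per_row)),
    }


def degree_trend(
    sample: RDSSample,
    n_permutations: int = 2000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> tuple[float, str, float]:
    """Trend of reported degree over enrollment order.

    Returns (OLS slope of effective degree on standardized enrollment
    order, label, two-sided permutation p-value).  A significant negative
    slope ("decreasing") is the depletion signature expected when the
    sample is a large fraction of the population; a significant positive
    slope ("increasing") indicates recruitment is not operating as the
    successive-sampling model expects and the size estimate merits caution.
    """
    d = sample.effective_degrees().astype(np.float64)
    keep = d != MISSING_DEGREE
    d = d[keep]
    if d.size < 10:
        raise ValueError("degree_trend needs at least 10 nonmissing degrees")
    if np.ptp(d) == 0.0:
        return 0.0, "constant", 1.0
    order = np.arange(d.size, dtype=np.float64)
    z = (order - order.mean()) / order.std()
    slope = float(z @ (d - d.mean()) / d.size)
    rng = np.random.default_rng(rng_seed)
    perm = np.tile(d, (n_permutations, 1))
    rng.permuted(perm, axis=1, out=perm)
    null = (perm - d.mean()) @ z / d.size
    p = float((1 + np.sum(np.abs(null) >= abs(slope))) / (n_permutations + 1))
    if p <= alpha:
        label = "decreasing" if slope < 0 else "increasing"
    else:
        label = "constant"
    return slope, label, p
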
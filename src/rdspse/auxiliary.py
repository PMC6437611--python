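"""Comparison population-size estimators used alongside SS-PSE.

* Service multiplier: a count of nonduplicated clients of a service (e.g.
  HIV tests in a window) divided by the survey proportion reporting use of
  that service.
* Unique-object multiplier: unique objects distributed to the population
  divided by the survey proportion reporting receipt.
* Wisdom of the crowds: the average of participants' guesses of their own
  population's size.

All are point estimators in routine practice; an optional delta-method
interval is offered for the multipliers when a standard error of the
proportion is supplied.  Survey proportions should be RDS-weighted; this
module accepts an externally computed proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .assess import ExpertBounds

logger = logging.getLogger(__name__)

METHODS = ("service_multiplier", "object_multiplier", "wisdom_of_crowds", "sspse")


@dataclass(frozen=True)
class MultiplierInput:
    """Unique count from a program source plus the survey proportion
    reporting contact with that source."""

    unique_count: int
    proportion: float
    proportion_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.unique_count < 0:
            raise ValueError("unique_count must be nonnegative")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError(
                "proportion must lie in (0, 1]; a zero proportion leaves the "
                "multiplier undefined"
            )


@dataclass(frozen=True)
class PSEEstimate:
    point: float
    method: str
    interval: Optional[tuple[float, float]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.interval is not None:
            lo, hi = self.interval
            if not lo <= self.point <= hi:
                raise ValueError("interval must bracket the point estimate")


def multiplier_estimate(inp: MultiplierInput, method: str = "service_multiplier",
                        level: float = 0.95) -> PSEEstimate:
    """Point estimate count/proportion; optional delta-method interval.

    The delta-method variance of count/p is count^2 * se^2 / p^4; the
    interval is truncated below at the unique count (the population cannot
    be smaller than the people actually counted).
    """
    point = inp.unique_count / inp.proportion
    interval = None
    if inp.proportion_se is not None:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        half = z * inp.unique_count * inp.proportion_se / inp.proportion**2
        lo = max(point - half, float(inp.unique_count))
        interval = (lo, point + half)
    return PSEEstimate(point=point, method=method, interval=interval)


def wisdom_of_crowds(guesses: Sequence[float]) -> PSEEstimate:
    """Mean of participants' size guesses; nonpositive or missing guesses
    are dropped (logged)."""
    g = np.asarray(guesses, dtype=np.float64)
    valid = g[np.isfinite(g) & (g > 0)]
    dropped = g.size - valid.size
    if dropped:
        logger.info("wisdom_of_crowds: dropped %d nonpositive/missing guesses", dropped)
    if valid.size == 0:
        raise ValueError("no valid size guesses")
    return PSEEstimate(point=float(valid.mean()), method="wisdom_of_crowds")


def compare_methods(estimates: Iterable[PSEEstimate], bounds: ExpertBounds) -> pd.DataFrame:
    """Side-by-side comparison of estimates against the widest expert range.

    Flags as implausible any estimate outside [minimum expert low, maximum
    expert high] — the same range that separates Bad from not-Bad fits.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate to compare")
    lo, hi = min(bounds.lows), max(bounds.highs)
    rows = [
        {
            "method": e.method,
            "label": e.label,
            "point": e.point,
            "expert_min_low": lo,
            "expert_max_high": hi,
            "implausible": e.point < lo or e.point > hi,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
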
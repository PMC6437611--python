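"""Diagnostic and reporting figures.

Every plotting function returns ``(figure, data)`` where ``data`` is the
DataFrame of plotted values, so tests and reports can assert on numbers
rather than pixels; :func:`rdspse.pipeline.run_pipeline` writes both the
PNG and the CSV.
"""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .assess import degree_trend
from .data import MISSING_DEGREE, RDSSample
from .model import PosteriorResult


def plot_enrollment_vs_degree(sample: RDSSample, trend_seed: int = 0):
    """Scatter of reported degree against enrollment order with a lowess
    smoother and the permutation-test trend label annotated.

    A visibly decreasing smoother is the depletion signature of a large
    sample fraction; an increasing one flags a recruitment process the
    successive-sampling model does not describe.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    d = sample.effective_degrees().astype(np.float64)
    keep = d != MISSING_DEGREE
    order = np.flatnonzero(keep) + 1.0
    d = d[keep]
    smooth = lowess(d, order, frac=0.5, return_sorted=False)
    slope, label, p = degree_trend(sample, rng_seed=trend_seed)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(order, d, s=14, alpha=0.6, color="#33618d")
    ax.plot(order, smooth, color="firebrick", lw=2)
    ax.set_xlabel("enrollment order")
    ax.set_ylabel("reported degree")
    title = sample.label or "RDS sample"
    ax.set_title(f"{title}: degree trend {label} (slope {slope:.3g}, p={p:.3g})")
    data = pd.DataFrame({"order": order, "degree": d, "smooth": smooth})
    data.attrs.update({"slope": slope, "trend": label, "p_value": p})
    return fig, data


def _posterior_density(result: PosteriorResult) -> pd.DataFrame:
    """Posterior and prior of N as per-unit densities on a common grid."""
    draws = result.N_draws
    grid = result.N_grid
    if np.ptp(draws) == 0:  # degenerate spike
        g = np.array([draws[0]])
        return pd.DataFrame({"N": g, "posterior": [1.0],
                             "prior": [float(result.prior_pmf[np.searchsorted(grid, g[0])])]})
    nbins = min(120, int(np.ptp(draws)) + 1)
    hist, edges = np.histogram(draws, bins=nbins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    prior = np.interp(centers, grid, result.prior_pmf)
    return pd.DataFrame({"N": centers, "posterior": hist, "prior": prior})


def plot_posterior(result: PosteriorResult):
    """Posterior distribution of N with the prior overlaid, the central 90%
    credible interval shaded, and a vertical line at the posterior median."""
    data = _posterior_density(result)
    lo, hi = result.credible_interval(0.90)
    med = result.quantiles[50]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(data["N"], data["posterior"], color="#2166ac", label="posterior")
    ax.plot(data["N"], data["prior"], color="gray", ls="--", label="prior")
    sel = (data["N"] >= lo) & (data["N"] <= hi)
    ax.fill_between(data["N"][sel], data["posterior"][sel], color="#92c5de",
                    alpha=0.6, label="90% credible interval")
    ax.axvline(med, color="red", lw=2, label=f"posterior median ({med:.0f})")
    ax.set_xlabel("population size N")
    ax.set_ylabel("density")
    if result.label:
        ax.set_title(result.label)
    ax.legend(frameon=False, fontsize=8)
    data.attrs.update({"median": med, "ci_low": lo, "ci_high": hi})
    return fig, data


def plot_trend(results_by_year: Mapping[int, PosteriorResult],
               prior_median: Optional[float] = None):
    """Mirrored prior/posterior shapes per survey year with the posterior
    medians connected and a dotted horizontal line at the shared prior
    median — the visual used to judge whether apparent year-to-year change
    exceeds the posteriors' own spread."""
    years = sorted(results_by_year)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    rows = []
    for x, yr in enumerate(years):
        r = results_by_year[yr]
        dens = _posterior_density(r)
        if prior_median is None:
            c = np.cumsum(r.prior_pmf)
            prior_median = float(r.N_grid[np.searchsorted(c, 0.5 * c[-1])])
        half = 0.38
        for col, side, color in (("prior", -1, "gray"), ("posterior", 1, "#2166ac")):
            v = dens[col].to_numpy()
            if v.max() > 0:
                v = v / v.max() * half
            ax.fill_betweenx(dens["N"], x + side * v, x, color=color, alpha=0.5, lw=0)
        lo, hi = r.credible_interval(0.90)
        rows.append({"year": yr, "median": r.quantiles[50], "q5": lo, "q95": hi,
                     "prior_median": prior_median})
    df = pd.DataFrame(rows)
    ax.plot(range(len(years)), df["median"], "o-", color="red", label="posterior median")
    ax.axhline(df["prior_median"].iloc[0], color="k", ls=":", label="prior median")
    ax.set_xticks(range(len(years)), [str(y) for y in years])
    ax.set_ylabel("population size N")
    ax.legend(frameon=False, fontsize=8)
    return fig, df


def plot_recruitment_chains(sample: RDSSample):
    """Recruitment forest with seeds highlighted (red squares) and waves
    laid out vertically."""
    import networkx as nx

    g = nx.DiGraph()
    for p in sample.participants:
        g.add_node(p.participant_id)
        if p.recruiter_id is not None:
            g.add_edge(p.recruiter_id, p.participant_id)
    waves = sample.waves
    # spread nodes horizontally within each wave
    by_wave: dict[int, list[str]] = {}
    for pid, w in waves.items():
        by_wave.setdefault(w, []).append(pid)
    pos = {}
    for w, pids in by_wave.items():
        for i, pid in enumerate(sorted(pids)):
            pos[pid] = (i - len(pids) / 2.0, -w)
    fig, ax = plt.subplots(figsize=(8, 5))
    seeds = {p.participant_id for p in sample.seeds}
    nx.draw_networkx_edges(g, pos, ax=ax, arrows=False, alpha=0.4)
    nx.draw_networkx_nodes(g, pos, nodelist=[p for p in g if p not in seeds],
                           node_size=25, node_color="#33618d", ax=ax)
    nx.draw_networkx_nodes(g, pos, nodelist=sorted(seeds), node_size=60,
                           node_color="red", node_shape="s", ax=ax)
    ax.set_ylabel("wave")
    ax.set_axis_off()
    data = pd.DataFrame(
        {"id": list(waves), "wave": list(waves.values())}
    )
    return fig, data
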
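"""End-to-end pipeline: read -> fit -> summarize -> assess -> plot.

Every artifact is stamped with the run seed and a hash of the
configuration; a rerun with the same configuration is numerically
identical (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .assess import ExpertBounds, classify_fit, degree_trend
from .data import RDSSample, read_rds_csv
from .errors import ModelError
from .model import MCMCConfig, PosteriorResult, PriorSpec, fit_sspse, posterior_summary
from .plots import plot_enrollment_vs_degree, plot_posterior

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: input data, prior, chain settings, benchmarks."""

    input_csv: str
    outdir: str
    prior: PriorSpec
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    expert_bounds: Optional[ExpertBounds] = None
    label: str = ""
    impute_visibility: bool = True
    verbosity: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def result_to_json(result: PosteriorResult, include_draws: bool = True) -> dict:
    out = {
        "n": result.n,
        "label": result.label,
        "rng_seed": result.rng_seed,
        "impute_visibility": result.impute_visibility,
        "quantiles": {str(k): v for k, v in result.quantiles.items()},
        "credible_interval_90": list(result.credible_interval(0.90)),
        "acceptance": result.acceptance,
        "param_posterior_medians": result.param_draws.median().to_dict(),
    }
    if include_draws:
        out["N_draws"] = result.N_draws.tolist()
        out["prior_grid_start"] = int(result.N_grid[0])
        out["prior_pmf"] = result.prior_pmf.tolist()
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a bundle of artifact paths and
    headline numbers.  Any stage failure aborts with a stage-named error."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setLevel(config.verbosity)
    root = logging.getLogger("rdspse")
    root.addHandler(handler)
    root.setLevel(config.verbosity)
    bundle: dict = {"config_hash": tag, "rng_seed": config.mcmc.rng_seed}
    try:
        try:
            sample = read_rds_csv(config.input_csv, label=config.label)
        except Exception as e:
            raise ModelError(f"[read stage] {e}") from e
        logger.info("read %d participants (%d seeds, %d waves)", sample.n,
                    len(sample.seeds), max(sample.waves.values()) + 1)

        try:
            result = fit_sspse(sample, config.prior, config.mcmc,
                               impute_visibility=config.impute_visibility)
        except Exception as e:
            raise ModelError(f"[fit stage] {e}") from e
        summary = posterior_summary(result)

        fit_json = outdir / "fit.json"
        payload = result_to_json(result)
        payload["config_hash"] = tag
        fit_json.write_text(json.dumps(payload, indent=1))
        bundle["fit_json"] = str(fit_json)
        bundle["quantiles"] = summary

        try:
            slope, trend, pval = degree_trend(sample, rng_seed=config.mcmc.rng_seed)
            bundle["degree_trend"] = {"slope": slope, "label": trend, "p_value": pval}
            if trend == "increasing":
                logger.warning("increasing degree trend: interpret the size "
                               "estimate with caution")
        except ValueError:
            bundle["degree_trend"] = None

        if config.expert_bounds is not None:
            try:
                fa = classify_fit(summary[50], config.expert_bounds)
            except Exception as e:
                raise ModelError(f"[assess stage] {e}") from e
            assess_csv = outdir / "assessment.csv"
            with open(assess_csv, "w") as fh:
                fh.write("label,posterior_median,verdict," +
                         ",".join(fa.bounds_used) + "\n")
                fh.write(f"{config.label},{fa.posterior_median},{fa.verdict}," +
                         ",".join(str(v) for v in fa.bounds_used.values()) + "\n")
            bundle["assessment_csv"] = str(assess_csv)
            bundle["verdict"] = fa.verdict

        try:
            for name, (fig, data) in {
                "posterior": plot_posterior(result),
                "enrollment_degree": plot_enrollment_vs_degree(
                    sample, trend_seed=config.mcmc.rng_seed),
            }.items():
                fig.savefig(outdir / f"{name}.png", dpi=120)
                data.to_csv(outdir / f"{name}.csv", index=False)
                bundle[f"{name}_png"] = str(outdir / f"{name}.png")
        except Exception as e:
            raise ModelError(f"[plot stage] {e}") from e

        bundle["result"] = result
        return bundle
    finally:
        root.removeHandler(handler)
        handler.close()
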
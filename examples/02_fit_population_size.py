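"""Fit imputed-visibility SS-PSE to a simulated survey and read the answer.

The model sees only the enrollment order and the noisy self-reported
degrees, plus an expert prior median for N; it returns the posterior
distribution of the hidden population size.  The posterior median is the
point estimate and the 5%/95% quantiles bound the 90% credible interval.
"""

from rdspse import (
    MCMCConfig,
    PriorSpec,
    SimConfig,
    SuperpopParams,
    fit_sspse,
    generate_population,
    posterior_summary,
    simulate_rds,
)

cfg = SimConfig(N=1000, target_n=300, superpop=SuperpopParams(10, 5), rng_seed=7)
pop = generate_population(cfg)
sample, _ = simulate_rds(pop, cfg)

result = fit_sspse(
    sample,
    PriorSpec(median_N=1000),             # expert prior median at the truth
    MCMCConfig(burnin=1500, samples=2000, thin=1, rng_seed=1),
)

q = posterior_summary(result)
print(f"true N = {cfg.N}, sample n = {sample.n}")
print("posterior quantiles for N:")
for level in (5, 25, 50, 75, 95):
    print(f"  {level:>2}%: {q[level]:8.0f}")
lo, hi = result.credible_interval(0.90)
print(f"point estimate (median): {q[50]:.0f}; 90% credible interval "
      f"[{lo:.0f}, {hi:.0f}]")
print("posterior medians of the other unknowns:")
print(result.param_draws[["mu", "sigma", "tau", "rho"]].median().round(2).to_string())
print("-> the interval is wide: a single RDS survey carries limited")
print("   information about N beyond the prior, mostly from degree depletion.")
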
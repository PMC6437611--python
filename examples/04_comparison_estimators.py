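"""Auxiliary population size estimators: multipliers and wisdom of the crowds.

The service multiplier divides a deduplicated count of service clients by
the survey proportion reporting use of that service; the unique-object
multiplier does the same with distributed objects; wisdom of the crowds
averages participants' own guesses.  All are point estimates, compared
here against the experts' widest plausible range.
"""

import numpy as np

from rdspse import (
    ExpertBounds,
    MultiplierInput,
    PSEEstimate,
    compare_methods,
    multiplier_estimate,
    wisdom_of_crowds,
)

# a small-city PWID survey: 180 unique HIV tests in the service window,
# 30% of the survey reported testing; 80 bracelets handed out, 45% recall
service = multiplier_estimate(MultiplierInput(180, 0.30, proportion_se=0.03),
                              method="service_multiplier")
objects = multiplier_estimate(MultiplierInput(80, 0.45),
                              method="object_multiplier")
rng = np.random.default_rng(0)
woc = wisdom_of_crowds(rng.lognormal(np.log(400), 0.8, size=100))

print(f"service multiplier : {service.point:7.0f}  "
      f"(95% interval {service.interval[0]:.0f}-{service.interval[1]:.0f})")
print(f"object multiplier  : {objects.point:7.0f}")
print(f"wisdom of crowds   : {woc.point:7.0f}")

bounds = ExpertBounds(lows=(167, 300), medians=(500, 668), highs=(1000, 1446))
table = compare_methods(
    [service, objects, woc, PSEEstimate(596, "sspse")], bounds)
print("\ncomparison against the expert range "
      f"[{min(bounds.lows)}, {max(bounds.highs)}]:")
print(table[["method", "point", "implausible"]].to_string(index=False))
print("-> estimates flagged implausible fall outside the widest expert range,")
print("   the same range that separates Bad from not-Bad SS-PSE fits.")
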
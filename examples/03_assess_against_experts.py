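"""Classify size estimates against expert benchmarks.

Experts provide low/median/high plausibility bounds per population.  A
posterior median is Great/Good/Okay depending on which nested expert range
contains it, and Bad outside the widest range.  Applied to the 15
published Armenia survey rows, the widest-range rule flags 6 datasets
(40%) as Bad.
"""

from rdspse import ExpertBounds, armenia_sspse_table, assess_table, classify_fit

# two experts with overlapping ranges: the classification uses the six
# derived cutpoints (min/avg/max of the lows and highs)
bounds = ExpertBounds(lows=(120, 180), medians=(200, 250), highs=(250, 400))
for median in (200, 170, 130, 90):
    fa = classify_fit(median, bounds)
    print(f"posterior median {median:>3} -> {fa.verdict}")

table = armenia_sspse_table()
res = assess_table(
    (f"{r.population} {r.city} {r.year}", r.median, r.expert_low, r.expert_high)
    for r in table.itertuples()
)
print(f"\npublished datasets: {res['n']}; Bad: {res['n_bad']} ({res['pct_bad']}%)")
for row in res["rows"]:
    if row["bad"]:
        print(f"  Bad: {row['label']} (median {row['posterior_median']}, "
              f"range [{row['min_low']}, {row['max_high']}])")
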
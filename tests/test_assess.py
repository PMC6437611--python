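import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdspse.assess import (
    ExpertBounds,
    assess_table,
    classify_fit,
    degree_trend,
    great_fit_feasible,
    is_bad_from_range,
)
from rdspse.datasets import NO_VISIBILITY_NO_FIT, armenia_sspse_table
from rdspse.model import MeasErrParams
from rdspse.simulate import SimConfig, generate_population, simulate_rds
from rdspse.superpop import SuperpopParams
from tests.conftest import make_sample

VERDICT_RANK = {"Great": 0, "Good": 1, "Okay": 2, "Bad": 3}


class TestClassify:
    def test_identical_experts_inside(self):
        b = ExpertBounds((100, 100), (200, 200), (300, 300))
        assert classify_fit(150, b).verdict == "Great"

    def test_identical_experts_below(self):
        b = ExpertBounds((100, 100), (200, 200), (300, 300))
        assert classify_fit(99, b).verdict == "Bad"

    def test_two_expert_cutpoints(self):
        # max-low 180 <= 200 <= min-high 250
        b = ExpertBounds((120, 180), (200, 250), (250, 400))
        fa = classify_fit(200, b)
        assert fa.verdict == "Great"
        assert fa.bounds_used["max_low"] == 180
        assert fa.bounds_used["min_high"] == 250

    def test_good_band(self):
        b = ExpertBounds((100, 200), (250, 350), (400, 500))
        # avg_low 150, max_low 200; 170 misses Great but lands Good
        assert classify_fit(170, b).verdict == "Good"

    def test_okay_band(self):
        b = ExpertBounds((100, 200), (250, 350), (400, 500))
        # below avg_low 150 but above min_low 100
        assert classify_fit(120, b).verdict == "Okay"

    def test_inclusive_endpoints(self):
        b = ExpertBounds((100, 180), (200, 250), (250, 400))
        assert classify_fit(180, b).verdict == "Great"
        assert classify_fit(250, b).verdict == "Great"

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ExpertBounds((300, 100), (200, 200), (250, 300))

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 500), st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 300), st.integers(0, 300), st.integers(0, 400))
    def test_widening_never_worsens(self, m, lo1, lo2, w1, w2, widen):
        lows = (1 + lo1, 1 + lo2)
        meds = (lows[0] + 10, lows[1] + 10)
        highs = (meds[0] + w1, meds[1] + w2)
        b = ExpertBounds(lows, meds, highs)
        wider = ExpertBounds((max(1, lows[0] - widen), max(1, lows[1] - widen)),
                             meds, (highs[0] + widen, highs[1] + widen))
        assert VERDICT_RANK[classify_fit(m, wider).verdict] <= \
            VERDICT_RANK[classify_fit(m, b).verdict]

    @settings(max_examples=60, deadline=None)
    @given(st.integers(1, 2000))
    def test_bad_rule_consistency(self, m):
        b = ExpertBounds((120, 180), (200, 250), (250, 400))
        assert is_bad_from_range(m, min(b.lows), max(b.highs)) == \
            (classify_fit(m, b).verdict == "Bad")


class TestIsBadPublishedRows:
    @pytest.mark.parametrize("median,lo,hi,expected", [
        (445, 1500, 9900, True),    # FSW Yerevan 2014
        (3734, 1500, 9900, False),  # FSW Yerevan 2012
        (666, 123, 339, True),      # MSM Vanadzor 2016
        (2407, 2420, 6667, True),   # MSM Yerevan 2012, just below min low
        (596, 167, 1446, False),    # PWID Gyumri 2016
    ])
    def test_rows(self, median, lo, hi, expected):
        assert is_bad_from_range(median, lo, hi) is expected

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            is_bad_from_range(10, 100, 50)


class TestAssessTable:
    def test_armenia_counts(self):
        t = armenia_sspse_table()
        res = assess_table(
            (f"{r.population} {r.city} {r.year}", r.median, r.expert_low,
             r.expert_high) for r in t.itertuples())
        assert res["n"] == 15
        assert res["n_bad"] == 6
        assert res["pct_bad"] == 40
        flagged = {r["label"] for r in res["rows"] if r["bad"]}
        published = {f"{r.population} {r.city} {r.year}"
                     for r in t.itertuples() if r.assessment == "Bad"}
        assert flagged == published

    def test_no_bad_rows(self):
        res = assess_table([("a", 50, 10, 100), ("b", 99, 10, 100)])
        assert res["n_bad"] == 0 and res["pct_bad"] == 0

    def test_single_bad_row(self):
        res = assess_table([("a", 5, 10, 100)])
        assert res["n_bad"] == 1 and res["pct_bad"] == 100

    def test_empty_error(self):
        with pytest.raises(ValueError):
            assess_table([])

    def test_pct_rounding(self):
        rows = [("x", 5, 10, 100)] + [("y", 50, 10, 100)] * 2
        assert assess_table(rows)["pct_bad"] == 33


class TestGreatFeasible:
    def test_disjoint_expert_ranges(self):
        b = ExpertBounds((100, 180), (140, 200), (150, 300))
        assert not great_fit_feasible(b)  # max low 180 > min high 150

    def test_identical_experts(self):
        b = ExpertBounds((100, 100), (200, 200), (300, 300))
        assert great_fit_feasible(b)

    def test_published_dataset_counts(self):
        # published assessments: 4 Great, 2 Good, 3 Okay, 6 Bad of 15
        t = armenia_sspse_table()
        counts = t.assessment.value_counts().to_dict()
        assert counts == {"Bad": 6, "Great": 4, "Okay": 3, "Good": 2}
        assert len(NO_VISIBILITY_NO_FIT) == 6


class TestDegreeTrend:
    def test_monotone_decreasing(self):
        s = make_sample(list(range(60, 10, -1)))
        slope, label, p = degree_trend(s)
        assert slope < 0 and label == "decreasing" and p <= 0.05

    def test_monotone_increasing_flags_caution(self):
        s = make_sample(list(range(10, 60)))
        slope, label, p = degree_trend(s)
        assert slope > 0 and label == "increasing" and p <= 0.05

    def test_constant_degrees(self):
        s = make_sample([7] * 40)
        slope, label, p = degree_trend(s)
        assert (slope, label, p) == (0.0, "constant", 1.0)

    def test_too_few_degrees(self):
        with pytest.raises(ValueError):
            degree_trend(make_sample([3] * 5))

    def test_shuffled_iid_mostly_constant(self):
        rng = np.random.default_rng(5)
        labels = []
        for _ in range(20):
            degs = rng.integers(1, 30, size=80).tolist()
            labels.append(degree_trend(make_sample(degs), rng_seed=1)[1])
        assert labels.count("constant") >= 16  # ~alpha = 0.05 false positives

    def test_depletion_scenario_detected(self):
        # 80% sample fraction at the capital-city sample size
        hits = 0
        for seed in range(30):
            cfg = SimConfig(N=375, target_n=300, superpop=SuperpopParams(10, 5),
                            meas_err=MeasErrParams(1.0, 1.0), rng_seed=seed)
            pop = generate_population(cfg)
            sample, _ = simulate_rds(pop, cfg)
            if degree_trend(sample, rng_seed=seed)[1] == "decreasing":
                hits += 1
        assert hits > 15  # majority of replicates
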
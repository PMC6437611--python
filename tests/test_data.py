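import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdspse.data import (
    MISSING_DEGREE,
    Participant,
    RDSSample,
    effective_degree,
    read_coupon_matrix_csv,
    read_rds_csv,
    write_rds_csv,
)
from rdspse.errors import (
    CyclicRecruitmentError,
    DegreeInconsistencyError,
    DuplicateIdError,
    MissingColumnError,
    RDSValidationError,
    RecruitmentOrderError,
)
from rdspse.simulate import SimConfig, generate_population, simulate_rds
from rdspse.superpop import SuperpopParams


def _write(tmp_path, text, name="rds.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCsv:
    def test_minimal_forest(self, tmp_path):
        p = _write(tmp_path, (
            "id,recruiter_id,date,degree_known,degree_seen,coupons_issued\n"
            "A,,2016-01-01,10,4,3\n"
            "B,A,2016-01-02,5,,3\n"
            "C,A,2016-01-03,7,2,3\n"
        ))
        s = read_rds_csv(p)
        assert s.n == 3
        assert [s.waves[x] for x in ("A", "B", "C")] == [0, 1, 1]
        assert [p_.is_seed for p_ in s.participants] == [True, False, False]

    def test_cycle_raises(self, tmp_path):
        p = _write(tmp_path, "id,recruiter_id,degree_known\nA,B,3\nB,A,4\n")
        with pytest.raises(CyclicRecruitmentError):
            read_rds_csv(p)

    def test_degree_inconsistency_names_row(self, tmp_path):
        p = _write(tmp_path, (
            "id,recruiter_id,degree_known,degree_seen\nA,,10,4\nB,A,5,9\n"
        ))
        with pytest.raises(DegreeInconsistencyError, match="B"):
            read_rds_csv(p)

    def test_missing_column(self, tmp_path):
        p = _write(tmp_path, "id,degree_known\nA,3\n")
        with pytest.raises(MissingColumnError):
            read_rds_csv(p)

    def test_duplicate_id(self, tmp_path):
        p = _write(tmp_path, "id,recruiter_id,degree_known\nA,,3\nA,,4\n")
        with pytest.raises(DuplicateIdError):
            read_rds_csv(p)

    def test_recruiter_after_recruit(self, tmp_path):
        # B appears before its recruiter C; no cycle
        p = _write(tmp_path,
                   "id,recruiter_id,degree_known\nA,,3\nB,C,4\nC,A,5\n")
        with pytest.raises(RecruitmentOrderError):
            read_rds_csv(p)

    def test_dialect_mapping(self, tmp_path):
        p = _write(tmp_path, "pid,ref,deg\nA,,10\nB,A,5\n")
        s = read_rds_csv(p, dialect={"participant_id": "pid",
                                     "recruiter_id": "ref",
                                     "degree_known": "deg"})
        assert s.n == 2 and s.participants[1].recruiter_id == "A"

    def test_date_ordering_ties_by_file_order(self, tmp_path):
        p = _write(tmp_path, (
            "id,recruiter_id,date,degree_known\n"
            "A,,2016-01-02,1\nB,,2016-01-01,2\nC,B,2016-01-02,3\n"
        ))
        s = read_rds_csv(p)
        assert [x.participant_id for x in s.participants] == ["B", "A", "C"]


class TestEffectiveDegree:
    @pytest.mark.parametrize("known,seen,expected", [
        (20, 8, 8),        # second, more restrictive number is used
        (5, None, 5),      # fall back on the broader count
        (None, None, MISSING_DEGREE),
    ])
    def test_cases(self, known, seen, expected):
        p = Participant("X", None, 1, degree_known=known, degree_seen=seen)
        assert effective_degree(p) == expected

    def test_never_exceeds_known(self):
        p = Participant("X", None, 1, degree_known=9, degree_seen=3)
        assert effective_degree(p) <= p.degree_known

    def test_seen_above_known_rejected(self):
        with pytest.raises(DegreeInconsistencyError):
            Participant("X", None, 1, degree_known=3, degree_seen=9)


class TestRoundTrip:
    def test_empty_sample_rejected(self):
        with pytest.raises(RDSValidationError):
            RDSSample(participants=[])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_roundtrip(self, tmp_path, seed):
        cfg = SimConfig(N=300, target_n=100, superpop=SuperpopParams(8, 4),
                        rng_seed=seed)
        pop = generate_population(cfg)
        sample, _ = simulate_rds(pop, cfg)
        path = tmp_path / f"s{seed}.csv"
        write_rds_csv(sample, path)
        back = read_rds_csv(path, label=sample.label)
        assert back.n == sample.n
        assert [p.participant_id for p in back.participants] == \
            [p.participant_id for p in sample.participants]
        assert np.array_equal(back.effective_degrees(), sample.effective_degrees())
        assert back.waves == sample.waves

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=80), min_size=1, max_size=30),
           st.booleans())
    def test_chain_roundtrip_property(self, tmp_path_factory, degrees, chain):
        parts = []
        for i, dk in enumerate(degrees):
            rid = None if (i == 0 or not chain) else f"P{i}"
            parts.append(Participant(f"P{i + 1}", rid, i + 1, degree_known=dk,
                                     coupons_issued=len(degrees)))
        s = RDSSample(participants=parts)
        path = tmp_path_factory.mktemp("rt") / "s.csv"
        write_rds_csv(s, path)
        back = read_rds_csv(path)
        assert np.array_equal(back.effective_degrees(), s.effective_degrees())
        assert back.waves == s.waves


class TestWaves:
    def test_wave_recursion(self):
        parts = [
            Participant("S", None, 1, degree_known=5, coupons_issued=3),
            Participant("A", "S", 2, degree_known=5, coupons_issued=3),
            Participant("B", "A", 3, degree_known=5, coupons_issued=3),
            Participant("T", None, 4, degree_known=5, coupons_issued=3),
        ]
        s = RDSSample(participants=parts)
        assert s.waves == {"S": 0, "A": 1, "B": 2, "T": 0}
        for p in s.participants:
            if p.recruiter_id is not None:
                assert s.waves[p.participant_id] == s.waves[p.recruiter_id] + 1

    def test_coupon_capacity_enforced(self):
        parts = [Participant("S", None, 1, degree_known=5, coupons_issued=1)]
        parts += [Participant(f"R{i}", "S", i + 2, degree_known=3,
                              coupons_issued=1) for i in range(2)]
        with pytest.raises(RDSValidationError, match="coupons"):
            RDSSample(participants=parts)


def test_coupon_matrix_shim(tmp_path):
    p = tmp_path / "cm.csv"
    p.write_text(
        "id,own_coupon,coupon_1,coupon_2,degree_known\n"
        "A,,c1,c2,10\n"
        "B,c1,c3,,5\n"
        "C,c2,,,7\n"
    )
    s = read_coupon_matrix_csv(p)
    assert s.n == 3
    assert s.participants[0].is_seed
    assert s.participants[1].recruiter_id == "A"
    assert s.waves == {"A": 0, "B": 1, "C": 1}
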
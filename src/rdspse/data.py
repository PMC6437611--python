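"""Domain types and CSV I/O for respondent-driven sampling (RDS) recruitment data.

An RDS survey starts from a handful of convenience-selected *seeds*; every
enrollee receives a small fixed number of coupons (typically at most three)
with which to recruit peers, so the who-recruited-whom links form a forest
rooted at the seeds.  Each participant reports a network size (degree): how
many eligible alters they know, and — more restrictively — how many of those
they have seen recently.  The model's time axis is the order of enrollment;
calendar dates are optional metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    CyclicRecruitmentError,
    DegreeInconsistencyError,
    DuplicateIdError,
    MissingColumnError,
    RDSValidationError,
    RecruitmentOrderError,
)

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`effective_degree` when both degree questions
#: are unanswered; the model imputes the visibility for such participants.
MISSING_DEGREE: int = -1

#: Default column-name mapping for :func:`read_rds_csv`.
DEFAULT_DIALECT: Mapping[str, str] = {
    "participant_id": "id",
    "recruiter_id": "recruiter_id",
    "enrollment_date": "date",
    "degree_known": "degree_known",
    "degree_seen": "degree_seen",
    "coupons_issued": "coupons_issued",
}


@dataclass(frozen=True)
class Participant:
    """One RDS enrollee.

    ``recruiter_id is None`` marks a seed.  ``enrollment_index`` is the
    1-based order of enrollment within the sample.  ``degree_known`` is the
    count of eligible alters known; ``degree_seen`` the (more restrictive)
    subset seen in the past month.  Either may be missing (None).
    """

    participant_id: str
    recruiter_id: Optional[str]
    enrollment_index: int
    degree_known: Optional[int] = None
    degree_seen: Optional[int] = None
    coupons_issued: int = 3
    enrollment_date: Optional[date] = None

    def __post_init__(self) -> None:
        if self.enrollment_index < 1:
            raise RDSValidationError(
                f"participant {self.participant_id!r}: enrollment_index must be >= 1"
            )
        for name in ("degree_known", "degree_seen"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise RDSValidationError(
                    f"participant {self.participant_id!r}: {name} must be nonnegative"
                )
        if (
            self.degree_known is not None
            and self.degree_seen is not None
            and self.degree_seen > self.degree_known
        ):
            raise DegreeInconsistencyError(
                f"participant {self.participant_id!r}: degree_seen "
                f"({self.degree_seen}) exceeds degree_known ({self.degree_known})"
            )
        if self.coupons_issued < 0:
            raise RDSValidationError(
                f"participant {self.participant_id!r}: coupons_issued must be >= 0"
            )

    @property
    def is_seed(self) -> bool:
        return self.recruiter_id is None


def effective_degree(p: Participant) -> int:
    """The reported degree d_i used by the model.

    The two-part network size question asks how many eligible alters the
    participant knows and, as a follow-up, how many of them they have seen in
    the past month; the second, more restrictive number is used when present.
    Returns :data:`MISSING_DEGREE` when both are missing.
    """
    if p.degree_seen is not None:
        return p.degree_seen
    if p.degree_known is not None:
        return p.degree_known
    return MISSING_DEGREE


@dataclass
class RDSSample:
    """An ordered RDS sample: participants sorted by enrollment order.

    Invariants checked on construction: enrollment indices are a permutation
    of 1..n, ids unique, recruitment links form a forest rooted at the seeds
    with every recruiter enrolled strictly before their recruits.
    """

    participants: list[Participant]
    label: str = ""
    _waves: Optional[dict[str, int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.participants:
            raise RDSValidationError("an RDS sample must contain at least one participant")
        self.participants = sorted(self.participants, key=lambda p: p.enrollment_index)
        idx = [p.enrollment_index for p in self.participants]
        n = len(idx)
        if idx != list(range(1, n + 1)):
            raise RDSValidationError(
                f"enrollment_index values must be a permutation of 1..{n}, got {idx[:10]}..."
            )
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != n:
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise DuplicateIdError(f"duplicate participant id {dup!r}")
        by_id = {p.participant_id: p for p in self.participants}
        for p in self.participants:
            if p.recruiter_id is None:
                continue
            rec = by_id.get(p.recruiter_id)
            if rec is None:
                raise RDSValidationError(
                    f"participant {p.participant_id!r} has unknown recruiter "
                    f"{p.recruiter_id!r}"
                )
            if rec.enrollment_index >= p.enrollment_index:
                # covers self-recruitment and 2-cycles like A->B->A as well
                if rec.participant_id == p.participant_id or _on_cycle(by_id, p):
                    raise CyclicRecruitmentError(
                        f"recruitment links through {p.participant_id!r} form a cycle"
                    )
                raise RecruitmentOrderError(
                    f"recruiter {rec.participant_id!r} (index {rec.enrollment_index}) "
                    f"enrolled after recruit {p.participant_id!r} "
                    f"(index {p.enrollment_index})"
                )
        counts: dict[str, int] = {}
        for p in self.participants:
            if p.recruiter_id is not None:
                counts[p.recruiter_id] = counts.get(p.recruiter_id, 0) + 1
        for rid, c in counts.items():
            cap = by_id[rid].coupons_issued
            if c > cap:
                raise RDSValidationError(
                    f"recruiter {rid!r} has {c} recruits but issued only {cap} coupons"
                )

    @property
    def n(self) -> int:
        return len(self.participants)

    @property
    def waves(self) -> dict[str, int]:
        """Wave per participant: seeds are wave 0, a recruit is recruiter's wave + 1."""
        if self._waves is None:
            w: dict[str, int] = {}
            for p in self.participants:  # enrollment order => recruiter already done
                w[p.participant_id] = 0 if p.recruiter_id is None else w[p.recruiter_id] + 1
            self._waves = w
        return self._waves

    @property
    def seeds(self) -> list[Participant]:
        return [p for p in self.participants if p.is_seed]

    def effective_degrees(self) -> np.ndarray:
        """Reported degrees d_i in enrollment order (MISSING_DEGREE where absent)."""
        return np.array([effective_degree(p) for p in self.participants], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": p.participant_id,
                "recruiter_id": p.recruiter_id if p.recruiter_id is not None else "",
                "date": p.enrollment_date.isoformat() if p.enrollment_date else "",
                "degree_known": p.degree_known,
                "degree_seen": p.degree_seen,
                "coupons_issued": p.coupons_issued,
                "wave": self.waves[p.participant_id],
            }
            for p in self.participants
        ]
        return pd.DataFrame(rows)


def _on_cycle(by_id: Mapping[str, Participant], start: Participant) -> bool:
    slow = start
    seen = {start.participant_id}
    while slow.recruiter_id is not None:
        nxt = by_id.get(slow.recruiter_id)
        if nxt is None:
            return False
        if nxt.participant_id in seen:
            return True
        seen.add(nxt.participant_id)
        slow = nxt
    return False


def read_rds_csv(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    label: str = "",
    degree_cap: Optional[int] = None,
) -> RDSSample:
    """Read an RDS sample from a CSV file.

    ``dialect`` maps canonical field names (keys of :data:`DEFAULT_DIALECT`)
    to the column names used in the file.  Rows are ordered by enrollment
    date when present, ties broken by file order (logged); otherwise file
    order is the enrollment order.  ``degree_cap`` only flags (logs)
    impossibly high degrees — values are never truncated at read time.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canon in ("participant_id", "recruiter_id", "degree_known"):
        if cols[canon] not in df.columns:
            raise MissingColumnError(
                f"required column {cols[canon]!r} (for {canon}) not found in {path}"
            )

    def _opt_int(v: str, row: int, name: str) -> Optional[int]:
        v = v.strip()
        if v in ("", "NA", "nan", "None"):
            return None
        try:
            return int(float(v))
        except ValueError:
            raise RDSValidationError(f"row {row}: cannot parse {name}={v!r}") from None

    has_date = cols["enrollment_date"] in df.columns
    if has_date:
        dates = pd.to_datetime(
            df[cols["enrollment_date"]].replace("", pd.NA), errors="coerce"
        )
        if dates.notna().any():
            order = np.argsort(dates.to_numpy(), kind="stable")  # stable: file order ties
            if dates.duplicated(keep=False).any():
                logger.info("tied enrollment dates in %s resolved by file order", path)
            df = df.iloc[order].reset_index(drop=True)
            dates = dates.iloc[order].reset_index(drop=True)
    participants = []
    for i, row in df.iterrows():
        rid = row[cols["recruiter_id"]].strip()
        dk = _opt_int(row[cols["degree_known"]], i, "degree_known")
        ds = (
            _opt_int(row[cols["degree_seen"]], i, "degree_seen")
            if cols["degree_seen"] in df.columns
            else None
        )
        if dk is not None and ds is not None and ds > dk:
            raise DegreeInconsistencyError(
                f"row {i} (id {row[cols['participant_id']]!r}): degree_seen {ds} "
                f"> degree_known {dk}"
            )
        if degree_cap is not None and dk is not None and dk > degree_cap:
            logger.warning(
                "row %d: degree_known %d exceeds cap %d (kept)", i, dk, degree_cap
            )
        cp = (
            _opt_int(row[cols["coupons_issued"]], i, "coupons_issued")
            if cols["coupons_issued"] in df.columns
            else None
        )
        ed = None
        if has_date and str(row[cols["enrollment_date"]]).strip():
            ts = pd.to_datetime(row[cols["enrollment_date"]], errors="coerce")
            ed = None if pd.isna(ts) else ts.date()
        participants.append(
            Participant(
                participant_id=row[cols["participant_id"]].strip(),
                recruiter_id=rid or None,
                enrollment_index=i + 1,
                degree_known=dk,
                degree_seen=ds,
                coupons_issued=cp if cp is not None else 3,
                enrollment_date=ed,
            )
        )
    return RDSSample(participants=participants, label=label)


def write_rds_csv(sample: RDSSample, path) -> None:
    """Write a sample as CSV; round-trips losslessly through :func:`read_rds_csv`."""
    df = sample.to_frame().drop(columns=["wave"])
    df.to_csv(path, index=False)


def read_coupon_matrix_csv(path, label: str = "") -> RDSSample:
    """Reader shim for coupon-matrix style RDS files.

    Expects columns ``id``, ``own_coupon`` and ``coupon_1..coupon_k``; the
    recruiter of a participant is whoever issued the coupon the participant
    redeemed.  Maps into the same :class:`RDSSample` type.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns or "own_coupon" not in df.columns:
        raise MissingColumnError("coupon-matrix file needs 'id' and 'own_coupon' columns")
    coupon_cols = [c for c in df.columns if c.startswith("coupon_")]
    issued_by: dict[str, str] = {}
    for _, row in df.iterrows():
        for c in coupon_cols:
            v = row[c].strip()
            if v:
                issued_by[v] = row["id"].strip()
    participants = []
    for i, row in df.iterrows():
        own = row["own_coupon"].strip()
        dk = row.get("degree_known", "")
        participants.append(
            Participant(
                participant_id=row["id"].strip(),
                recruiter_id=issued_by.get(own),
                enrollment_index=i + 1,
                degree_known=int(dk) if str(dk).strip() else None,
                degree_seen=None,
                coupons_issued=sum(1 for c in coupon_cols if row[c].strip()),
            )
        )
    return RDSSample(participants=participants, label=label)
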
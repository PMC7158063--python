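"""Life-stage calendar: conception dating and pregnancy/infancy windows.

Every exposure window in this package is a *life stage*: a closed interval of
calendar days anchored on a cohort member's date of conception (DoC) and date
of birth (DoB).  DoC is derived from the gestational age at birth in completed
weeks:

    DoC = DoB - (7 x gestation_weeks) - 1 day

and the stages are laid out as

    P  : [DoC, DoB]                      whole pregnancy, delivery day included
    T1 : [DoC, DoC + 92 d]               first trimester
    T2 : [DoC + 93 d, min(DoC + 183 d, DoB - 1 d)]
    T3 : [DoC + 184 d, DoB - 1 d]        omitted when the birth is premature
                                         enough that DoC + 184 d > DoB - 1 d
    EI : [DoB, DoB + 6 months - 1 d]     early infancy
    LI : [DoB + 6 months, DoB + 12 months - 1 d]   late infancy

For premature births without a T3, T2 is truncated to end on DoB - 1 day so
that the trimesters and infancy stages tile [DoC, LI end] with no gap and no
double-covered day.  The day of birth itself belongs to P and EI but to no
trimester; this asymmetry is deliberate (P is defined through DoB inclusive)
and is preserved literally.

Month arithmetic for EI/LI clamps the day-of-month to the target month's last
day (e.g. 31 Aug + 6 months -> 28/29 Feb), matching common administrative
date handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

__all__ = [
    "StudyMember",
    "LifeStage",
    "MemberValidationError",
    "conception_date",
    "build_life_stages",
    "pregnancy_window",
    "add_months",
    "build_stage_table",
    "members_from_frame",
    "TRIMESTER_STAGES",
    "INFANCY_STAGES",
    "TILING_STAGES",
    "PREGNANCY",
    "ALL_STAGES",
]

# Stage name constants, in chronological order.
TRIMESTER_STAGES: tuple[str, ...] = ("T1", "T2", "T3")
INFANCY_STAGES: tuple[str, ...] = ("EI", "LI")
TILING_STAGES: tuple[str, ...] = TRIMESTER_STAGES + INFANCY_STAGES
PREGNANCY = "P"
ALL_STAGES: tuple[str, ...] = TILING_STAGES + (PREGNANCY,)

#: completed-weeks range outside which a gestational age draws a warning
PLAUSIBLE_GESTATION = (20, 44)

_DAY = timedelta(days=1)


class MemberValidationError(ValueError):
    """A cohort member's fields cannot support life-stage construction."""


def _check_gestation(member_id: str, gestation_weeks) -> int:
    if isinstance(gestation_weeks, bool) or not isinstance(
        gestation_weeks, (int, np.integer)
    ):
        raise MemberValidationError(
            f"member {member_id!r}: gestational age must be an integer number "
            f"of completed weeks, got {gestation_weeks!r}"
        )
    weeks = int(gestation_weeks)
    if weeks < 0:
        raise MemberValidationError(
            f"member {member_id!r}: negative gestational age ({weeks} weeks)"
        )
    lo, hi = PLAUSIBLE_GESTATION
    if not lo <= weeks <= hi:
        warnings.warn(
            f"member {member_id!r}: gestational age {weeks} weeks outside the "
            f"plausible range [{lo}, {hi}]",
            stacklevel=3,
        )
    return weeks


@dataclass(frozen=True)
class StudyMember:
    """A cohort participant: the anchors for all temporal windows.

    Parameters
    ----------
    member_id
        Opaque identifier, unique within a cohort.
    date_of_birth
        Calendar date of delivery.
    gestation_weeks
        Gestational age at birth in completed weeks (integer).  Values
        outside ``PLAUSIBLE_GESTATION`` trigger a warning; values so low that
        a mandatory stage would be empty raise ``MemberValidationError`` in
        :func:`build_life_stages`.
    """

    member_id: str
    date_of_birth: date
    gestation_weeks: int

    def __post_init__(self) -> None:
        _check_gestation(self.member_id, self.gestation_weeks)

    @property
    def conception(self) -> date:
        return conception_date(self.date_of_birth, self.gestation_weeks)


@dataclass(frozen=True)
class LifeStage:
    """A named closed date interval; both endpoints are inclusive days."""

    name: str
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"stage {self.name}: start {self.start_date} after end {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def __contains__(self, day: date) -> bool:
        return self.start_date <= day <= self.end_date

    def overlap_days(self, start: date, end: date) -> int:
        """Days shared with the closed interval [start, end]."""
        lo = max(self.start_date, start)
        hi = min(self.end_date, end)
        return max(0, (hi - lo).days + 1)


def conception_date(date_of_birth: date, gestation_weeks: int, member_id: str = "?") -> date:
    """Date of conception: DoB minus (7 x completed weeks) minus one day."""
    weeks = _check_gestation(member_id, gestation_weeks)
    return date_of_birth - timedelta(days=7 * weeks + 1)


def add_months(day: date, months: int) -> date:
    """Add calendar months, clamping the day-of-month to the target month."""
    return day + relativedelta(months=months)


def build_life_stages(member: StudyMember) -> list[LifeStage]:
    """Construct the tiling stages T1..LI for one member.

    The returned stages partition [DoC, LI end]: pairwise disjoint,
    chronologically ordered, and contiguous.  T3 is omitted for births
    premature enough that its interval would be empty, in which case T2 is
    truncated to end the day before birth.

    Raises
    ------
    MemberValidationError
        If the second trimester would be empty (gestation below 14 weeks);
        such members must be excluded from the cohort.
    """
    dob = member.date_of_birth
    doc = conception_date(dob, member.gestation_weeks, member.member_id)
    last_prenatal = dob - _DAY
    if last_prenatal < doc + timedelta(days=93):
        raise MemberValidationError(
            f"member {member.member_id!r}: gestation {member.gestation_weeks} "
            "weeks leaves the second trimester empty; member excluded "
            "(reason: empty mandatory life stage)"
        )
    stages = [
        LifeStage("T1", doc, doc + timedelta(days=92)),
        LifeStage("T2", doc + timedelta(days=93), min(doc + timedelta(days=183), last_prenatal)),
    ]
    t3_start = doc + timedelta(days=184)
    if t3_start <= last_prenatal:
        stages.append(LifeStage("T3", t3_start, last_prenatal))
    half_year = add_months(dob, 6)
    stages.append(LifeStage("EI", dob, half_year - _DAY))
    stages.append(LifeStage("LI", half_year, add_months(dob, 12) - _DAY))
    return stages


def pregnancy_window(member: StudyMember) -> LifeStage:
    """Whole-pregnancy stage P = [DoC, DoB], delivery day included.

    Note P shares its start with T1 but, unlike every trimester, includes the
    day of birth itself.
    """
    doc = conception_date(member.date_of_birth, member.gestation_weeks, member.member_id)
    return LifeStage(PREGNANCY, doc, member.date_of_birth)


# ---------------------------------------------------------------------------
# cohort-level helpers

def members_from_frame(frame: pd.DataFrame) -> list[StudyMember]:
    """Build validated StudyMembers from a members table.

    Expects columns member_id, date_of_birth, gestation_weeks; duplicate
    member ids raise ``MemberValidationError``.
    """
    dup = frame["member_id"][frame["member_id"].duplicated()]
    if len(dup):
        raise MemberValidationError(
            f"duplicate member ids: {sorted(set(dup.astype(str)))[:5]}"
        )
    members = []
    for row in frame.itertuples(index=False):
        dob = row.date_of_birth
        if isinstance(dob, pd.Timestamp):
            dob = dob.date()
        members.append(StudyMember(str(row.member_id), dob, int(row.gestation_weeks)))
    return members


def build_stage_table(
    members: Iterable[StudyMember], include_pregnancy: bool = True
) -> pd.DataFrame:
    """Stage table for a cohort: one row per member x emitted stage.

    Columns: member_id, stage_name, start_date, end_date, n_days (dates as
    datetime64).  Includes the whole-pregnancy stage P unless disabled.
    """
    rows = []
    for m in members:
        stages: Sequence[LifeStage] = build_life_stages(m)
        if include_pregnancy:
            stages = list(stages) + [pregnancy_window(m)]
        for s in stages:
            rows.append((m.member_id, s.name, s.start_date, s.end_date, s.n_days))
    out = pd.DataFrame(
        rows, columns=["member_id", "stage_name", "start_date", "end_date", "n_days"]
    )
    out["start_date"] = pd.to_datetime(out["start_date"])
    out["end_date"] = pd.to_datetime(out["end_date"])
    return out
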
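"""Clean audit-style contact-database address records into residential histories.

A cohort contact database audits *current* addresses: a new row is created
whenever anything changes, including corrections, so raw rows are not a
residence history.  The cleaning protocol here turns those rows into a
contiguous one-location-per-day history per member under a single governing
assumption, *start-date primacy*: the start date of an address period is a
database time stamp and therefore a stronger signal than its end date, which
is typically imputed.  Conflicts are always resolved by adjusting end dates.

The per-member pipeline:

1. ``impute_missing_dates`` — missing start dates become the date of
   conception; missing end dates become the configured current date.
2. ``order_periods`` — sort by start date; among rows sharing a start date
   only the newest (highest record sequence) survives, treating later rows
   as corrections.
3. ``resolve_gaps_overlaps`` — set each period's end to the day before its
   successor's start, closing gaps and trimming overlaps alike; the final
   period's end is never altered.
4. ``subsume_invalid_geocodes`` — an address period without a usable geocode
   is absorbed by the following valid period (whose start moves back),
   provided the invalid period overlaps no life stage by more than a
   configurable fraction of the stage's days (default 25%).  Otherwise the
   period is retained and every stage it touches is marked unreliable.
5. ``validate_history`` — report any life-stage days not covered by the
   history; shortfalls mark the affected stages unreliable.

Only *reliable* member x stage combinations — fully covered by usable
geocoded periods — later receive exposure aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .lifestages import LifeStage, StudyMember, build_life_stages, conception_date, pregnancy_window

__all__ = [
    "RawAddressRecord",
    "AddressPeriod",
    "ChangeLogEntry",
    "DropLogEntry",
    "CleaningAudit",
    "CleanedHistory",
    "HistoryValidation",
    "DEFAULT_MAX_OVERLAP_FRACTION",
    "impute_missing_dates",
    "order_periods",
    "resolve_gaps_overlaps",
    "subsume_invalid_geocodes",
    "validate_history",
    "clean_member_history",
    "clean_cohort",
    "periods_to_frame",
    "records_from_frame",
]

_DAY = timedelta(days=1)

#: largest tolerated |invalid period ∩ stage| / |stage| for subsumption (non-strict)
DEFAULT_MAX_OVERLAP_FRACTION = 0.25


@dataclass(frozen=True)
class RawAddressRecord:
    """One contact-database row, as extracted.

    ``record_seq`` ranks database entry order (creation time) within a
    member and must be unique per member.  Either date may be missing, and
    start <= end is *not* assumed: raw audit data may violate it.
    """

    member_id: str
    record_seq: int
    location_id: str | None
    start_date: date | None
    end_date: date | None
    geocode_valid: bool = True
    in_study_area: bool = True

    @property
    def usable_geocode(self) -> bool:
        return bool(self.geocode_valid and self.in_study_area and self.location_id)


@dataclass
class AddressPeriod:
    """A cleaned address period in a member's contiguous history."""

    member_id: str
    period_index: int
    location_id: str | None
    start_date: date
    end_date: date
    start_imputed: bool = False
    end_imputed: bool = False
    end_adjusted: bool = False
    subsumed_predecessor: bool = False
    usable_geocode: bool = True
    record_seq: int | None = None

    @property
    def n_dates_changed(self) -> int:
        start_changed = self.start_imputed or self.subsumed_predecessor
        end_changed = self.end_imputed or self.end_adjusted
        return int(start_changed) + int(end_changed)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def __contains__(self, day: date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass(frozen=True)
class ChangeLogEntry:
    member_id: str
    record_seq: int | None
    field: str
    old: object
    new: object
    rule: str


@dataclass(frozen=True)
class DropLogEntry:
    member_id: str
    record_seq: int | None
    reason: str


@dataclass
class CleaningAudit:
    """Per-change log plus counters; counters equal the log subsets' sizes."""

    changes: list[ChangeLogEntry] = field(default_factory=list)
    drops: list[DropLogEntry] = field(default_factory=list)
    n_records_in: int = 0
    n_periods_out: int = 0
    n_subsumed: int = 0
    n_with_any_date_changed: int = 0
    n_with_more_than_one_date_changed: int = 0

    @property
    def n_dropped(self) -> int:
        return len(self.drops)

    def extend(self, other: "CleaningAudit") -> None:
        self.changes.extend(other.changes)
        self.drops.extend(other.drops)
        self.n_records_in += other.n_records_in
        self.n_periods_out += other.n_periods_out
        self.n_subsumed += other.n_subsumed
        self.n_with_any_date_changed += other.n_with_any_date_changed
        self.n_with_more_than_one_date_changed += other.n_with_more_than_one_date_changed

    def summary(self) -> dict:
        return {
            "n_records_in": self.n_records_in,
            "n_periods_out": self.n_periods_out,
            "n_dropped": self.n_dropped,
            "n_subsumed": self.n_subsumed,
            "n_with_any_date_changed": self.n_with_any_date_changed,
            "n_with_more_than_one_date_changed": self.n_with_more_than_one_date_changed,
        }

    def to_records(self) -> list[dict]:
        """Flatten both logs into JSON-serialisable dicts (one per event)."""
        out: list[dict] = []
        for c in self.changes:
            out.append(
                {
                    "event": "change",
                    "member_id": c.member_id,
                    "record_seq": c.record_seq,
                    "field": c.field,
                    "old": None if c.old is None else str(c.old),
                    "new": None if c.new is None else str(c.new),
                    "rule": c.rule,
                }
            )
        for d in self.drops:
            out.append(
                {
                    "event": "drop",
                    "member_id": d.member_id,
                    "record_seq": d.record_seq,
                    "reason": d.reason,
                }
            )
        return out


# ---------------------------------------------------------------------------
# step 1: imputation

def impute_missing_dates(
    record: RawAddressRecord, doc: date, current_date: date
) -> tuple[RawAddressRecord | None, tuple[bool, bool], CleaningAudit]:
    """Fill missing dates: start <- date of conception, end <- current date.

    Returns the (possibly) updated record, the (start_imputed, end_imputed)
    flags, and an audit fragment.  A record with no location and neither
    date is unusable and is dropped (record None, reason logged).
    """
    if current_date < doc:
        raise ValueError("current_date precedes the date of conception")
    audit = CleaningAudit(n_records_in=1)
    if record.location_id is None and record.start_date is None and record.end_date is None:
        audit.drops.append(DropLogEntry(record.member_id, record.record_seq, "empty record"))
        return None, (False, False), audit
    start_imputed = end_imputed = False
    new = record
    if new.start_date is None:
        audit.changes.append(
            ChangeLogEntry(new.member_id, new.record_seq, "start_date", None, doc,
                           "impute missing start with DoC")
        )
        new = replace(new, start_date=doc)
        start_imputed = True
    if new.end_date is None:
        audit.changes.append(
            ChangeLogEntry(new.member_id, new.record_seq, "end_date", None, current_date,
                           "impute missing end with current date")
        )
        new = replace(new, end_date=current_date)
        end_imputed = True
    return new, (start_imputed, end_imputed), audit


# ---------------------------------------------------------------------------
# step 2: ordering and correction-row deduplication

_Imputed = tuple[RawAddressRecord, bool, bool]  # record (dates filled), start/end imputed


def order_periods(imputed: Sequence[_Imputed]) -> tuple[list[_Imputed], CleaningAudit]:
    """Sort records by (start date, entry order); deduplicate shared starts.

    Among records sharing an identical start date only the highest
    ``record_seq`` survives: a newer row restating the same start is a
    correction superseding the older rows, whatever their locations say.
    """
    audit = CleaningAudit()
    ordered = sorted(imputed, key=lambda t: (t[0].start_date, t[0].record_seq))
    kept: list[_Imputed] = []
    for item in ordered:
        if kept and kept[-1][0].start_date == item[0].start_date:
            superseded = kept.pop()
            audit.drops.append(
                DropLogEntry(superseded[0].member_id, superseded[0].record_seq,
                             "superseded duplicate start")
            )
        kept.append(item)
    return kept, audit


# ---------------------------------------------------------------------------
# step 3: gap and overlap resolution

def resolve_gaps_overlaps(ordered: Sequence[_Imputed]) -> tuple[list[AddressPeriod], CleaningAudit]:
    """Make the history contiguous by adjusting end dates only.

    For each consecutive pair the earlier period's end is set to the day
    before the successor's start whenever the two are not already
    contiguous; this one rule closes gaps (end extended forward) and trims
    overlaps (end pulled back) alike.  The final period's end is never
    altered here.  A period whose adjusted end would precede its start is
    dropped as fully enclosed by its successor.
    """
    audit = CleaningAudit()
    periods: list[AddressPeriod] = []
    items = list(ordered)
    for i, (rec, s_imp, e_imp) in enumerate(items):
        p = AddressPeriod(
            member_id=rec.member_id,
            period_index=0,  # reassigned below
            location_id=rec.location_id,
            start_date=rec.start_date,
            end_date=rec.end_date,
            start_imputed=s_imp,
            end_imputed=e_imp,
            usable_geocode=rec.usable_geocode,
            record_seq=rec.record_seq,
        )
        if i + 1 < len(items):
            target_end = items[i + 1][0].start_date - _DAY
            if p.end_date != target_end:
                audit.changes.append(
                    ChangeLogEntry(p.member_id, p.record_seq, "end_date",
                                   p.end_date, target_end,
                                   "align end with successor start (start-date primacy)")
                )
                p.end_date = target_end
                p.end_adjusted = True
        if p.end_date < p.start_date:
            audit.drops.append(
                DropLogEntry(p.member_id, p.record_seq, "zero-length after overlap resolution")
            )
            continue
        periods.append(p)
    for idx, p in enumerate(periods):
        p.period_index = idx
    return periods, audit


# ---------------------------------------------------------------------------
# step 4: invalid-geocode subsumption

def subsume_invalid_geocodes(
    periods: Sequence[AddressPeriod],
    stages: Sequence[LifeStage],
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION,
) -> tuple[list[AddressPeriod], dict[str, str], CleaningAudit]:
    """Absorb unusably geocoded periods into their valid successors.

    A period lacking a usable geocode is subsumed — the following period's
    start moves back over it — only when (a) the immediately following
    period has a usable geocode and (b) the invalid period overlaps no life
    stage by more than ``max_overlap_fraction`` of that stage's days (ties
    at the threshold are allowed).  Retained invalid periods mark every
    stage they touch as unreliable.

    Chains of consecutive invalid periods are resolved innermost-first: the
    invalid period next to a valid one is absorbed, then its predecessor
    becomes eligible in turn (still subject to its own overlap test).  The
    result is a fixpoint, so re-cleaning a cleaned history changes nothing.

    Returns the new period list, a stage -> reason map for unreliable
    stages, and an audit fragment.
    """
    out = list(periods)
    audit = CleaningAudit()
    changed = True
    while changed:
        changed = False
        for i, p in enumerate(out):
            if p.usable_geocode:
                continue
            nxt = out[i + 1] if i + 1 < len(out) else None
            if nxt is None or not nxt.usable_geocode:
                continue
            if any(
                s.overlap_days(p.start_date, p.end_date) > max_overlap_fraction * s.n_days
                for s in stages
            ):
                continue
            audit.changes.append(
                ChangeLogEntry(nxt.member_id, nxt.record_seq, "start_date",
                               nxt.start_date, p.start_date,
                               "subsume preceding invalid-geocode period")
            )
            nxt.start_date = p.start_date
            nxt.subsumed_predecessor = True
            audit.drops.append(
                DropLogEntry(p.member_id, p.record_seq, "subsumed by following valid period")
            )
            audit.n_subsumed += 1
            del out[i]
            changed = True
            break
    unreliable: dict[str, str] = {}
    for p in out:
        if p.usable_geocode:
            continue
        for s in stages:
            if s.overlap_days(p.start_date, p.end_date) > 0 and s.name not in unreliable:
                unreliable[s.name] = (
                    f"invalid-geocode period [{p.start_date}..{p.end_date}] retained"
                )
    for idx, p in enumerate(out):
        p.period_index = idx
    return out, unreliable, audit


# ---------------------------------------------------------------------------
# step 5: coverage validation

@dataclass
class HistoryValidation:
    """Coverage report of a cleaned history against a member's window."""

    member_id: str
    window_start: date
    window_end: date
    uncovered: list[tuple[date, date]]

    @property
    def fully_covered(self) -> bool:
        return not self.uncovered

    @property
    def n_uncovered_days(self) -> int:
        return sum((e - s).days + 1 for s, e in self.uncovered)


def validate_history(
    periods: Sequence[AddressPeriod], window: tuple[date, date], member_id: str = "?"
) -> HistoryValidation:
    """Check that every day of [window] maps to exactly one period.

    Internal contiguity is guaranteed by construction after
    :func:`resolve_gaps_overlaps`; what can still fail is coverage at the
    edges — days before the first period's start or after the last period's
    end — which this report enumerates.
    """
    lo, hi = window
    uncovered: list[tuple[date, date]] = []
    if not periods:
        uncovered.append((lo, hi))
    else:
        first, last = periods[0], periods[-1]
        for p, q in zip(periods, periods[1:]):
            if q.start_date != p.end_date + _DAY:  # pragma: no cover - defensive
                raise ValueError(f"member {member_id!r}: history not contiguous")
        if first.start_date > lo:
            uncovered.append((lo, min(hi, first.start_date - _DAY)))
        if last.end_date < hi:
            uncovered.append((max(lo, last.end_date + _DAY), hi))
    return HistoryValidation(member_id, lo, hi, uncovered)


# ---------------------------------------------------------------------------
# per-member and cohort drivers

@dataclass
class CleanedHistory:
    member_id: str
    periods: list[AddressPeriod]
    unreliable_stages: dict[str, str]
    audit: CleaningAudit
    no_address_data: bool = False

    def location_on(self, day: date) -> str | None:
        for p in self.periods:
            if day in p:
                return p.location_id
        return None


def clean_member_history(
    records: Iterable[RawAddressRecord],
    member: StudyMember,
    current_date: date,
    stages: Sequence[LifeStage] | None = None,
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION,
) -> CleanedHistory:
    """Run the full cleaning pipeline for one member.

    ``stages`` defaults to the member's tiling stages plus the pregnancy
    window; they drive the subsumption overlap test and reliability marking.
    The validation window is [DoC, last stage end].
    """
    doc = conception_date(member.date_of_birth, member.gestation_weeks, member.member_id)
    if stages is None:
        stages = list(build_life_stages(member)) + [pregnancy_window(member)]
    audit = CleaningAudit()
    imputed: list[_Imputed] = []
    for rec in records:
        new, (s_imp, e_imp), frag = impute_missing_dates(rec, doc, current_date)
        audit.extend(frag)
        if new is not None:
            imputed.append((new, s_imp, e_imp))
    if not imputed:
        return CleanedHistory(member.member_id, [], {s.name: "no address data" for s in stages},
                              audit, no_address_data=True)
    ordered, frag = order_periods(imputed)
    audit.extend(frag)
    periods, frag = resolve_gaps_overlaps(ordered)
    audit.extend(frag)
    periods, unreliable, frag = subsume_invalid_geocodes(periods, stages, max_overlap_fraction)
    audit.extend(frag)
    window = (min(s.start_date for s in stages), max(s.end_date for s in stages))
    report = validate_history(periods, window, member.member_id)
    for s, e in report.uncovered:
        for stage in stages:
            if stage.overlap_days(s, e) > 0 and stage.name not in unreliable:
                unreliable[stage.name] = f"history does not cover [{s}..{e}]"
    audit.n_periods_out += len(periods)
    for p in periods:
        if p.n_dates_changed >= 1:
            audit.n_with_any_date_changed += 1
        if p.n_dates_changed > 1:
            audit.n_with_more_than_one_date_changed += 1
    return CleanedHistory(member.member_id, periods, unreliable, audit)


@dataclass
class CohortCleaningResult:
    periods: pd.DataFrame
    reliability: pd.DataFrame
    audit: CleaningAudit
    histories: dict[str, CleanedHistory]


def records_from_frame(frame: pd.DataFrame) -> dict[str, list[RawAddressRecord]]:
    """Group a contact-records table into per-member RawAddressRecord lists."""

    def _to_date(v):
        if v is None or pd.isna(v):
            return None
        return v.date() if isinstance(v, pd.Timestamp) else v

    by_member: dict[str, list[RawAddressRecord]] = {}
    for row in frame.itertuples(index=False):
        loc = None if (row.location_id is None or pd.isna(row.location_id)) else str(row.location_id)
        rec = RawAddressRecord(
            member_id=str(row.member_id),
            record_seq=int(row.record_seq),
            location_id=loc,
            start_date=_to_date(row.start_date),
            end_date=_to_date(row.end_date),
            geocode_valid=bool(row.geocode_valid),
            in_study_area=bool(row.in_study_area),
        )
        by_member.setdefault(rec.member_id, []).append(rec)
    return by_member


def periods_to_frame(histories: Mapping[str, CleanedHistory]) -> pd.DataFrame:
    rows = []
    for h in histories.values():
        for p in h.periods:
            rows.append(
                (p.member_id, p.period_index, p.location_id, p.start_date, p.end_date,
                 p.start_imputed, p.end_imputed, p.end_adjusted, p.subsumed_predecessor,
                 p.usable_geocode, p.n_dates_changed, p.record_seq)
            )
    out = pd.DataFrame(
        rows,
        columns=["member_id", "period_index", "location_id", "start_date", "end_date",
                 "start_imputed", "end_imputed", "end_adjusted", "subsumed_predecessor",
                 "usable_geocode", "n_dates_changed", "record_seq"],
    )
    if len(out):
        out["start_date"] = pd.to_datetime(out["start_date"])
        out["end_date"] = pd.to_datetime(out["end_date"])
    return out


def clean_cohort(
    contact_records: pd.DataFrame,
    members: Sequence[StudyMember],
    current_date: date,
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION,
) -> CohortCleaningResult:
    """Clean every member's records; return cohort tables plus the audit.

    ``reliability`` has one row per member x emitted stage with a boolean
    ``reliable`` and, where false, the reason.  Members without any address
    record are flagged with reason "no address data" for every stage.
    """
    by_member = records_from_frame(contact_records)
    audit = CleaningAudit()
    histories: dict[str, CleanedHistory] = {}
    rel_rows = []
    for m in members:
        stages = list(build_life_stages(m)) + [pregnancy_window(m)]
        recs = by_member.get(m.member_id, [])
        h = clean_member_history(recs, m, current_date, stages, max_overlap_fraction)
        histories[m.member_id] = h
        audit.extend(h.audit)
        for s in stages:
            reason = h.unreliable_stages.get(s.name)
            rel_rows.append((m.member_id, s.name, reason is None, reason))
    reliability = pd.DataFrame(
        rel_rows, columns=["member_id", "stage_name", "reliable", "reason"]
    )
    return CohortCleaningResult(periods_to_frame(histories), reliability, audit, histories)
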
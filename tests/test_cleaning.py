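"""Address-record cleaning: imputation, ordering, contiguity, subsumption."""

from datetime import date, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from addrexp import (
    RawAddressRecord,
    StudyMember,
    build_life_stages,
    clean_member_history,
    impute_missing_dates,
    order_periods,
    pregnancy_window,
    resolve_gaps_overlaps,
    subsume_invalid_geocodes,
    validate_history,
)
from addrexp.cleaning import AddressPeriod
from addrexp.lifestages import LifeStage

DOC = date(1990, 9, 7)
NOW = date(1994, 1, 1)


def rec(seq, start, end, loc="A", member="m1", **kw):
    return RawAddressRecord(member, seq, loc, start, end, **kw)


def day(n):
    """Day n of an arbitrary fixed calendar (day 1 = 1991-01-01)."""
    return date(1991, 1, 1) + timedelta(days=n - 1)


# ---------------------------------------------------------------------------
# imputation

def test_missing_start_imputed_with_conception_date():
    r, (s_imp, e_imp), audit = impute_missing_dates(
        rec(1, None, date(1991, 5, 1)), DOC, NOW
    )
    assert r.start_date == DOC and s_imp and not e_imp
    assert audit.changes[0].rule == "impute missing start with DoC"


def test_missing_end_imputed_with_current_date():
    r, (s_imp, e_imp), _ = impute_missing_dates(
        rec(1, date(1991, 1, 1), None), DOC, NOW
    )
    assert r.end_date == NOW and e_imp and not s_imp


def test_complete_record_untouched():
    orig = rec(1, date(1991, 1, 1), date(1991, 2, 1))
    r, flags, audit = impute_missing_dates(orig, DOC, NOW)
    assert r == orig and flags == (False, False) and not audit.changes


def test_fully_empty_record_dropped():
    r, _, audit = impute_missing_dates(
        RawAddressRecord("m1", 1, None, None, None), DOC, NOW
    )
    assert r is None
    assert audit.drops[0].reason == "empty record"


# ---------------------------------------------------------------------------
# ordering / correction semantics

def _imputed(records):
    out = []
    for r in records:
        new, (s, e), _ = impute_missing_dates(r, DOC, NOW)
        out.append((new, s, e))
    return out


def test_identical_start_keeps_newest_entry_only():
    a = rec(3, day(1), day(10), loc="OLD")
    b = rec(7, day(1), day(20), loc="NEW")
    kept, audit = order_periods(_imputed([a, b]))
    assert [k[0].record_seq for k in kept] == [7]
    assert audit.drops[0].reason == "superseded duplicate start"
    assert audit.drops[0].record_seq == 3


def test_records_reordered_by_start_date():
    a = rec(1, day(50), day(60))
    b = rec(2, day(1), day(49))
    kept, _ = order_periods(_imputed([a, b]))
    assert [k[0].record_seq for k in kept] == [2, 1]


def test_member_without_records_flagged(member_term):
    h = clean_member_history([], member_term, NOW)
    assert h.no_address_data
    assert all("no address data" in v for v in h.unreliable_stages.values())


# ---------------------------------------------------------------------------
# gap / overlap resolution (start-date primacy)

@pytest.mark.parametrize(
    "a_end, expected_a_end, adjusted",
    [
        (day(8), day(10), True),  # gap: days 9-10 missing, end extended forward
        (day(12), day(10), True),  # overlap: day 11-12 double-booked, end pulled back
        (day(10), day(10), False),  # contiguous: untouched
    ],
)
def test_gap_and_overlap_resolved_by_adjusting_earlier_end(a_end, expected_a_end, adjusted):
    a = rec(1, day(1), a_end, loc="A")
    b = rec(2, day(11), day(20), loc="B")
    periods, audit = resolve_gaps_overlaps(_imputed([a, b]))
    assert periods[0].end_date == expected_a_end
    assert periods[0].end_adjusted is adjusted
    assert (periods[1].start_date, periods[1].end_date) == (day(11), day(20))
    assert periods[1].end_adjusted is False
    assert len(audit.changes) == (1 if adjusted else 0)


def test_final_period_end_never_altered():
    a = rec(1, day(1), day(5))
    b = rec(2, day(11), day(999))
    periods, _ = resolve_gaps_overlaps(_imputed([a, b]))
    assert periods[-1].end_date == day(999)


# ---------------------------------------------------------------------------
# invalid-geocode subsumption

T1 = LifeStage("T1", day(1), day(93))  # 93-day stage


def period(i, start, end, loc="A", usable=True):
    return AddressPeriod("m1", i, loc, start, end, usable_geocode=usable)


def test_subsumable_invalid_period_absorbed_by_follower():
    ps = [period(0, day(5), day(9), loc="X", usable=False),
          period(1, day(10), day(20), loc="B")]
    out, unreliable, audit = subsume_invalid_geocodes(ps, [T1])
    assert len(out) == 1
    assert (out[0].start_date, out[0].end_date, out[0].location_id) == (day(5), day(20), "B")
    assert out[0].subsumed_predecessor
    assert audit.n_subsumed == 1 and not unreliable


def test_invalid_period_over_threshold_retained_and_stage_unreliable():
    stage = LifeStage("T1", day(1), day(100))  # 100 days
    ps = [period(0, day(1), day(30), loc="X", usable=False),  # 30% > 25%
          period(1, day(31), day(200), loc="B")]
    out, unreliable, _ = subsume_invalid_geocodes(ps, [stage])
    assert len(out) == 2
    assert "T1" in unreliable


def test_overlap_exactly_at_threshold_is_subsumable():
    stage = LifeStage("T1", day(1), day(100))
    ps = [period(0, day(1), day(25), loc="X", usable=False),  # exactly 25%
          period(1, day(26), day(200), loc="B")]
    out, unreliable, _ = subsume_invalid_geocodes(ps, [stage])
    assert len(out) == 1 and not unreliable


def test_no_invalid_periods_is_a_noop():
    ps = [period(0, day(1), day(10)), period(1, day(11), day(20), loc="B")]
    out, unreliable, audit = subsume_invalid_geocodes(ps, [T1])
    assert [(p.start_date, p.end_date) for p in out] == [(day(1), day(10)), (day(11), day(20))]
    assert not unreliable and not audit.changes


def test_trailing_invalid_period_retained():
    ps = [period(0, day(1), day(10)), period(1, day(11), day(20), loc="X", usable=False)]
    out, unreliable, _ = subsume_invalid_geocodes(ps, [T1])
    assert len(out) == 2 and "T1" in unreliable


def test_chain_of_invalid_periods_resolved_innermost_first():
    ps = [period(0, day(1), day(4), loc="X", usable=False),
          period(1, day(5), day(9), loc="Y", usable=False),
          period(2, day(10), day(120), loc="B")]
    out, unreliable, audit = subsume_invalid_geocodes(ps, [T1])
    assert len(out) == 1 and out[0].start_date == day(1) and not unreliable
    assert audit.n_subsumed == 2


# ---------------------------------------------------------------------------
# coverage validation

def test_full_coverage_reports_nothing():
    ps = [period(0, day(1), day(400))]
    report = validate_history(ps, (day(1), day(365)))
    assert report.fully_covered


def test_late_first_start_reports_uncovered_days():
    ps = [period(0, day(11), day(400))]
    report = validate_history(ps, (day(1), day(365)))
    assert report.uncovered == [(day(1), day(10))]
    assert report.n_uncovered_days == 10


# ---------------------------------------------------------------------------
# whole-member pipeline properties

def _as_records(periods, member="m1"):
    return [
        RawAddressRecord(member, i + 1, p.location_id, p.start_date, p.end_date)
        for i, p in enumerate(periods)
    ]


def test_cleaning_is_idempotent(member_term):
    raw = [
        rec(1, None, date(1991, 2, 1), loc="A", member="m-term"),
        rec(2, date(1991, 3, 1), None, loc="B", member="m-term"),
        rec(3, date(1991, 3, 1), date(1992, 12, 31), loc="B2", member="m-term"),
    ]
    h1 = clean_member_history(raw, member_term, NOW)
    h2 = clean_member_history(_as_records(h1.periods, "m-term"), member_term, NOW)
    assert [(p.location_id, p.start_date, p.end_date) for p in h1.periods] == [
        (p.location_id, p.start_date, p.end_date) for p in h2.periods
    ]


@given(
    starts=st.lists(st.integers(0, 600), min_size=1, max_size=6, unique=True),
    end_offsets=st.lists(st.one_of(st.none(), st.integers(-30, 400)), min_size=6, max_size=6),
)
def test_start_date_primacy_and_one_location_per_day(starts, end_offsets, member_term):
    """Cleaned starts equal raw starts; each covered day has exactly one location."""
    doc = member_term.conception
    raw = []
    for i, s in enumerate(sorted(starts)):
        start = doc + timedelta(days=s)
        off = end_offsets[i]
        end = None if off is None else start + timedelta(days=off)
        raw.append(RawAddressRecord("m-term", i + 1, f"L{i}", start, end))
    h = clean_member_history(raw, member_term, NOW)
    raw_starts = {r.start_date for r in raw}
    for p in h.periods:
        assert p.start_date in raw_starts  # never invented, never moved
        assert p.start_date <= p.end_date
    for a, b in zip(h.periods, h.periods[1:]):
        assert b.start_date == a.end_date + timedelta(days=1)  # exactly one location per day


def test_history_coverage_shortfall_marks_stages_unreliable(member_term):
    # first period starts mid-T2: T1, T2 and P lack coverage
    raw = [rec(1, date(1991, 1, 15), None, member="m-term")]
    h = clean_member_history(raw, member_term, NOW)
    assert {"T1", "T2", "P"} <= set(h.unreliable_stages)
    assert "LI" not in h.unreliable_stages
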
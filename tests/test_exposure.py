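"""Daily exposure assignment and life-stage aggregation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from addrexp import ExposureSurface, SurfaceLookupError
from addrexp.exposure import (
    aggregate_life_stage,
    assign_daily_exposure,
    daily_location_series,
    summarize_cohort,
)


def frame(rows, cols):
    f = pd.DataFrame(rows, columns=cols)
    for c in ("start_date", "end_date", "date"):
        if c in f.columns:
            f[c] = pd.to_datetime(f[c])
    return f


def periods_frame(rows):
    return frame(rows, ["member_id", "period_index", "location_id", "start_date", "end_date"])


def stages_frame(rows):
    f = frame(rows, ["member_id", "stage_name", "start_date", "end_date"])
    f["n_days"] = (f.end_date - f.start_date).dt.days + 1
    return f


def surface_from(rows):
    return ExposureSurface(frame(rows, ["location_id", "date", "value"]))


STAGES = stages_frame([("m1", "T1", "1991-01-01", "1991-01-03")])


def test_single_period_covers_every_stage_day():
    per = periods_frame([("m1", 0, "A", "1990-01-01", "1995-01-01")])
    series = daily_location_series(per, STAGES)
    assert len(series) == 3
    assert (series.location_id == "A").all()
    assert list(series.stage_name.unique()) == ["T1"]


def test_move_day_boundary_splits_locations():
    per = periods_frame([
        ("m1", 0, "A", "1990-01-01", "1991-01-01"),
        ("m1", 1, "B", "1991-01-02", "1995-01-01"),
    ])
    series = daily_location_series(per, STAGES).set_index("date")
    assert series.loc["1991-01-01", "location_id"] == "A"
    assert series.loc["1991-01-02", "location_id"] == "B"
    assert series.loc["1991-01-03", "location_id"] == "B"


def test_uncovered_day_gets_null_location():
    per = periods_frame([("m1", 0, "A", "1991-01-02", "1991-01-02")])
    series = daily_location_series(per, STAGES)
    assert series.location_id.isna().sum() == 2  # Jan 1 (before) and Jan 3 (after)


def test_premature_member_has_no_t3_rows(member_preterm):
    from addrexp.lifestages import build_stage_table

    stages = build_stage_table([member_preterm])
    per = periods_frame([("m-preterm", 0, "A", "1990-01-01", "1995-01-01")])
    series = daily_location_series(per, stages)
    assert "T3" not in set(series.stage_name)


def test_surface_lookup_joins_daily_values():
    per = periods_frame([
        ("m1", 0, "A", "1990-01-01", "1991-01-02"),
        ("m1", 1, "B", "1991-01-03", "1995-01-01"),
    ])
    surf = surface_from([
        ("A", "1991-01-01", 10.0), ("A", "1991-01-02", 20.0), ("B", "1991-01-03", 30.0),
    ])
    daily = assign_daily_exposure(daily_location_series(per, STAGES), surf)
    assert list(daily.value) == [10.0, 20.0, 30.0]
    assert (daily.quality == "valid").all()


def test_missing_surface_fail_policy_names_the_key():
    per = periods_frame([("m1", 0, "A", "1990-01-01", "1995-01-01")])
    surf = surface_from([("A", "1991-01-01", 10.0), ("A", "1991-01-03", 30.0)])
    with pytest.raises(SurfaceLookupError, match="1991-01-02"):
        assign_daily_exposure(daily_location_series(per, STAGES), surf)


def test_missing_surface_flag_day_policy_counts_and_excludes():
    per = periods_frame([("m1", 0, "A", "1990-01-01", "1995-01-01")])
    surf = surface_from([("A", "1991-01-01", 10.0), ("A", "1991-01-03", 30.0)])
    daily = assign_daily_exposure(daily_location_series(per, STAGES), surf, "flag_day")
    assert (daily.quality == "missing_surface").sum() == 1
    summ = aggregate_life_stage(daily, STAGES)
    row = summ.iloc[0]
    assert row.n_days == 3 and row.n_valid_days == 2
    assert row["mean"] == 20.0 and row.cumulative == 40.0


def _summary_of(values, stage_days=None):
    n = len(values)
    stages = stages_frame([("m1", "T1", "1991-01-01",
                            (pd.Timestamp("1991-01-01") + pd.Timedelta(days=n - 1)).date())])
    daily = pd.DataFrame({
        "member_id": "m1",
        "stage_name": "T1",
        "date": pd.date_range("1991-01-01", periods=n),
        "location_id": "A",
        "value": values,
        "quality": "valid",
    })
    return aggregate_life_stage(daily, stages).iloc[0]


def test_aggregate_mean_median_cumulative():
    row = _summary_of([10.0, 20.0, 30.0])
    assert (row["mean"], row["median"], row["cumulative"]) == (20.0, 20.0, 60.0)


def test_even_count_median_is_central_midpoint():
    assert _summary_of([1.0, 2.0, 3.0, 100.0])["median"] == 2.5


def test_constant_series_aggregates():
    row = _summary_of([7.5] * 10)
    assert row["mean"] == row["median"] == 7.5
    assert row["cumulative"] == 75.0


def test_zero_valid_days_nulls_aggregates():
    stages = stages_frame([("m1", "T1", "1991-01-01", "1991-01-03")])
    daily = pd.DataFrame({
        "member_id": ["m1"] * 3, "stage_name": "T1",
        "date": pd.date_range("1991-01-01", periods=3),
        "location_id": None, "value": np.nan, "quality": "unreliable_stage",
    })
    row = aggregate_life_stage(daily, stages).iloc[0]
    assert not row.reliable and np.isnan(row["mean"]) and row.reason


def test_unreliable_stage_forces_null_aggregates():
    reliability = pd.DataFrame(
        [("m1", "T1", False, "invalid geocode")],
        columns=["member_id", "stage_name", "reliable", "reason"],
    )
    stages = stages_frame([("m1", "T1", "1991-01-01", "1991-01-03")])
    daily = pd.DataFrame({
        "member_id": ["m1"] * 3, "stage_name": "T1",
        "date": pd.date_range("1991-01-01", periods=3),
        "location_id": "A", "value": [1.0, 2.0, 3.0], "quality": "valid",
    })
    row = aggregate_life_stage(daily, stages, reliability).iloc[0]
    assert not row.reliable and np.isnan(row["cumulative"])


@given(values=st.lists(st.floats(0, 500, allow_nan=False, width=32), min_size=1, max_size=40))
def test_aggregation_identities(values):
    """cumulative = mean x n_valid_days; mean and median inside [min, max]."""
    row = _summary_of([float(v) for v in values])
    assert row["cumulative"] == pytest.approx(row["mean"] * row["n_valid_days"], rel=1e-9)
    assert min(values) <= row["mean"] <= max(values)
    assert min(values) <= row["median"] <= max(values)


@given(shift=st.floats(0, 50, allow_nan=False))
def test_shift_equivariance_of_aggregates(shift):
    """Adding k to every surface value adds k to means/medians, k*n to cumulative."""
    base = [10.0, 20.0, 35.0, 41.0]
    a = _summary_of(base)
    b = _summary_of([v + shift for v in base])
    assert b["mean"] == pytest.approx(a["mean"] + shift, rel=1e-12)
    assert b["median"] == pytest.approx(a["median"] + shift, rel=1e-12)
    assert b["cumulative"] == pytest.approx(a["cumulative"] + shift * 4, rel=1e-12)


# ---------------------------------------------------------------------------
# two-method machinery

def _two_method_setup(move_mid_t2=False):
    from addrexp.lifestages import build_stage_table
    from addrexp import StudyMember

    member = StudyMember("m1", date(1991, 6, 15), 40)
    stages = build_stage_table([member])
    members_df = pd.DataFrame({
        "member_id": ["m1"],
        "date_of_birth": pd.to_datetime([date(1991, 6, 15)]),
        "gestation_weeks": [40],
    })
    if move_mid_t2:
        per = periods_frame([
            ("m1", 0, "A", "1990-01-01", "1991-01-20"),
            ("m1", 1, "B", "1991-01-21", "1995-01-01"),
        ])
    else:
        per = periods_frame([("m1", 0, "A", "1990-01-01", "1995-01-01")])
    dates = pd.date_range("1990-01-01", "1995-01-01")
    surf = ExposureSurface(pd.DataFrame({
        "location_id": np.repeat(["A", "B"], len(dates)),
        "date": np.tile(dates, 2),
        "value": np.concatenate([np.full(len(dates), 10.0), np.full(len(dates), 30.0)]),
    }))
    return per, stages, members_df, surf


def test_non_mover_methods_are_identical():
    per, stages, members_df, surf = _two_method_setup()
    summ = summarize_cohort(per, stages, members_df, surf)
    wide = summ.pivot_table(index="stage_name", columns="method",
                            values=["mean", "median", "cumulative"], aggfunc="first")
    for stat in ("mean", "median", "cumulative"):
        assert (wide[stat]["mobility"] == wide[stat]["birth_address"]).all()


def test_mid_t2_mover_birth_address_overstates_t2():
    per, stages, members_df, surf = _two_method_setup(move_mid_t2=True)
    summ = summarize_cohort(per, stages, members_df, surf).set_index(["method", "stage_name"])
    mob_t2 = summ.loc[("mobility", "T2"), "mean"]
    birth_t2 = summ.loc[("birth_address", "T2"), "mean"]
    assert 10.0 < mob_t2 < 30.0
    assert birth_t2 == 30.0  # birth address B for every day
    # T1 precedes the move entirely: mobility says A, birth address says B
    assert summ.loc[("mobility", "T1"), "mean"] == 10.0
    assert summ.loc[("birth_address", "T1"), "mean"] == 30.0


def test_negative_surface_values_rejected():
    with pytest.raises(ValueError, match="negative"):
        surface_from([("A", "1991-01-01", -1.0)])
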
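"""Daily exposure assignment and per-life-stage aggregation.

Given a cleaned residential history, a stage table, and a daily exposure
surface (one concentration per location per day, e.g. modelled PM10 in
ug/m3), this module places each member at exactly one location on each day of
each life stage, joins the surface, and aggregates the dailies into
mean / median / cumulative summaries per member x stage.

Two assignment methods are produced with identical machinery:

* ``mobility`` — each day's location comes from the cleaned history, so
  residential moves are honoured;
* ``birth_address`` — the location occupied on the day of birth (in the
  cleaned history) is used for *every* day of every stage, the convention
  common in epidemiological studies that this tool quantifies against.

Stages marked unreliable during cleaning, and stages with no valid daily
value, are emitted with null aggregates rather than silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSurface",
    "SurfaceLookupError",
    "daily_location_series",
    "assign_daily_exposure",
    "aggregate_life_stage",
    "summarize_cohort",
    "birth_address_locations",
]

QUALITY_VALID = "valid"
QUALITY_MISSING_SURFACE = "missing_surface"
QUALITY_UNRELIABLE = "unreliable_stage"


class SurfaceLookupError(KeyError):
    """A (location, date) key required for assignment is absent from the surface."""


class ExposureSurface:
    """Daily concentration per location, with a declared coverage window.

    Wraps a long-format frame (location_id, date, value).  Values must be
    non-negative; a lookup outside the surface is a detectable miss, never a
    silent zero.
    """

    def __init__(self, frame: pd.DataFrame, first_date: date | None = None,
                 last_date: date | None = None):
        required = {"location_id", "date", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"surface frame missing columns: {sorted(missing)}")
        f = frame.loc[:, ["location_id", "date", "value"]].copy()
        f["location_id"] = f["location_id"].astype(str)
        f["date"] = pd.to_datetime(f["date"])
        f["value"] = f["value"].astype(float)
        if (f["value"] < 0).any():
            bad = f.loc[f["value"] < 0].iloc[0]
            raise ValueError(
                f"negative concentration {bad['value']} at "
                f"({bad['location_id']}, {bad['date'].date()})"
            )
        if f.duplicated(["location_id", "date"]).any():
            raise ValueError("duplicate (location_id, date) keys in surface")
        self.frame = f
        self.first_date = pd.Timestamp(first_date) if first_date else f["date"].min()
        self.last_date = pd.Timestamp(last_date) if last_date else f["date"].max()

    def lookup(self, location_id: str, day: date) -> float:
        sel = self.frame[
            (self.frame["location_id"] == str(location_id))
            & (self.frame["date"] == pd.Timestamp(day))
        ]
        if sel.empty:
            raise SurfaceLookupError((location_id, day))
        return float(sel["value"].iloc[0])


def _explode_stage_days(stages: pd.DataFrame) -> pd.DataFrame:
    """One row per (member, stage, day) for every day of every stage."""
    if stages.empty:
        return pd.DataFrame(columns=["member_id", "stage_name", "date"])
    start = stages["start_date"].to_numpy(dtype="datetime64[D]")
    end = stages["end_date"].to_numpy(dtype="datetime64[D]")
    n = (end - start).astype(int) + 1
    offsets = np.concatenate([np.arange(k) for k in n])
    return pd.DataFrame(
        {
            "member_id": np.repeat(stages["member_id"].to_numpy(), n),
            "stage_name": np.repeat(stages["stage_name"].to_numpy(), n),
            "date": pd.to_datetime(
                (np.repeat(start, n) + offsets.astype("timedelta64[D]")).astype("datetime64[ns]")
            ),
        }
    )


def daily_location_series(periods: pd.DataFrame, stages: pd.DataFrame) -> pd.DataFrame:
    """Expand stages to days and attach the covering address period's location.

    Returns one row per (member, stage, day) with columns member_id,
    stage_name, date, location_id; a day not covered by the cleaned history
    gets a null location (its stage is unreliable and is nulled downstream).
    Because the whole-pregnancy stage P overlaps the trimesters, a calendar
    day may appear once per stage that contains it.
    """
    days = _explode_stage_days(stages)
    if days.empty:
        days["location_id"] = pd.Series(dtype=object)
        return days
    per = periods.loc[:, ["member_id", "start_date", "end_date", "location_id"]].copy()
    per["start_date"] = pd.to_datetime(per["start_date"]).astype("datetime64[ns]")
    per["end_date"] = pd.to_datetime(per["end_date"]).astype("datetime64[ns]")
    left = days.sort_values("date", kind="stable").reset_index(drop=True)
    right = per.sort_values("start_date", kind="stable").reset_index(drop=True)
    merged = pd.merge_asof(
        left, right, left_on="date", right_on="start_date",
        by="member_id", direction="backward",
    )
    outside = merged["end_date"].isna() | (merged["date"] > merged["end_date"])
    merged.loc[outside, "location_id"] = None
    out = merged[["member_id", "stage_name", "date", "location_id"]]
    return out.sort_values(["member_id", "stage_name", "date"], kind="stable").reset_index(drop=True)


def assign_daily_exposure(
    series: pd.DataFrame,
    surface: ExposureSurface,
    missing_policy: str = "fail",
) -> pd.DataFrame:
    """Join the daily location series to the exposure surface.

    ``missing_policy``:

    * ``"fail"`` (default) — raise :class:`SurfaceLookupError` naming the
      first offending (location, date) keys; silent gaps would corrupt
      cumulative sums.
    * ``"flag_day"`` — mark the day ``missing_surface``; it is excluded from
      aggregates and counted.

    Days with a null location (history coverage gap) are marked
    ``unreliable_stage`` regardless of policy.
    """
    if missing_policy not in ("fail", "flag_day"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out = series.merge(surface.frame, on=["location_id", "date"], how="left")
    no_loc = out["location_id"].isna()
    miss = out["value"].isna() & ~no_loc
    if miss.any() and missing_policy == "fail":
        bad = out.loc[miss, ["location_id", "date"]].head(5)
        keys = [(r.location_id, str(r.date.date())) for r in bad.itertuples(index=False)]
        raise SurfaceLookupError(
            f"{int(miss.sum())} member-days have no surface value; first offenders: {keys}"
        )
    out["quality"] = QUALITY_VALID
    out.loc[miss, "quality"] = QUALITY_MISSING_SURFACE
    out.loc[no_loc, "quality"] = QUALITY_UNRELIABLE
    return out


def aggregate_life_stage(
    daily: pd.DataFrame,
    stages: pd.DataFrame,
    reliability: pd.DataFrame | None = None,
    method: str = "mobility",
) -> pd.DataFrame:
    """Aggregate daily records into one summary row per member x stage.

    mean / median / cumulative are computed over days with quality
    ``valid``; the median of an even count is the midpoint of the two
    central order statistics.  A stage flagged unreliable during cleaning,
    or with zero valid days, carries null aggregates and ``reliable=False``.
    """
    valid = daily[daily["quality"] == QUALITY_VALID]
    agg = (
        valid.groupby(["member_id", "stage_name"])["value"]
        .agg(n_valid_days="count", mean="mean", median="median", cumulative="sum")
        .reset_index()
    )
    out = stages[["member_id", "stage_name", "n_days"]].merge(
        agg, on=["member_id", "stage_name"], how="left"
    )
    out["n_valid_days"] = out["n_valid_days"].fillna(0).astype(int)
    if reliability is not None:
        out = out.merge(
            reliability[["member_id", "stage_name", "reliable", "reason"]],
            on=["member_id", "stage_name"], how="left",
        )
        out["reliable"] = out["reliable"].fillna(True).astype(bool)
    else:
        out["reliable"] = True
        out["reason"] = None
    no_valid = out["n_valid_days"] == 0
    out.loc[no_valid & out["reliable"], "reason"] = "no valid daily exposure values"
    out.loc[no_valid, "reliable"] = False
    nulled = ~out["reliable"]
    out.loc[nulled, ["mean", "median", "cumulative"]] = np.nan
    out["method"] = method
    cols = ["member_id", "stage_name", "method", "n_days", "n_valid_days",
            "mean", "median", "cumulative", "reliable", "reason"]
    return out[cols]


def birth_address_locations(
    periods: pd.DataFrame, members: pd.DataFrame
) -> tuple[pd.Series, list[str]]:
    """Location occupied on the day of birth, per member, from the cleaned history.

    Returns (member_id -> location_id Series, members whose history does not
    cover the day of birth — excluded from the method comparison).
    """
    m = members[["member_id", "date_of_birth"]].copy()
    m["date_of_birth"] = pd.to_datetime(m["date_of_birth"])
    j = m.merge(periods, on="member_id", how="left")
    at_birth = j[
        (j["start_date"] <= j["date_of_birth"]) & (j["date_of_birth"] <= j["end_date"])
    ]
    locs = at_birth.set_index("member_id")["location_id"]
    excluded = sorted(set(m["member_id"]) - set(locs.index))
    return locs, excluded


def summarize_cohort(
    periods: pd.DataFrame,
    stages: pd.DataFrame,
    members: pd.DataFrame,
    surface: ExposureSurface,
    reliability: pd.DataFrame | None = None,
    missing_policy: str = "fail",
    return_daily: bool = False,
):
    """Run both assignment methods end to end for a cohort.

    Returns a summary frame with ``method`` in {mobility, birth_address}
    (and, optionally, the two daily frames).  Members whose cleaned history
    does not cover the day of birth appear only under the mobility method.
    """
    series = daily_location_series(periods, stages)
    daily_mob = assign_daily_exposure(series, surface, missing_policy)
    mob = aggregate_life_stage(daily_mob, stages, reliability, method="mobility")

    birth_locs, excluded = birth_address_locations(periods, members)
    series_birth = series[~series["member_id"].isin(excluded)].copy()
    series_birth["location_id"] = series_birth["member_id"].map(birth_locs)
    daily_birth = assign_daily_exposure(series_birth, surface, missing_policy)
    stages_birth = stages[~stages["member_id"].isin(excluded)]
    rel_birth = None
    if reliability is not None:
        rel_birth = reliability[~reliability["member_id"].isin(excluded)]
    birth = aggregate_life_stage(daily_birth, stages_birth, rel_birth, method="birth_address")

    summaries = pd.concat([mob, birth], ignore_index=True)
    if return_daily:
        return summaries, daily_mob, daily_birth
    return summaries
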
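"""Cohort mobility statistics and birth-address vs mobility comparison.

Quantifies how much exposure estimates change when residential mobility is
ignored: per member x stage, the difference between the birth-address-only
mean and the mobility-based mean (the latter treated as the reference), and
cohort-level descriptive statistics — difference range, 5th/95th percentiles
(linear interpolation), the squared Pearson correlation (R2, equivalently the
R2 of the simple linear fit of one method on the other), and Spearman's rank
correlation with average ranks on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import AddressPeriod

__all__ = [
    "count_moves",
    "mobility_summary",
    "compare_methods",
    "MobilityStats",
    "MethodComparison",
]


def count_moves(
    periods: Sequence[AddressPeriod], window: tuple[date, date]
) -> int:
    """Number of residential moves inside a closed window.

    A move is a day d with window_start < d <= window_end on which the
    member's location differs from the day before.  A transition exactly on
    the window's first day is not counted (the change of residence precedes
    the window).  If the window extends beyond the history's coverage, the
    count runs over the covered sub-window.
    """
    if not periods:
        return 0
    start, end = window
    lo = max(start, periods[0].start_date)
    hi = min(end, periods[-1].end_date)
    n = 0
    for prev, cur in zip(periods, periods[1:]):
        d = cur.start_date  # first day at the new location
        if lo < d <= hi and cur.location_id != prev.location_id:
            n += 1
    return n


def _distinct_addresses(periods: Sequence[AddressPeriod], window: tuple[date, date]) -> int:
    start, end = window
    locs = {
        p.location_id
        for p in periods
        if p.start_date <= end and p.end_date >= start and p.location_id is not None
    }
    return len(locs)


@dataclass
class MobilityStats:
    """Per-member move indicators plus cohort-level rates."""

    per_member: pd.DataFrame
    cohort: dict

    def __getitem__(self, key: str):
        return self.cohort[key]


def mobility_summary(
    histories: dict,
    stages: pd.DataFrame,
) -> MobilityStats:
    """Cohort mobility statistics from cleaned histories.

    ``histories`` maps member_id -> CleanedHistory; ``stages`` is the cohort
    stage table.  The pregnancy window is the whole-pregnancy stage P
    (conception through delivery day); the infancy window runs from the day
    of birth (EI start) through the end of late infancy.  The denominator
    for "% moved" is members with a reliable (fully covered) history in that
    window; the move-count distribution is over members with at least one
    move anywhere in [conception, LI end].
    """
    if not histories:
        raise ValueError("empty cohort")
    sidx = stages.set_index(["member_id", "stage_name"])
    rows = []
    for mid, h in histories.items():
        if h.no_address_data:
            continue
        p_start = sidx.loc[(mid, "P"), "start_date"].date()
        p_end = sidx.loc[(mid, "P"), "end_date"].date()
        ei_start = sidx.loc[(mid, "EI"), "start_date"].date()
        li_end = sidx.loc[(mid, "LI"), "end_date"].date()
        preg = (p_start, p_end)
        inf = (ei_start, li_end)
        full = (p_start, li_end)
        n_preg = count_moves(h.periods, preg)
        n_inf = count_moves(h.periods, inf)
        n_total = count_moves(h.periods, full)
        covered = (
            bool(h.periods)
            and h.periods[0].start_date <= p_start
            and h.periods[-1].end_date >= li_end
        )
        rows.append(
            (mid, n_preg >= 1, n_inf >= 1, n_preg, n_inf, n_total,
             _distinct_addresses(h.periods, full), covered)
        )
    per_member = pd.DataFrame(
        rows,
        columns=["member_id", "moved_pregnancy", "moved_infancy", "n_moves_pregnancy",
                 "n_moves_infancy", "n_moves_total", "n_distinct_addresses", "covered"],
    )
    cov = per_member[per_member["covered"]]
    movers = cov[cov["n_moves_total"] >= 1]
    move_dist = {}
    if len(movers):
        counts = movers["n_moves_total"].value_counts().sort_index()
        move_dist = {int(k): 100.0 * v / len(movers) for k, v in counts.items()}
    cohort = {
        "n_members": len(per_member),
        "n_covered": len(cov),
        "pct_moved_pregnancy": 100.0 * cov["moved_pregnancy"].mean() if len(cov) else np.nan,
        "pct_moved_infancy": 100.0 * cov["moved_infancy"].mean() if len(cov) else np.nan,
        "pct_moved_any": 100.0 * (movers.shape[0] / len(cov)) if len(cov) else np.nan,
        "move_count_distribution_pct": move_dist,
        "mean_addresses_per_member": float(cov["n_distinct_addresses"].mean()) if len(cov) else np.nan,
    }
    return MobilityStats(per_member, cohort)


# ---------------------------------------------------------------------------
# method comparison

@dataclass
class MethodComparison:
    """Per-pair differences and per-stage cohort statistics."""

    pairs: pd.DataFrame
    by_stage: pd.DataFrame
    n_excluded_zero_reference: int


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def compare_methods(summaries: pd.DataFrame, value: str = "mean") -> MethodComparison:
    """Compare birth-address-only against mobility-based stage summaries.

    ``summaries`` is the long frame from :func:`addrexp.exposure.summarize_cohort`
    holding both methods.  Pairs are matched on (member, stage) and kept only
    when both sides are reliable.  Per pair:

        difference         = birth_address - mobility      (ug/m3)
        percent_difference = 100 * difference / mobility   (mobility = reference)

    Pairs with a zero mobility mean are excluded from percent differences and
    counted (cannot occur with strictly positive surfaces).  Per stage the
    cohort statistics are min/max and interpolated 5th/95th percentiles of
    the differences, R2 and Spearman's rho between the paired values, and the
    least-squares fit line (birth_address on mobility) for scatter plots.
    """
    rel = summaries[summaries["reliable"]]
    wide = rel.pivot_table(
        index=["member_id", "stage_name"], columns="method", values=value,
        aggfunc="first",
    ).reset_index()
    if "mobility" not in wide.columns or "birth_address" not in wide.columns:
        raise ValueError("summaries must contain both methods")
    wide = wide.dropna(subset=["mobility", "birth_address"])
    pairs = wide.rename(columns={"mobility": "mobility_value",
                                 "birth_address": "birth_address_value"})
    pairs["difference"] = pairs["birth_address_value"] - pairs["mobility_value"]
    zero_ref = pairs["mobility_value"] == 0
    n_excluded = int(zero_ref.sum())
    pairs["percent_difference"] = np.where(
        zero_ref, np.nan, 100.0 * pairs["difference"] / pairs["mobility_value"]
    )
    stage_rows = []
    for stage, g in pairs.groupby("stage_name", sort=False):
        d = g["difference"].to_numpy(float)
        x = g["mobility_value"].to_numpy(float)
        y = g["birth_address_value"].to_numpy(float)
        if len(x) >= 2 and np.std(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
        else:
            slope = intercept = np.nan
        pct = g["percent_difference"].to_numpy(float)
        pct = pct[~np.isnan(pct)]
        stage_rows.append(
            {
                "stage_name": stage,
                "n_pairs": len(g),
                "min_difference": float(d.min()),
                "max_difference": float(d.max()),
                "p5_difference": float(np.percentile(d, 5)),
                "p95_difference": float(np.percentile(d, 95)),
                "max_abs_percent_difference": float(np.max(np.abs(pct))) if len(pct) else np.nan,
                "r_squared": _r_squared(x, y),
                "spearman_rho": _spearman(x, y),
                "fit_slope": float(slope),
                "fit_intercept": float(intercept),
            }
        )
    by_stage = pd.DataFrame(stage_rows)
    return MethodComparison(pairs.reset_index(drop=True), by_stage, n_excluded)
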
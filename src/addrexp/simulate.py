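"""Synthetic cohorts, audit-style corruption, and exposure surfaces.

Real cohort contact databases and pollution surfaces are not public, so this
module generates the full study from scratch:

1. ``generate_truth`` — a ground-truth cohort: members with birth dates and
   gestational ages, plus contiguous fully-geocoded residential histories
   with per-window move probabilities (defaults: 6.7% of members move during
   pregnancy, 18.0% during infancy; movers make one/two/three moves with
   probability 95% / 4.5% / 0.5%).
2. ``corrupt_to_contact_db`` — re-encodes the truth as an audit-style
   contact-database extract: missing end dates, noisy end dates, missing
   first start dates, superseded duplicate rows posing as corrections, and
   invalid-geocode periods.  In ``strict_recoverable`` mode every corruption
   is constructed so that the cleaning protocol provably recovers the truth
   (end dates are freely corrupted because start-date primacy rebuilds them;
   the final period ends at the configured current date so end imputation is
   exact; invalid periods are only inserted where the subsumption rule can
   repair them).  ``freeform`` mode lifts those guarantees for robustness
   testing.
3. ``generate_exposure_surface`` — a daily concentration field
   value(loc, d) = max(0, B_loc + A sin(2*pi*doy/365.25) + eps) with
   lognormal per-location baselines, a shared seasonal cycle and iid daily
   noise, emulating the structure (not the physics) of a modelled urban
   PM10 field.

Every function is a pure function of (config, seed): same seed, identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .cleaning import AddressPeriod, CleanedHistory, CleaningAudit
from .lifestages import (
    LifeStage,
    StudyMember,
    build_life_stages,
    build_stage_table,
    pregnancy_window,
)

__all__ = [
    "SurfaceConfig",
    "CorruptionConfig",
    "SimulationConfig",
    "TruthBundle",
    "SimulatedStudy",
    "generate_truth",
    "corrupt_to_contact_db",
    "generate_exposure_surface",
    "simulate_study",
    "truth_histories",
    "histories_match_truth",
]

_DAY = timedelta(days=1)


@dataclass(frozen=True)
class SurfaceConfig:
    """Synthetic daily-concentration field parameters (synthetic-only defaults).

    ``baseline_log_mean``/``baseline_log_sd`` parameterise the lognormal
    per-location annual baseline in log(ug/m3); the defaults put the median
    baseline near 31 ug/m3 with ~10% between-location spread, a seasonal
    swing of +-4 ug/m3 and day-to-day noise of 3 ug/m3, loosely shaped like
    an early-1990s urban PM10 field.
    """

    n_locations: int = 150
    baseline_log_mean: float = float(np.log(31.0))
    baseline_log_sd: float = 0.10
    seasonal_amplitude: float = 4.0
    daily_noise_sd: float = 3.0


@dataclass(frozen=True)
class CorruptionConfig:
    """Rates at which the audit-style corruption is applied.

    ``end_date_noise_days`` is a magnitude: every eligible (non-final,
    non-missing) end date is shifted by a uniform integer in
    [-noise, +noise] when it is positive.  In ``strict_recoverable`` mode
    the final period's end is never perturbed and invalid-geocode periods
    are inserted only where the subsumption rule is guaranteed to repair
    them; ``strict_recoverable=False`` (freeform) lifts both guarantees.
    """

    missing_end: float = 0.5
    missing_start: float = 0.1
    end_date_noise_days: int = 10
    duplicate_rate: float = 0.2
    invalid_geocode_rate: float = 0.05
    strict_recoverable: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters.

    Move probabilities and the mover move-count distribution default to the
    rates observed in a large English birth cohort (6.7% moved during
    pregnancy, 18.0% during infancy; of movers 95% moved once, 4.5% twice,
    0.5% three times).  Gestation is drawn normal(39.5, 2) weeks, rounded
    and clamped.  ``current_date`` anchors end-date imputation and must
    postdate every member's late-infancy end.
    """

    n_members: int = 1000
    seed: int = 0
    dob_first: date = date(1991, 4, 1)
    dob_last: date = date(1992, 12, 31)
    gestation_mean: float = 39.5
    gestation_sd: float = 2.0
    gestation_clamp: tuple[int, int] = (30, 44)
    p_move_pregnancy: float = 0.067
    p_move_infancy: float = 0.18
    move_count_probs: tuple[float, ...] = (0.95, 0.045, 0.005)
    current_date: date = date(1994, 12, 31)
    corruption: CorruptionConfig = field(default_factory=CorruptionConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)

    def __post_init__(self) -> None:
        probs = (self.p_move_pregnancy, self.p_move_infancy,
                 self.corruption.missing_end, self.corruption.missing_start,
                 self.corruption.duplicate_rate, self.corruption.invalid_geocode_rate)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities and corruption rates must lie in [0, 1]")
        if abs(sum(self.move_count_probs) - 1.0) > 1e-9:
            raise ValueError("move_count_probs must sum to 1")
        lo, hi = self.gestation_clamp
        if not (20 <= lo <= hi <= 44):
            raise ValueError("gestation_clamp must lie within [20, 44]")
        if self.dob_first > self.dob_last:
            raise ValueError("dob window reversed")
        if self.current_date < self.dob_last + timedelta(days=400):
            raise ValueError("current_date must postdate every member's infancy")


@dataclass
class TruthBundle:
    """Ground truth: members, contiguous histories, and stage table."""

    members: list[StudyMember]
    members_frame: pd.DataFrame
    periods: pd.DataFrame  # member_id, period_index, location_id, start_date, end_date
    stages: pd.DataFrame
    location_pool: list[str]


@dataclass
class SimulatedStudy:
    truth: TruthBundle
    contact_records: pd.DataFrame
    surface: pd.DataFrame
    config: SimulationConfig


def _sample_days(rng: np.random.Generator, lo: date, hi: date, k: int) -> list[date]:
    """k distinct days uniform over [lo, hi]."""
    n = (hi - lo).days + 1
    k = min(k, n)
    offs = rng.choice(n, size=k, replace=False)
    return sorted(lo + timedelta(days=int(o)) for o in offs)


def generate_truth(config: SimulationConfig) -> TruthBundle:
    """Draw the ground-truth cohort and residential histories.

    Birth dates are uniform over the configured window; per member and
    window a mover flag is drawn, movers get a move count from the
    configured distribution with move days uniform inside the window
    (pregnancy: day after conception through delivery day; infancy: day
    after birth through late-infancy end).  Locations are drawn from the
    pool without immediate repeats.  Every history starts at conception and
    ends at the configured current date, covering all life stages.
    """
    rng = np.random.default_rng([config.seed, 0])
    pool = [f"L{i:04d}" for i in range(config.surface.n_locations)]
    n_days = (config.dob_last - config.dob_first).days + 1
    dob_offsets = rng.integers(0, n_days, size=config.n_members)
    gest = np.clip(
        np.rint(rng.normal(config.gestation_mean, config.gestation_sd, config.n_members)),
        *config.gestation_clamp,
    ).astype(int)
    members: list[StudyMember] = []
    period_rows = []
    n_counts = np.arange(1, len(config.move_count_probs) + 1)
    for i in range(config.n_members):
        mid = f"M{i:06d}"
        dob = config.dob_first + timedelta(days=int(dob_offsets[i]))
        m = StudyMember(mid, dob, int(gest[i]))
        members.append(m)
        stages = build_life_stages(m)
        p = pregnancy_window(m)
        li_end = stages[-1].end_date
        move_days: list[date] = []
        if rng.random() < config.p_move_pregnancy:
            k = int(rng.choice(n_counts, p=config.move_count_probs))
            move_days += _sample_days(rng, p.start_date + _DAY, p.end_date, k)
        if rng.random() < config.p_move_infancy:
            k = int(rng.choice(n_counts, p=config.move_count_probs))
            move_days += _sample_days(rng, dob + _DAY, li_end, k)
        move_days.sort()
        locs: list[str] = []
        for _ in range(len(move_days) + 1):
            nxt = pool[int(rng.integers(len(pool)))]
            while locs and nxt == locs[-1]:
                nxt = pool[int(rng.integers(len(pool)))]
            locs.append(nxt)
        bounds = [p.start_date] + move_days + [config.current_date + _DAY]
        for j, loc in enumerate(locs):
            period_rows.append((mid, j, loc, bounds[j], bounds[j + 1] - _DAY))
    periods = pd.DataFrame(
        period_rows,
        columns=["member_id", "period_index", "location_id", "start_date", "end_date"],
    )
    periods["start_date"] = pd.to_datetime(periods["start_date"])
    periods["end_date"] = pd.to_datetime(periods["end_date"])
    members_frame = pd.DataFrame(
        {
            "member_id": [m.member_id for m in members],
            "date_of_birth": pd.to_datetime([m.date_of_birth for m in members]),
            "gestation_weeks": [m.gestation_weeks for m in members],
        }
    )
    stages = build_stage_table(members) if members else pd.DataFrame(
        columns=["member_id", "stage_name", "start_date", "end_date", "n_days"]
    )
    return TruthBundle(members, members_frame, periods, stages, pool)


def corrupt_to_contact_db(truth: TruthBundle, config: SimulationConfig) -> pd.DataFrame:
    """Re-encode the truth as an audit-style contact-database extract.

    Applies, at the configured rates: invalid-geocode insertions (a short
    unusably geocoded period carved from the front of a true period, so the
    subsumption rule restores it), end-date removal, end-date noise,
    first-start removal (recoverable because every true history starts at
    conception), and superseded duplicate rows (a bogus lower-ranked row
    sharing the correction's start date).  Rows are then shuffled and
    assigned ``record_seq`` so corrections always outrank the rows they
    supersede.
    """
    rng = np.random.default_rng([config.seed, 1])
    cfg = config.corruption
    strict = cfg.strict_recoverable
    rows: list[dict] = []  # fields + _dup_of marker for seq ordering
    stages_by_member = {
        mid: g for mid, g in truth.stages.groupby("member_id", sort=False)
    }
    for member in truth.members:
        mid = member.member_id
        per = truth.periods[truth.periods["member_id"] == mid]
        base = [
            {
                "location_id": r.location_id,
                "start_date": r.start_date.date(),
                "end_date": r.end_date.date(),
                "geocode_valid": True,
                "in_study_area": True,
            }
            for r in per.itertuples(index=False)
        ]
        # --- invalid-geocode insertion: carve the front off one period
        if rng.random() < cfg.invalid_geocode_rate:
            j = int(rng.integers(len(base)))
            k = int(rng.integers(3, 11))
            src = base[j]
            length = (src["end_date"] - src["start_date"]).days + 1
            ok = length > k
            if ok and strict:
                sg = stages_by_member[mid]
                c_start = src["start_date"]
                c_end = c_start + timedelta(days=k - 1)
                for srow in sg.itertuples(index=False):
                    s0, s1 = srow.start_date.date(), srow.end_date.date()
                    ov = max(0, (min(s1, c_end) - max(s0, c_start)).days + 1)
                    if ov > 0.25 * srow.n_days:
                        ok = False
                        break
            if ok:
                # unusable either way: failed geocoding, or outside the study area
                failed_geocode = bool(rng.random() < 0.5)
                chunk = {
                    "location_id": f"X{rng.integers(10_000):04d}",
                    "start_date": src["start_date"],
                    "end_date": src["start_date"] + timedelta(days=k - 1),
                    "geocode_valid": not failed_geocode,
                    "in_study_area": failed_geocode,
                }
                src["start_date"] = src["start_date"] + timedelta(days=k)
                base.insert(j, chunk)
        # --- end-date corruption
        n_base = len(base)
        member_rows: list[dict] = []
        for j, r in enumerate(base):
            row = dict(r, member_id=mid, _rank=0)
            is_final = j == n_base - 1
            if rng.random() < cfg.missing_end:
                row["end_date"] = None
            elif cfg.end_date_noise_days > 0 and (not is_final or not strict):
                delta = int(rng.integers(-cfg.end_date_noise_days, cfg.end_date_noise_days + 1))
                if row["end_date"] is not None:
                    row["end_date"] = row["end_date"] + timedelta(days=delta)
            member_rows.append(row)
            # --- superseded duplicate: bogus earlier row sharing the start
            if rng.random() < cfg.duplicate_rate:
                bogus_loc = truth.location_pool[int(rng.integers(len(truth.location_pool)))]
                bogus_end = None if rng.random() < 0.5 else (
                    row["start_date"] + timedelta(days=int(rng.integers(1, 400)))
                    if row["start_date"] is not None else None
                )
                member_rows.append(
                    {
                        "member_id": mid,
                        "location_id": bogus_loc,
                        "start_date": row["start_date"],
                        "end_date": bogus_end,
                        "geocode_valid": True,
                        "in_study_area": True,
                        "_rank": -1,  # must receive a lower seq than its correction
                    }
                )
        # --- first-start removal (first period starts at DoC, so imputation recovers it)
        first = min(
            (r for r in member_rows if r["_rank"] == 0),
            key=lambda r: r["start_date"],
        )
        if rng.random() < cfg.missing_start:
            first["start_date"] = None
        rows.extend(member_rows)
    # --- shuffle, then assign record_seq with corrections outranking originals
    order = rng.permutation(len(rows))
    shuffled = [rows[i] for i in order]
    shuffled.sort(key=lambda r: r["_rank"])  # stable: bogus rows first, shuffled within
    for seq, r in enumerate(shuffled, start=1):
        r["record_seq"] = seq
    out = pd.DataFrame(shuffled).drop(columns="_rank")
    out = out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    out["start_date"] = pd.to_datetime(out["start_date"])
    out["end_date"] = pd.to_datetime(out["end_date"])
    cols = ["member_id", "record_seq", "location_id", "start_date", "end_date",
            "geocode_valid", "in_study_area"]
    return out[cols]


def generate_exposure_surface(
    locations: Sequence[str],
    window: tuple[date, date],
    config: SurfaceConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily concentration field over the window for every location.

    value(loc, d) = max(0, B_loc + A sin(2*pi*doy(d)/365.25) + eps_{loc,d})
    with B_loc lognormal and eps iid normal, all driven by ``seed``.
    """
    if not len(locations):
        raise ValueError("empty location set")
    rng = np.random.default_rng([seed, 2])
    dates = pd.date_range(window[0], window[1], freq="D")
    doy = dates.dayofyear.to_numpy()
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, len(locations))
    seasonal = config.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
    noise = (
        rng.normal(0.0, config.daily_noise_sd, (len(locations), len(dates)))
        if config.daily_noise_sd > 0
        else np.zeros((len(locations), len(dates)))
    )
    values = np.maximum(0.0, baseline[:, None] + seasonal[None, :] + noise)
    out = pd.DataFrame(
        {
            "location_id": np.repeat(np.asarray(locations, dtype=object), len(dates)),
            "date": np.tile(dates.to_numpy(), len(locations)),
            "value": values.ravel(),
        }
    )
    return out


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate truth, corrupt it into a contact extract, and build the surface.

    The surface covers [min conception, max late-infancy end] for the whole
    location pool, so every true member-day inside a life stage has a value.
    """
    truth = generate_truth(config)
    records = corrupt_to_contact_db(truth, config)
    lo = truth.stages["start_date"].min().date()
    hi = truth.stages["end_date"].max().date()
    surface = generate_exposure_surface(truth.location_pool, (lo, hi), config.surface, config.seed)
    return SimulatedStudy(truth, records, surface, config)


# ---------------------------------------------------------------------------
# recovery checking helpers

def truth_histories(truth: TruthBundle) -> dict[str, CleanedHistory]:
    """Wrap the true periods as CleanedHistory objects (all stages reliable)."""
    out: dict[str, CleanedHistory] = {}
    for mid, g in truth.periods.groupby("member_id", sort=False):
        periods = [
            AddressPeriod(
                member_id=mid,
                period_index=int(r.period_index),
                location_id=r.location_id,
                start_date=r.start_date.date(),
                end_date=r.end_date.date(),
            )
            for r in g.sort_values("period_index").itertuples(index=False)
        ]
        out[mid] = CleanedHistory(mid, periods, {}, CleaningAudit())
    return out


def histories_match_truth(
    cleaned: pd.DataFrame, truth_periods: pd.DataFrame
) -> pd.Series:
    """Per-member boolean: cleaned (location, start, end) sequence equals truth."""
    key = ["member_id", "period_index", "location_id", "start_date", "end_date"]
    a = cleaned[key].sort_values(["member_id", "period_index"]).reset_index(drop=True)
    b = truth_periods[key].sort_values(["member_id", "period_index"]).reset_index(drop=True)
    members = sorted(set(b["member_id"]))
    a_by = dict(tuple(a.groupby("member_id", sort=False)))
    b_by = dict(tuple(b.groupby("member_id", sort=False)))
    result = {}
    for mid in members:
        ga = a_by.get(mid)
        gb = b_by[mid]
        if ga is None or len(ga) != len(gb):
            result[mid] = False
            continue
        result[mid] = bool(
            (ga.reset_index(drop=True)[["location_id", "start_date", "end_date"]]
             .equals(gb.reset_index(drop=True)[["location_id", "start_date", "end_date"]]))
        )
    return pd.Series(result, name="recovered")
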
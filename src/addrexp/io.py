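"""File formats, run configuration, and the end-to-end pipeline.

All interchange is delimited text (comma-separated) with ISO-8601 dates;
empty strings are null dates.  Three inputs:

* members:          member_id, date_of_birth, gestation_weeks
* contact records:  member_id, record_seq, location_id, start_date,
                    end_date, geocode_valid, in_study_area
* exposure surface: location_id, date, value   (long format, daily)

``run_pipeline`` orchestrates clean -> stages -> assign -> compare and
writes every output table, the cleaning audit (JSON lines, one change per
line), and a run manifest (config, package version, input checksums).  All
results are computed before anything is written, and each file is written to
a temporary name then atomically renamed, so no output is ever partial.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cleaning import DEFAULT_MAX_OVERLAP_FRACTION, clean_cohort
from .compare import compare_methods, mobility_summary
from .exposure import ExposureSurface, summarize_cohort
from .lifestages import build_stage_table, members_from_frame

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_members",
    "read_contact_records",
    "read_surface",
    "write_table",
    "run_pipeline",
]


class SchemaError(ValueError):
    """An input file does not match its declared schema."""


MEMBERS_COLUMNS = ["member_id", "date_of_birth", "gestation_weeks"]
CONTACT_COLUMNS = ["member_id", "record_seq", "location_id", "start_date",
                   "end_date", "geocode_valid", "in_study_area"]
SURFACE_COLUMNS = ["location_id", "date", "value"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "t": True, "f": False, True: True, False: False}


def _check_columns(frame: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in frame.columns]
    extra = [c for c in frame.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: schema mismatch; missing columns {missing}, extra columns {extra}"
        )


def _parse_iso_dates(frame: pd.DataFrame, column: str, path, allow_null: bool) -> pd.Series:
    raw = frame[column].astype("string")
    blank = raw.isna() | (raw.str.strip() == "")
    parsed = pd.to_datetime(raw.where(~blank), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & ~blank
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad][:5]]  # +2: header + 1-based
        vals = list(raw[bad][:5])
        raise SchemaError(
            f"{path}: column {column!r} has non-ISO-8601 dates {vals} at file rows {rows}"
        )
    if not allow_null and blank.any():
        rows = [int(i) + 2 for i in frame.index[blank][:5]]
        raise SchemaError(f"{path}: column {column!r} empty at file rows {rows}")
    return parsed


def _parse_bool(frame: pd.DataFrame, column: str, path) -> pd.Series:
    raw = frame[column]
    norm = raw.map(lambda v: _BOOL_MAP.get(v.strip().lower() if isinstance(v, str) else v))
    bad = norm.isna()
    if bad.any():
        rows = [int(i) + 2 for i in frame.index[bad][:5]]
        raise SchemaError(f"{path}: column {column!r} not boolean at file rows {rows}")
    return norm.astype(bool)


def read_members(path) -> pd.DataFrame:
    """Read and validate the members table (dates parsed, ids unique)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(frame, MEMBERS_COLUMNS, path)
    frame["date_of_birth"] = _parse_iso_dates(frame, "date_of_birth", path, allow_null=False)
    try:
        frame["gestation_weeks"] = frame["gestation_weeks"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: gestation_weeks must be integers ({exc})") from None
    if frame["member_id"].duplicated().any():
        dups = sorted(set(frame["member_id"][frame["member_id"].duplicated()]))[:5]
        raise SchemaError(f"{path}: duplicate member ids {dups}")
    return frame


def read_contact_records(path, known_members=None) -> pd.DataFrame:
    """Read and validate the contact-records extract.

    Null dates are empty strings.  Unknown members (when ``known_members``
    is given) and duplicate (member_id, record_seq) pairs are rejected.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_columns(frame, CONTACT_COLUMNS, path)
    frame["start_date"] = _parse_iso_dates(frame, "start_date", path, allow_null=True)
    frame["end_date"] = _parse_iso_dates(frame, "end_date", path, allow_null=True)
    try:
        frame["record_seq"] = frame["record_seq"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path}: record_seq must be integers ({exc})") from None
    frame["geocode_valid"] = _parse_bool(frame, "geocode_valid", path)
    frame["in_study_area"] = _parse_bool(frame, "in_study_area", path)
    frame["location_id"] = frame["location_id"].replace("", None)
    if frame.duplicated(["member_id", "record_seq"]).any():
        bad = frame[frame.duplicated(["member_id", "record_seq"])].head(3)
        raise SchemaError(
            f"{path}: duplicate (member_id, record_seq): "
            f"{list(zip(bad['member_id'], bad['record_seq']))}"
        )
    if known_members is not None:
        unknown = sorted(set(frame["member_id"]) - set(known_members))
        if unknown:
            raise SchemaError(
                f"{path}: contact records reference unknown members {unknown[:5]}"
            )
    return frame


def read_surface(path) -> pd.DataFrame:
    """Read and validate the long-format daily exposure surface."""
    frame = pd.read_csv(path, dtype={"location_id": str}, keep_default_na=False,
                        na_values=[""])
    _check_columns(frame, SURFACE_COLUMNS, path)
    frame["date"] = _parse_iso_dates(frame.astype({"date": str}), "date", path, allow_null=False)
    try:
        frame["value"] = frame["value"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: value must be numeric ({exc})") from None
    return frame


# ---------------------------------------------------------------------------
# atomic writers

def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a table as CSV with ISO dates, atomically (temp + rename)."""
    path = Path(path)
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    _atomic_write_text(path, out.to_csv(index=False))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Everything a pipeline run needs; no wall-clock or hidden defaults.

    ``current_date`` (the end-date imputation anchor) is mandatory so runs
    are reproducible; ``max_overlap_fraction`` is the invalid-geocode
    subsumption threshold.
    """

    members_path: str
    contact_records_path: str
    surface_path: str
    output_dir: str
    current_date: date
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION
    missing_policy: str = "fail"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.current_date, str):
            self.current_date = date.fromisoformat(self.current_date)
        if not 0.0 <= self.max_overlap_fraction <= 1.0:
            raise ValueError("max_overlap_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["current_date"] = self.current_date.isoformat()
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Clean, window, assign, and compare; write all artifacts.

    Returns a dict of output paths.  Re-running with identical inputs and
    config reproduces identical files.  Any failure aborts before a single
    output file is (even partially) written.
    """
    out_dir = Path(config.output_dir)
    members_df = read_members(config.members_path)
    records_df = read_contact_records(config.contact_records_path,
                                      known_members=members_df["member_id"])
    surface_df = read_surface(config.surface_path)

    members = members_from_frame(members_df)
    stages = build_stage_table(members)
    cleaning = clean_cohort(records_df, members, config.current_date,
                            config.max_overlap_fraction)
    surface = ExposureSurface(surface_df)
    summaries = summarize_cohort(cleaning.periods, stages, members_df, surface,
                                 cleaning.reliability, config.missing_policy)
    mobility = mobility_summary(cleaning.histories, stages)
    comparison = compare_methods(summaries)

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cleaned_periods": out_dir / "cleaned_periods.csv",
        "life_stages": out_dir / "life_stages.csv",
        "summaries": out_dir / "summaries.csv",
        "mobility_per_member": out_dir / "mobility_per_member.csv",
        "mobility_cohort": out_dir / "mobility_cohort.json",
        "comparison_pairs": out_dir / "comparison_pairs.csv",
        "comparison_by_stage": out_dir / "comparison_by_stage.csv",
        "reliability": out_dir / "reliability.csv",
        "audit": out_dir / "audit.jsonl",
        "manifest": out_dir / "manifest.json",
    }
    write_table(cleaning.periods, paths["cleaned_periods"])
    write_table(stages, paths["life_stages"])
    write_table(summaries, paths["summaries"])
    write_table(mobility.per_member, paths["mobility_per_member"])
    _atomic_write_text(paths["mobility_cohort"], json.dumps(mobility.cohort, indent=2))
    write_table(comparison.pairs, paths["comparison_pairs"])
    write_table(comparison.by_stage, paths["comparison_by_stage"])
    write_table(cleaning.reliability, paths["reliability"])
    _atomic_write_text(
        paths["audit"],
        "".join(json.dumps(rec) + "\n" for rec in cleaning.audit.to_records()),
    )
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "inputs": {
            "members": _sha256(config.members_path),
            "contact_records": _sha256(config.contact_records_path),
            "surface": _sha256(config.surface_path),
        },
        "audit_summary": cleaning.audit.summary(),
    }
    _atomic_write_text(paths["manifest"], json.dumps(manifest, indent=2))
    return {k: str(v) for k, v in paths.items()}
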
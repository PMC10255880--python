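"""Canonical tabular schemas and delimited-text I/O for stepping data.

Three tables flow through the pipeline, all plain UTF-8 CSV with a header
row and local-naive ISO 8601 timestamps:

* **events** — one row per variable-length stepping event
  (``participant_id, device, start, duration_s, steps``); cadence in
  steps/min is derived as ``steps / (duration_s / 60)`` and never stored.
* **wear** — one row per participant-device-day
  (``participant_id, device, date, wear_hours``), with an optional
  ``period`` column for multi-period cohort recordings.
* **cohort** — one row per participant-period with the physical-function
  outcome (SPPB, an integer 0–12) and the modelling covariates.

Readers are *total*: every input row either becomes a validated record or
a row-numbered diagnostic. In strict mode (the default) any diagnostic
raises; in permissive mode offending rows are dropped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEVICES = ("thigh", "wrist")
PERIODS = (0, 6, 12, 24)

SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("secondary", "some college", "college/degree")
COMORBIDITY_LEVELS = ("none", "one or more")
SF36_LEVELS = ("very good/excellent", "good", "fair/poor")
ALLOCATION_LEVELS = ("control", "intervention")
SITE_LEVELS = ("bristol/bath", "birmingham", "exeter")

EVENT_COLUMNS = ["participant_id", "device", "start", "duration_s", "steps"]
WEAR_COLUMNS = ["participant_id", "device", "date", "wear_hours"]
COHORT_COLUMNS = [
    "participant_id",
    "period",
    "sppb",
    "age_at_recruitment",
    "sex",
    "imd_quintile",
    "education",
    "comorbidity",
    "sf36_class",
    "allocation",
    "site",
]


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """One or more rows violate the schema invariants (strict mode)."""


@dataclass(frozen=True)
class RowIssue:
    row: int  # 0-based data-row index (excluding the header)
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: [{self.column}] {self.message}"


@dataclass
class ReadReport:
    """Accounting of a read: every input row is kept or diagnosed."""

    n_rows: int = 0
    n_kept: int = 0
    issues: list[RowIssue] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_rows - self.n_kept


@dataclass(frozen=True)
class Dialect:
    """Column-map adapter for vendor-style exports.

    ``rename`` maps source column names onto the canonical schema;
    ``constants`` supplies canonical columns absent from the export
    (e.g. the device of a single-device report).
    """

    rename: Mapping[str, str] = field(default_factory=dict)
    constants: Mapping[str, object] = field(default_factory=dict)


#: Built-in dialects. The vendor export layouts are configurable column
#: maps, not faithful reproductions of any proprietary report.
EVENT_DIALECTS: dict[str, Dialect] = {
    "canonical": Dialect(),
    "thigh_export": Dialect(
        rename={
            "ID": "participant_id",
            "Event Start": "start",
            "Duration (s)": "duration_s",
            "Step Count": "steps",
        },
        constants={"device": "thigh"},
    ),
    "wrist_export": Dialect(
        rename={
            "subject": "participant_id",
            "start_time": "start",
            "duration": "duration_s",
            "steps": "steps",
        },
        constants={"device": "wrist"},
    ),
}


def _finish(frame: pd.DataFrame, keep: np.ndarray, report: ReadReport,
            mode: str, what: str) -> tuple[pd.DataFrame, ReadReport]:
    report.n_kept = int(keep.sum())
    if report.issues and mode == "strict":
        head = "; ".join(str(i) for i in report.issues[:8])
        more = "" if len(report.issues) <= 8 else f" (+{len(report.issues) - 8} more)"
        raise ValidationError(f"{len(report.issues)} invalid {what} row(s): {head}{more}")
    out = frame.loc[keep].reset_index(drop=True)
    return out, report


def _flag(keep: np.ndarray, bad: pd.Series, column: str, message: str,
          report: ReadReport) -> None:
    for idx in np.flatnonzero(bad.to_numpy() & keep):
        report.issues.append(RowIssue(int(idx), column, message))
    keep &= ~bad.to_numpy()


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_events(path, dialect: str | Dialect = "canonical",
                mode: str = "strict") -> tuple[pd.DataFrame, ReadReport]:
    """Read a stepping-event table and derive cadence.

    Parameters
    ----------
    path : str or Path
        CSV file to read.
    dialect : str or Dialect
        ``"canonical"`` or a vendor adapter (``"thigh_export"``,
        ``"wrist_export"``) or an explicit :class:`Dialect`.
    mode : {"strict", "permissive"}
        Strict raises on any invalid row; permissive drops invalid rows
        and records them in the report.

    Returns
    -------
    (DataFrame, ReadReport)
        Events with columns ``participant_id, device, start, duration_s,
        steps, cadence`` (start as naive ``datetime64``), and the row
        accounting.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(dialect, str):
        try:
            dialect = EVENT_DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown event dialect {dialect!r}") from None
    raw = pd.read_csv(path, dtype=str)
    raw = raw.rename(columns=dict(dialect.rename))
    for col, value in dialect.constants.items():
        raw[col] = value
    _require_columns(raw, EVENT_COLUMNS, path)

    report = ReadReport(n_rows=len(raw))
    keep = np.ones(len(raw), dtype=bool)

    pid = raw["participant_id"].astype(str).str.strip()
    _flag(keep, pid.eq("") | raw["participant_id"].isna(), "participant_id",
          "empty participant id", report)
    device = raw["device"].astype(str).str.strip().str.lower()
    _flag(keep, ~device.isin(DEVICES), "device",
          f"device must be one of {DEVICES}", report)
    start = pd.to_datetime(raw["start"], errors="coerce", format="ISO8601")
    _flag(keep, start.isna(), "start", "unparseable ISO 8601 timestamp", report)
    duration = pd.to_numeric(raw["duration_s"], errors="coerce")
    _flag(keep, duration.isna() | (duration <= 0), "duration_s",
          "duration must be a number > 0", report)
    steps = pd.to_numeric(raw["steps"], errors="coerce")
    _flag(keep, steps.isna() | (steps < 1) | (steps % 1 != 0), "steps",
          "steps must be an integer >= 1", report)

    frame = pd.DataFrame(
        {
            "participant_id": pid,
            "device": device,
            "start": start,
            "duration_s": duration.astype(float),
            "steps": steps.astype("Int64").astype("float").astype("Int64"),
        }
    )
    frame, report = _finish(frame, keep, report, mode, "event")
    frame["steps"] = frame["steps"].astype(np.int64)
    frame["cadence"] = frame["steps"] / (frame["duration_s"] / 60.0)
    return frame, report


def read_wear(path, mode: str = "strict") -> tuple[pd.DataFrame, ReadReport]:
    """Read a wear-time table (one row per participant-device-date)."""
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, WEAR_COLUMNS, path)
    report = ReadReport(n_rows=len(raw))
    keep = np.ones(len(raw), dtype=bool)

    pid = raw["participant_id"].astype(str).str.strip()
    _flag(keep, pid.eq("") | raw["participant_id"].isna(), "participant_id",
          "empty participant id", report)
    device = raw["device"].astype(str).str.strip().str.lower()
    _flag(keep, ~device.isin(DEVICES), "device",
          f"device must be one of {DEVICES}", report)
    date = pd.to_datetime(raw["date"], errors="coerce", format="%Y-%m-%d")
    _flag(keep, date.isna(), "date", "unparseable calendar date", report)
    hours = pd.to_numeric(raw["wear_hours"], errors="coerce")
    _flag(keep, hours.isna() | (hours < 0) | (hours > 24), "wear_hours",
          "wear hours must lie in [0, 24]", report)

    frame = pd.DataFrame(
        {
            "participant_id": pid,
            "device": device,
            "date": date.dt.date,
            "wear_hours": hours.astype(float),
        }
    )
    if "period" in raw.columns:
        period = pd.to_numeric(raw["period"], errors="coerce")
        _flag(keep, period.isna() | ~period.isin(PERIODS), "period",
              f"period must be one of {PERIODS}", report)
        frame["period"] = period.astype("Int64")
    frame, report = _finish(frame, keep, report, mode, "wear")
    if "period" in frame.columns:
        frame["period"] = frame["period"].astype(np.int64)
    dup = frame.duplicated(["participant_id", "device", "date"])
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate participant-device-date wear record(s)")
    return frame, report


def read_cohort(path, mode: str = "strict") -> tuple[pd.DataFrame, ReadReport]:
    """Read a longitudinal cohort table (one row per participant-period)."""
    raw = pd.read_csv(path, dtype=str)
    _require_columns(raw, COHORT_COLUMNS, path)
    report = ReadReport(n_rows=len(raw))
    keep = np.ones(len(raw), dtype=bool)

    pid = raw["participant_id"].astype(str).str.strip()
    _flag(keep, pid.eq("") | raw["participant_id"].isna(), "participant_id",
          "empty participant id", report)
    period = pd.to_numeric(raw["period"], errors="coerce")
    _flag(keep, period.isna() | ~period.isin(PERIODS), "period",
          f"period must be one of {PERIODS}", report)
    sppb = pd.to_numeric(raw["sppb"], errors="coerce")
    _flag(keep, sppb.isna() | (sppb < 0) | (sppb > 12) | (sppb % 1 != 0),
          "sppb", "SPPB must be an integer in [0, 12]", report)
    age = pd.to_numeric(raw["age_at_recruitment"], errors="coerce")
    _flag(keep, age.isna() | (age <= 0), "age_at_recruitment",
          "age must be a positive number", report)
    imd = pd.to_numeric(raw["imd_quintile"], errors="coerce")
    _flag(keep, imd.isna() | ~imd.isin([1, 2, 3, 4, 5]), "imd_quintile",
          "IMD quintile must be 1-5", report)
    for col, levels in [
        ("sex", SEX_LEVELS),
        ("education", EDUCATION_LEVELS),
        ("comorbidity", COMORBIDITY_LEVELS),
        ("sf36_class", SF36_LEVELS),
        ("allocation", ALLOCATION_LEVELS),
        ("site", SITE_LEVELS),
    ]:
        value = raw[col].astype(str).str.strip().str.lower()
        _flag(keep, ~value.isin(levels), col,
              f"must be one of {levels}", report)
        raw[col] = value

    frame = pd.DataFrame(
        {
            "participant_id": pid,
            "period": period,
            "sppb": sppb,
            "age_at_recruitment": age,
            "sex": raw["sex"],
            "imd_quintile": imd,
            "education": raw["education"],
            "comorbidity": raw["comorbidity"],
            "sf36_class": raw["sf36_class"],
            "allocation": raw["allocation"],
            "site": raw["site"],
        }
    )
    frame, report = _finish(frame, keep, report, mode, "cohort")
    for col in ("period", "sppb", "imd_quintile"):
        frame[col] = frame[col].astype(np.int64)
    frame["age_at_recruitment"] = frame["age_at_recruitment"].astype(float)
    return frame, report


def write_events(events: pd.DataFrame, path) -> None:
    """Write events in the canonical layout (cadence is derived, not stored)."""
    out = events[EVENT_COLUMNS].copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def write_wear(wear: pd.DataFrame, path) -> None:
    cols = WEAR_COLUMNS + (["period"] if "period" in wear.columns else [])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    wear[cols].to_csv(path, index=False)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort[COHORT_COLUMNS].to_csv(path, index=False)
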
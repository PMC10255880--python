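"""Event quality control, cadence banding, and the pfSTEP biomarker.

The processing chain mirrors standard practice for event-based stepping
data from body-worn accelerometers:

1. discard unreliable events — fewer than 10 steps, cadence below
   20 steps/min or above 175 steps/min — and truncate each participant's
   recording to their first 7 distinct calendar days;
2. keep only *valid* days/periods, defined by wear-time rules
   (paired-device study: >= 20 h on both devices; cohort study: >= 18 h/day
   on >= 6 days per recording period);
3. classify each event's steps into cadence bands: non-walking
   [20, 45) steps/min, walking [45, 175], with walking split into
   slower- and faster-paced at the *median walking cadence* — the
   unweighted median cadence of all events >= 45 steps/min;
4. aggregate to daily and period-mean step counts per band, and render
   the two-integer pfSTEP biomarker (slower-paced steps/day;
   faster-paced walking steps/day), whose sum is the average total
   steps/day.

Cadence is treated as continuous throughout; the published integer band
labels are a display convention. The walking split uses the exact
(unrounded) median, with "slower" meaning cadence <= median.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CadenceBands",
    "ExclusionReport",
    "PfStep",
    "filter_events",
    "valid_days_paired",
    "valid_period_cohort",
    "median_walking_cadence",
    "aggregate_daily",
    "aggregate_period",
    "pfstep",
    "pfstep_render",
    "period_change",
]

BAND_COLUMNS = [
    "total_steps",
    "non_walking_steps",
    "walking_steps",
    "slower_walking_steps",
    "faster_walking_steps",
    "slower_paced_steps",
]


@dataclass(frozen=True)
class CadenceBands:
    """Cadence thresholds (steps/min) for band classification.

    ``median_walking_cadence`` is data-derived (see
    :func:`median_walking_cadence`) and must be set before daily
    aggregation can split walking into slower and faster paced.
    """

    min_cadence: float = 20.0
    walking_threshold: float = 45.0
    max_cadence: float = 175.0
    median_walking_cadence: float | None = None

    def __post_init__(self) -> None:
        if not (self.min_cadence < self.walking_threshold <= self.max_cadence):
            raise ValueError(
                "cadence thresholds must satisfy min < walking_threshold <= max")
        m = self.median_walking_cadence
        if m is not None and not (self.walking_threshold <= m < self.max_cadence):
            raise ValueError(
                "median walking cadence must lie in [walking_threshold, max_cadence)")

    def with_median(self, median: float) -> "CadenceBands":
        return replace(self, median_walking_cadence=float(median))


@dataclass
class ExclusionReport:
    """Per-rule accounting of removed events; rules apply in order, so a
    row is counted under the first rule it violates and
    ``n_input == n_kept + sum(removals)``."""

    n_input: int = 0
    removed_low_steps: int = 0
    removed_low_cadence: int = 0
    removed_high_cadence: int = 0
    removed_extra_days: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_low_steps": self.removed_low_steps,
            "removed_low_cadence": self.removed_low_cadence,
            "removed_high_cadence": self.removed_high_cadence,
            "removed_extra_days": self.removed_extra_days,
            "n_kept": self.n_kept,
        }


@dataclass(frozen=True)
class PfStep:
    """The two-integer stepping biomarker.

    ``slower_paced_steps`` is the average number of steps/day at or below
    the split cadence (non-walking plus slower-paced walking);
    ``faster_paced_steps`` the average above it. Their sum equals the
    rounded average total steps/day.
    """

    slower_paced_steps: int
    faster_paced_steps: int
    split_cadence: float

    def __post_init__(self) -> None:
        if self.slower_paced_steps < 0 or self.faster_paced_steps < 0:
            raise ValueError("pfSTEP components must be non-negative integers")

    @property
    def total_steps(self) -> int:
        return self.slower_paced_steps + self.faster_paced_steps

    def render(self) -> str:
        return f"({self.slower_paced_steps}; {self.faster_paced_steps})"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _event_dates(events: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(events["start"]).dt.date


def filter_events(
    events: pd.DataFrame,
    bands: CadenceBands = CadenceBands(),
    max_days: int = 7,
    wear: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the event-level quality filters.

    Removes, in order: events with fewer than 10 steps; cadence below
    ``bands.min_cadence``; cadence above ``bands.max_cadence``; and events
    starting after the participant's first ``max_days`` distinct calendar
    dates. Boundary cadences (exactly 20 or exactly 175 steps/min) are
    kept. The first-days window is computed from all dates with any event
    or, when ``wear`` is supplied, any wear record, in chronological order.
    """
    report = ExclusionReport(n_input=len(events))
    if len(events) == 0:
        return events.copy(), report

    cadence = events["cadence"].to_numpy(dtype=float)
    steps = events["steps"].to_numpy()
    keep = np.ones(len(events), dtype=bool)

    bad = steps < 10
    report.removed_low_steps = int(bad.sum())
    keep &= ~bad
    bad = keep & (cadence < bands.min_cadence)
    report.removed_low_cadence = int(bad.sum())
    keep &= ~bad
    bad = keep & (cadence > bands.max_cadence)
    report.removed_high_cadence = int(bad.sum())
    keep &= ~bad

    # First-days window per participant: union of event and wear dates.
    dates = _event_dates(events)
    date_sources = [pd.DataFrame({"participant_id": events["participant_id"],
                                  "date": dates})]
    if wear is not None and len(wear):
        date_sources.append(wear[["participant_id", "date"]])
    all_dates = pd.concat(date_sources, ignore_index=True).drop_duplicates()
    cutoff: dict[str, object] = {}
    for pid, grp in all_dates.groupby("participant_id", sort=False):
        ordered = sorted(grp["date"])
        if len(ordered) > max_days:
            cutoff[pid] = ordered[max_days - 1]
    if cutoff:
        limit = events["participant_id"].map(cutoff)
        bad = keep & limit.notna().to_numpy() & (dates > limit).to_numpy()
        report.removed_extra_days = int(bad.sum())
        keep &= ~bad

    report.n_kept = int(keep.sum())
    return events.loc[keep].reset_index(drop=True), report


def valid_days_paired(
    wear: pd.DataFrame, min_hours: float = 20.0
) -> set[tuple[str, object]]:
    """Participant-dates on which *both* devices were worn >= ``min_hours``.

    The threshold is inclusive (a day with exactly ``min_hours`` on each
    device is valid).
    """
    ok = wear.loc[wear["wear_hours"] >= min_hours]
    per_day = ok.groupby(["participant_id", "date"])["device"].nunique()
    return set(per_day.index[per_day >= 2])


def valid_period_cohort(
    wear: pd.DataFrame, min_hours: float = 18.0, min_days: int = 6
) -> set[tuple[str, int]]:
    """Participant-periods with >= ``min_days`` days of >= ``min_hours`` wear.

    ``wear`` must carry a ``period`` column assigning each date to a
    recording period.
    """
    if "period" not in wear.columns:
        raise ValueError("cohort wear table must have a 'period' column")
    ok = wear.loc[wear["wear_hours"] >= min_hours]
    per_period = ok.groupby(["participant_id", "period"])["date"].nunique()
    return set(per_period.index[per_period >= min_days])


def median_walking_cadence(
    events: pd.DataFrame, walking_threshold: float = 45.0
) -> float:
    """Unweighted median cadence of events at or above the walking threshold.

    Each event contributes one vote regardless of its step count; events
    are pooled over participants, days, and (if present) periods.
    """
    walking = events.loc[events["cadence"] >= walking_threshold, "cadence"]
    if len(walking) == 0:
        raise ValueError(
            f"no walking events (cadence >= {walking_threshold} steps/min); "
            "cannot compute a median walking cadence")
    return float(walking.median())


def _resolve_bands(bands, device: str) -> CadenceBands:
    if isinstance(bands, Mapping):
        try:
            bands = bands[device]
        except KeyError:
            raise ValueError(f"no cadence bands supplied for device {device!r}")
    return bands


def aggregate_daily(
    events: pd.DataFrame,
    bands: CadenceBands | Mapping[str, CadenceBands],
    valid_days: Iterable[tuple[str, object]] | None = None,
) -> pd.DataFrame:
    """Sum steps per participant-device-date in each cadence band.

    Band assignment: non-walking = [min, 45); slower-paced walking =
    [45, median]; faster-paced walking = (median, max]. Slower-paced
    steps are non-walking plus slower-paced walking, so the slower/faster
    pair partitions the daily total exactly.

    ``bands`` may be a single :class:`CadenceBands` or a per-device
    mapping (each device is split at its own median walking cadence).
    When ``valid_days`` is given, only those participant-dates are
    emitted — including a zero row for a valid day on which a device
    recorded no events — and invalid days are dropped.
    """
    devices = sorted(events["device"].unique()) if len(events) else []
    for device in devices:
        b = _resolve_bands(bands, device)
        if b.median_walking_cadence is None:
            raise ValueError(
                f"bands for device {device!r} have no median walking cadence set")

    frame = events.copy()
    frame["date"] = _event_dates(frame)
    if valid_days is not None:
        valid_days = set(valid_days)
        mask = [
            (p, d) in valid_days
            for p, d in zip(frame["participant_id"], frame["date"])
        ]
        frame = frame.loc[mask]

    rows = []
    for (pid, device, date), grp in frame.groupby(
        ["participant_id", "device", "date"], sort=True
    ):
        b = _resolve_bands(bands, device)
        cadence = grp["cadence"].to_numpy(dtype=float)
        steps = grp["steps"].to_numpy()
        non_walking = int(steps[cadence < b.walking_threshold].sum())
        walking_mask = cadence >= b.walking_threshold
        slower_walk = int(
            steps[walking_mask & (cadence <= b.median_walking_cadence)].sum())
        faster_walk = int(
            steps[walking_mask & (cadence > b.median_walking_cadence)].sum())
        rows.append(
            {
                "participant_id": pid,
                "device": device,
                "date": date,
                "total_steps": non_walking + slower_walk + faster_walk,
                "non_walking_steps": non_walking,
                "walking_steps": slower_walk + faster_walk,
                "slower_walking_steps": slower_walk,
                "faster_walking_steps": faster_walk,
                "slower_paced_steps": non_walking + slower_walk,
            }
        )
    daily = pd.DataFrame(
        rows, columns=["participant_id", "device", "date"] + BAND_COLUMNS)

    if valid_days and devices:
        # Zero-fill valid days with no events for a device.
        grid = pd.DataFrame(
            [
                {"participant_id": p, "device": dev, "date": d}
                for (p, d) in sorted(valid_days, key=lambda t: (str(t[0]), str(t[1])))
                for dev in devices
            ]
        )
        daily = grid.merge(daily, how="left",
                           on=["participant_id", "device", "date"])
        daily[BAND_COLUMNS] = daily[BAND_COLUMNS].fillna(0)
    if len(daily):
        daily[BAND_COLUMNS] = daily[BAND_COLUMNS].astype(np.int64)
    return daily.reset_index(drop=True)


def aggregate_period(
    daily: pd.DataFrame,
    valid_periods: Iterable[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Average daily band counts over each participant-(device-)period.

    ``daily`` must carry a ``period`` column; the mean is the plain
    arithmetic mean over that period's retained days. Returns one row per
    participant(-device)-period with mean daily steps per band and the
    day count ``n_days``.
    """
    if "period" not in daily.columns:
        raise ValueError("daily table must have a 'period' column")
    frame = daily
    if valid_periods is not None:
        valid_periods = set(valid_periods)
        mask = [
            (p, t) in valid_periods
            for p, t in zip(frame["participant_id"], frame["period"])
        ]
        frame = frame.loc[mask]
    keys = ["participant_id"]
    if "device" in frame.columns:
        keys.append("device")
    keys.append("period")
    out = frame.groupby(keys, sort=True)[BAND_COLUMNS].mean().reset_index()
    out["n_days"] = frame.groupby(keys, sort=True).size().to_numpy()
    return out


def pfstep(
    slower_paced_mean: float,
    faster_paced_mean: float,
    split_cadence: float,
) -> PfStep:
    """Render mean daily slower-/faster-paced steps as the two-integer
    biomarker.

    Each component is rounded half-up to the nearest integer; if the
    rounded components do not sum to the rounded mean total, the larger
    component absorbs the +/-1 discrepancy so the identity
    ``slower + faster == round(total)`` always holds.
    """
    if slower_paced_mean < 0 or faster_paced_mean < 0:
        raise ValueError("mean daily steps must be non-negative")
    slower = _round_half_up(slower_paced_mean)
    faster = _round_half_up(faster_paced_mean)
    total = _round_half_up(slower_paced_mean + faster_paced_mean)
    diff = total - (slower + faster)
    if diff:
        if slower >= faster:
            slower += diff
        else:
            faster += diff
    return PfStep(slower, faster, float(split_cadence))


def pfstep_render(biomarker: PfStep) -> str:
    return biomarker.render()


def period_change(
    summary_t0: Mapping[str, float], summary_t1: Mapping[str, float]
) -> pd.DataFrame:
    """Decline between two period-level mean tables, per band.

    ``change = mean(t0) - mean(t1)`` (positive = decline) and
    ``percent = change / mean(t0) * 100`` rounded to the nearest integer.
    A zero baseline yields an undefined percent, flagged with
    ``percent_defined = False``.
    """
    rows = []
    for band in summary_t0:
        if band not in summary_t1:
            continue
        base = float(summary_t0[band])
        change = base - float(summary_t1[band])
        defined = base != 0
        rows.append(
            {
                "band": band,
                "baseline": base,
                "followup": float(summary_t1[band]),
                "change": change,
                "percent": _round_half_up(change / base * 100) if defined else np.nan,
                "percent_defined": defined,
            }
        )
    return pd.DataFrame(rows)
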
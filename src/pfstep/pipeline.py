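"""End-to-end pipeline profiles, configuration, and report assembly.

Two reproducible profiles tie the stages together:

* **paired** — paired-device agreement study: event QC, per-device
  median walking cadence, daily band aggregation over valid days
  (>= 20 h wear on both devices), variance-components CCC per band with
  bootstrap intervals, variance shares, and paired-day scatter
  statistics.
* **cohort** — longitudinal cohort study: period validity (>= 18 h/day
  on >= 6 days), two-stage aggregation to period means, the three
  stepping-SPPB mixed models, a band-by-period summary table, and the
  scenario projections.

Every run writes CSV/JSON outputs plus a manifest recording the config
hash, the master seed, and package versions; a rerun with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import banding, io as pio
from .agreement import AgreementSpec, daily_scatter_stats, fit_agreement, \
    variance_share_report
from .association import (
    AssociationSpec,
    Scenario,
    fit_association,
    project_scenario,
    relative_increase,
    total_effect,
)
from .banding import CadenceBands
from .simulate import CohortSimConfig, PairedSimConfig, simulate_cohort, \
    simulate_paired_events

__all__ = ["PipelineConfig", "PipelineError", "run_paired", "run_cohort",
           "cohort_analysis_table"]

AGREEMENT_BANDS = ["total_steps", "walking_steps", "slower_walking_steps",
                   "faster_walking_steps"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    profile: str = "paired"
    seed: int = 0
    output_dir: str = "pfstep_output"
    # Input files; when None the matching simulator supplies the data.
    events_path: str | None = None
    wear_path: str | None = None
    cohort_path: str | None = None
    daily_path: str | None = None
    # Band and validity parameters.
    min_cadence: float = 20.0
    walking_threshold: float = 45.0
    max_cadence: float = 175.0
    max_days: int = 7
    paired_min_wear_hours: float = 20.0
    cohort_min_wear_hours: float = 18.0
    cohort_min_valid_days: int = 6
    # Model settings.
    n_bootstrap: int = 500
    include_subject_day: bool = True
    include_subject_device: bool = True
    # Scenario defaults: deltas in thousands of steps/day and coefficients
    # in SPPB points per 1000 steps/day (slower-paced, faster-paced).
    scenario_theta_slower: float = 0.13
    scenario_theta_faster: float = 0.53
    scenario_deltas: tuple = ((-0.708, -0.236), (0.5, 0.5), (-0.5, 1.0))
    # Simulator overrides (field name -> value), applied on top of defaults.
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "scenario_deltas" in raw:
            raw["scenario_deltas"] = tuple(tuple(d) for d in raw["scenario_deltas"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _read_or(path, reader, what):
    if path is None:
        return None
    if not Path(path).exists():
        raise PipelineError(f"{what} file not found: {path}")
    frame, _ = reader(path)
    return frame


def _write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    import scipy
    import statsmodels

    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "profile": config.profile,
        "versions": {
            "pfstep": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        **extra,
    }


def _agreement_dict(result, ci) -> dict:
    return {
        "response": result.response,
        "ccc": result.ccc,
        "ccc_ci_low": ci[0] if ci else None,
        "ccc_ci_high": ci[1] if ci else None,
        "pearson_daily": result.pearson_daily,
        "device_bias": result.device_bias,
        "var_subject": result.var_subject,
        "var_subject_day": result.var_subject_day,
        "var_subject_device": result.var_subject_device,
        "var_error": result.var_error,
        "s2_device": result.s2_device,
        "variance_shares": result.variance_shares,
        "n_participants": result.n_participants,
        "n_paired_days": result.n_pairs,
        "method": result.method,
        "warnings": result.warnings,
    }


@_stage("paired")
def run_paired(config: PipelineConfig) -> dict:
    """Run the paired-device agreement profile; returns the report bundle
    (also written under ``config.output_dir``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.events_path or config.wear_path:
        events = _read_or(config.events_path, pio.read_events, "events")
        wear = _read_or(config.wear_path, pio.read_wear, "wear")
        if events is None or wear is None:
            raise PipelineError(
                "paired profile needs both events_path and wear_path "
                "(or neither, to simulate)")
        truth = None
    else:
        sim = PairedSimConfig(seed=config.seed, **config.sim_overrides)
        events, wear, truth = simulate_paired_events(sim)
        pio.write_events(events, out / "simulated_events.csv")
        pio.write_wear(wear, out / "simulated_wear.csv")

    base = CadenceBands(config.min_cadence, config.walking_threshold,
                        config.max_cadence)
    kept, exclusions = banding.filter_events(events, base, config.max_days, wear)
    valid = banding.valid_days_paired(wear, config.paired_min_wear_hours)
    if not valid:
        raise PipelineError("no valid participant-days (both devices >= "
                            f"{config.paired_min_wear_hours} h)")

    bands = {}
    for device, grp in kept.groupby("device"):
        median = banding.median_walking_cadence(grp, config.walking_threshold)
        bands[device] = base.with_median(median)
    daily = banding.aggregate_daily(kept, bands, valid)

    thresholds = pd.DataFrame(
        [
            {
                "device": device,
                "min_cadence": b.min_cadence,
                "walking_threshold": b.walking_threshold,
                "median_walking_cadence": b.median_walking_cadence,
                "max_cadence": b.max_cadence,
            }
            for device, b in sorted(bands.items())
        ]
    )

    agreement_results, share_tables = {}, []
    for response in AGREEMENT_BANDS:
        spec = AgreementSpec(
            response=response,
            include_subject_day=config.include_subject_day,
            include_subject_device=config.include_subject_device,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        result = fit_agreement(daily, spec, ci=config.n_bootstrap > 0)
        agreement_results[response] = _agreement_dict(result, result.ccc_ci)
        shares = variance_share_report(result)
        shares.insert(0, "response", response)
        share_tables.append(shares)
    scatter = daily_scatter_stats(daily, AGREEMENT_BANDS)

    biomarkers = {}
    for device, grp in daily.groupby("device"):
        bm = banding.pfstep(grp["slower_paced_steps"].mean(),
                            grp["faster_walking_steps"].mean(),
                            bands[device].median_walking_cadence)
        biomarkers[device] = {
            "slower_paced_steps": bm.slower_paced_steps,
            "faster_paced_steps": bm.faster_paced_steps,
            "split_cadence": bm.split_cadence,
            "rendered": bm.render(),
        }

    daily.to_csv(out / "daily_aggregates.csv", index=False)
    thresholds.to_csv(out / "band_thresholds.csv", index=False)
    pd.concat(share_tables).to_csv(out / "variance_shares.csv", index=False)
    scatter.to_csv(out / "scatter_stats.csv", index=False)
    pd.DataFrame(agreement_results).T.to_csv(out / "agreement.csv")
    _write_json(exclusions.as_dict(), out / "exclusions.json")
    _write_json(agreement_results, out / "agreement.json")
    _write_json(biomarkers, out / "pfstep.json")
    manifest = _manifest(config, {
        "n_events_in": exclusions.n_input,
        "n_events_kept": exclusions.n_kept,
        "n_valid_days": len(valid),
    })
    _write_json(manifest, out / "manifest.json")
    return {
        "exclusions": exclusions,
        "thresholds": thresholds,
        "daily": daily,
        "agreement": agreement_results,
        "scatter": scatter,
        "biomarkers": biomarkers,
        "manifest": manifest,
        "truth": truth,
    }


def _table3_style(period_means: pd.DataFrame) -> pd.DataFrame:
    """Band-by-period cohort summary: mean (SD; % of total) per band."""
    bands = ["total_steps", "non_walking_steps", "slower_paced_steps",
             "slower_walking_steps", "faster_walking_steps"]
    rows = []
    for period, grp in period_means.groupby("period"):
        total_mean = grp["total_steps"].mean()
        for band in bands:
            mean = grp[band].mean()
            rows.append(
                {
                    "period": period,
                    "band": band,
                    "n": len(grp),
                    "mean": mean,
                    "sd": grp[band].std(ddof=1),
                    "pct_of_total": 100 * mean / total_mean if total_mean else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _coef_table(results: dict) -> pd.DataFrame:
    frames = []
    for model_id, result in results.items():
        coef = result.coefficients.copy()
        coef.insert(0, "model", model_id)
        coef["total_effect"] = [
            total_effect(result, r["term"], r["period"])
            for _, r in coef.iterrows()
        ]
        frames.append(coef)
    return pd.concat(frames, ignore_index=True)


def cohort_analysis_table(
    cohort: pd.DataFrame,
    daily: pd.DataFrame,
    min_wear_hours: float = 18.0,
    min_valid_days: int = 6,
) -> pd.DataFrame:
    """Join SPPB/covariate rows to period-mean stepping over valid days.

    Applies the period validity rule (>= ``min_valid_days`` days with
    >= ``min_wear_hours`` wear), averages the banded daily counts over
    the qualifying days, and inner-joins on participant and period. The
    result is the modelling table for :func:`~pfstep.association.fit_association`.
    """
    wear = daily[["participant_id", "device", "period", "date", "wear_hours"]]
    valid_periods = banding.valid_period_cohort(wear, min_wear_hours,
                                                min_valid_days)
    good_days = daily[daily["wear_hours"] >= min_wear_hours]
    period_means = banding.aggregate_period(good_days, valid_periods)
    drop = [c for c in ("device", "n_days") if c in period_means.columns]
    return cohort.merge(period_means.drop(columns=drop),
                        on=["participant_id", "period"], how="inner")


@_stage("cohort")
def run_cohort(config: PipelineConfig) -> dict:
    """Run the longitudinal cohort profile; returns the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path or config.daily_path:
        cohort = _read_or(config.cohort_path, pio.read_cohort, "cohort")
        if config.daily_path is None or not Path(config.daily_path).exists():
            raise PipelineError(
                f"daily stepping file not found: {config.daily_path}")
        daily = pd.read_csv(config.daily_path,
                            parse_dates=["date"]).assign(
                                date=lambda d: d["date"].dt.date)
        truth = None
    else:
        sim = CohortSimConfig(seed=config.seed, **config.sim_overrides)
        cohort, daily, truth = simulate_cohort(sim)
        pio.write_cohort(cohort, out / "simulated_cohort.csv")
        daily.to_csv(out / "simulated_daily_steps.csv", index=False)
    if cohort is None or cohort.empty or daily.empty:
        raise PipelineError("cohort profile received no usable rows")

    wear = daily[["participant_id", "device", "period", "date", "wear_hours"]]
    valid_periods = banding.valid_period_cohort(
        wear, config.cohort_min_wear_hours, config.cohort_min_valid_days)
    if not valid_periods:
        raise PipelineError("no valid participant-periods after the wear rule")

    good_days = daily[daily["wear_hours"] >= config.cohort_min_wear_hours]
    period_means = banding.aggregate_period(good_days, valid_periods)
    table3 = _table3_style(period_means)

    merged = cohort.merge(
        period_means.drop(columns=[c for c in ("device", "n_days")
                                   if c in period_means.columns]),
        on=["participant_id", "period"], how="inner")
    if merged.empty:
        raise PipelineError("no participant-periods with both valid stepping "
                            "and SPPB data")

    results = {}
    for model_id in (1, 2, 3):
        results[model_id] = fit_association(merged, AssociationSpec(model_id))
    coef_table = _coef_table(results)
    fit_stats = pd.DataFrame(
        [
            {
                "model": mid,
                "aic": res.aic,
                "loglik": res.loglik,
                "var_random_intercept": res.var_random_intercept,
                "var_residual": res.var_residual,
                "n_participants": res.n_participants,
                "n_participant_periods": res.n_participant_periods,
            }
            for mid, res in results.items()
        ]
    )

    scenarios = []
    for delta_slower, delta_faster in config.scenario_deltas:
        scenario = Scenario(delta_slower, delta_faster,
                            config.scenario_theta_slower,
                            config.scenario_theta_faster)
        scenarios.append(
            {
                "delta_slower_thousand": delta_slower,
                "delta_faster_thousand": delta_faster,
                "theta_slower": config.scenario_theta_slower,
                "theta_faster": config.scenario_theta_faster,
                "sppb_change": project_scenario(scenario),
            }
        )

    baseline = table3[table3["period"] == table3["period"].min()]
    base_means = dict(zip(baseline["band"], baseline["mean"]))
    rel = {
        band: relative_increase(1000.0, base_means[band])
        for band in ("total_steps", "slower_paced_steps",
                     "slower_walking_steps", "faster_walking_steps")
        if base_means.get(band, 0) > 0
    }
    last = table3[table3["period"] == table3["period"].max()]
    decline = banding.period_change(
        base_means, dict(zip(last["band"], last["mean"])))

    period_means.to_csv(out / "period_means.csv", index=False)
    table3.to_csv(out / "stepping_by_period.csv", index=False)
    coef_table.to_csv(out / "association_coefficients.csv", index=False)
    fit_stats.to_csv(out / "association_fit_stats.csv", index=False)
    decline.to_csv(out / "stepping_decline.csv", index=False)
    _write_json(scenarios, out / "scenarios.json")
    _write_json(rel, out / "relative_increase_pct.json")
    manifest = _manifest(config, {
        "n_participants": int(cohort["participant_id"].nunique()),
        "n_valid_participant_periods": len(valid_periods),
        "n_model_rows": int(len(merged)),
    })
    _write_json(manifest, out / "manifest.json")
    return {
        "period_means": period_means,
        "stepping_by_period": table3,
        "results": results,
        "coefficients": coef_table,
        "fit_stats": fit_stats,
        "scenarios": scenarios,
        "relative_increase_pct": rel,
        "decline": decline,
        "manifest": manifest,
        "truth": truth,
    }
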
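"""Synthetic stepping data with fully known ground truth.

Two generators make every downstream stage testable without access to
the restricted study data:

* :func:`simulate_paired_events` emulates a paired-device agreement
  study: each participant wears a thigh and a wrist accelerometer
  simultaneously for several days. Latent daily step totals follow a
  crossed random-effects decomposition

  .. math:: T_{ijk} = \\mu + \\beta_j + \\alpha_i + \\gamma_{ik}
            + \\delta_{ij} + \\varepsilon_{ijk}

  (participant *i*, device *j*, day *k*) with known variance components
  and a fixed wrist-minus-thigh offset. Each latent total is then
  decomposed into variable-length stepping events whose step counts sum
  to the total exactly, with cadences drawn from truncated log-normal
  band mixtures. Deliberately invalid events (< 10 steps, cadence
  outside [20, 175] steps/min) and sub-threshold wear days are injected
  on top so the quality filters have something to remove.

* :func:`simulate_cohort` emulates a four-period longitudinal cohort:
  banded daily stepping around period-specific means that decline over
  follow-up, and an integer physical-function score (SPPB, 0-12)
  generated from a random-intercepts linear model whose stepping
  coefficients (points per 1000 steps/day, per period) are known.

Both are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ALLOCATION_LEVELS,
    COMORBIDITY_LEVELS,
    EDUCATION_LEVELS,
    SEX_LEVELS,
    SF36_LEVELS,
    SITE_LEVELS,
)

__all__ = [
    "BandMixture",
    "PairedSimConfig",
    "CohortSimConfig",
    "ConfigError",
    "simulate_paired_events",
    "simulate_paired_daily",
    "simulate_cohort",
]


class ConfigError(ValueError):
    """A simulation config field is invalid; the message names the field."""


@dataclass(frozen=True)
class BandMixture:
    """Event mixture for one cadence band.

    ``step_share`` — fraction of the daily total allotted to the band;
    ``event_steps_mean`` — typical per-event step count (events are drawn
    until the band's step allotment is consumed, so the implied event
    count per day is roughly ``share * total / event_steps_mean``);
    ``cadence_log_mean``/``cadence_log_sd`` — log-normal cadence
    parameters, truncated to ``cadence_range`` (steps/min).
    """

    step_share: float
    event_steps_mean: float
    cadence_log_mean: float
    cadence_log_sd: float
    cadence_range: tuple[float, float]


def _default_cadence_mixture() -> dict[str, BandMixture]:
    return {
        "non_walking": BandMixture(0.38, 25.0, np.log(31.0), 0.22, (20.0, 45.0)),
        "slower_walking": BandMixture(0.26, 55.0, np.log(62.0), 0.13, (45.0, 75.0)),
        "faster_walking": BandMixture(0.36, 85.0, np.log(96.0), 0.17, (75.0, 175.0)),
    }


@dataclass
class PairedSimConfig:
    """Ground-truth parameters for the paired thigh/wrist simulation.

    Defaults emulate the scale of a small free-living agreement study in
    older adults: 56 participants over 7 days averaging ~9065 daily
    steps on the thigh reference, with the wrist reading ~656 steps/day
    higher, and variance dominated by between-participant (~51%) and
    day-to-day (~37%) variation with only a small device contribution.
    """

    n_participants: int = 56
    n_days: int = 7
    mu_total_steps: float = 9065.0
    var_subject: float = 1.30e7
    var_day: float = 9.60e6            # participant-day, shared across devices
    var_subject_device: float = 3.0e5
    var_error: float = 2.1e6
    device_bias: float = 656.0         # wrist minus thigh, steps/day
    cadence_shift_wrist: float = 2.0   # steps/min added to wrist cadences
    cadence_mixture: Mapping[str, BandMixture] = field(
        default_factory=_default_cadence_mixture)
    share_concentration: float = 60.0  # Dirichlet concentration of day shares
    wear_mean_hours: float = 23.2
    wear_sd_hours: float = 0.5
    low_wear_rate: float = 0.05        # fraction of device-days below 20 h
    invalid_event_rate: float = 0.02   # extra filter-bait events per valid event
    start_date: dt.date = dt.date(2022, 3, 7)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        for name in ("var_subject", "var_day", "var_subject_device", "var_error"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.mu_total_steps <= 0:
            raise ConfigError("mu_total_steps must be > 0")
        shares = [m.step_share for m in self.cadence_mixture.values()]
        if any(s < 0 for s in shares) or not np.isclose(sum(shares), 1.0):
            raise ConfigError("cadence_mixture step shares must be >= 0 and sum to 1")
        for band, mix in self.cadence_mixture.items():
            lo, hi = mix.cadence_range
            loc = float(np.exp(mix.cadence_log_mean))
            if not (20.0 <= loc <= 175.0):
                raise ConfigError(
                    f"cadence_mixture[{band!r}] location {loc:.1f} outside [20, 175]")
            if not (lo < hi):
                raise ConfigError(f"cadence_mixture[{band!r}] has an empty range")
        if not (0 <= self.low_wear_rate <= 1):
            raise ConfigError("low_wear_rate must be a probability")
        if not (0 <= self.invalid_event_rate <= 1):
            raise ConfigError("invalid_event_rate must be a probability")


def _truncated_lognormal(rng, log_mean, log_sd, lo, hi, size):
    """Rejection-sample a log-normal restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(log_mean, log_sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _split_band_targets(rng, total: int, shares: np.ndarray,
                        concentration: float) -> np.ndarray:
    """Integer step targets per band, summing to ``total`` exactly."""
    if total <= 0:
        return np.zeros(len(shares), dtype=np.int64)
    positive = shares > 0
    day_shares = np.zeros(len(shares))
    day_shares[positive] = rng.dirichlet(shares[positive] * concentration)
    targets = np.floor(day_shares * total).astype(np.int64)
    remainder = total - targets.sum()
    order = np.argsort(-(day_shares * total - targets))
    for idx in order[:remainder]:
        targets[idx] += 1
    # A band target below the 10-step event minimum cannot form a valid
    # event; fold it into the largest band to conserve the daily total.
    small = (targets > 0) & (targets < 10)
    if small.any():
        recipient = int(np.argmax(targets))
        if targets[recipient] >= 10 or targets[small].sum() + targets[recipient] >= 10:
            moved = targets[small].sum()
            targets[small] = 0
            targets[recipient] += moved
    return targets


def _events_for_band(rng, target: int, mix: BandMixture, cadence_shift: float,
                     day_start: dt.datetime) -> list[dict]:
    """Decompose a band's step target into >= 10-step events."""
    events = []
    remaining = int(target)
    while remaining >= 10:
        steps = int(round(rng.lognormal(np.log(mix.event_steps_mean), 0.6)))
        steps = max(10, min(steps, remaining))
        if remaining - steps < 10:
            steps = remaining  # absorb the tail so every event has >= 10 steps
        cadence = float(
            _truncated_lognormal(rng, mix.cadence_log_mean, mix.cadence_log_sd,
                                 *mix.cadence_range, size=1)[0])
        cadence = float(np.clip(cadence + cadence_shift, 20.0, 175.0))
        start = day_start + dt.timedelta(seconds=float(rng.uniform(6 * 3600, 22 * 3600)))
        events.append(
            {
                "start": start,
                "duration_s": steps / cadence * 60.0,
                "steps": steps,
            }
        )
        remaining -= steps
    return events


def _invalid_event(rng, day_start: dt.datetime) -> dict:
    """An event that violates exactly one quality filter."""
    kind = rng.integers(0, 3)
    start = day_start + dt.timedelta(seconds=float(rng.uniform(6 * 3600, 22 * 3600)))
    if kind == 0:  # too few steps
        steps, cadence = int(rng.integers(1, 10)), float(rng.uniform(30, 120))
    elif kind == 1:  # too slow
        steps, cadence = int(rng.integers(10, 40)), float(rng.uniform(5, 19.5))
    else:  # too fast
        steps, cadence = int(rng.integers(10, 40)), float(rng.uniform(175.5, 220))
    return {"start": start, "duration_s": steps / cadence * 60.0, "steps": steps}


def _latent_daily(config: PairedSimConfig, rng) -> np.ndarray:
    """Latent daily totals, shape (n_participants, 2 devices, n_days)."""
    n, K = config.n_participants, config.n_days
    bias = np.array([0.0, config.device_bias])  # thigh, wrist
    alpha = rng.normal(0.0, np.sqrt(config.var_subject), size=n)
    gamma = rng.normal(0.0, np.sqrt(config.var_day), size=(n, K))
    delta = rng.normal(0.0, np.sqrt(config.var_subject_device), size=(n, 2))
    eps = rng.normal(0.0, np.sqrt(config.var_error), size=(n, 2, K))
    latent = (config.mu_total_steps + bias[None, :, None]
              + alpha[:, None, None] + gamma[:, None, :]
              + delta[:, :, None] + eps)
    return latent


def simulate_paired_daily(
    config: PairedSimConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate only the latent paired daily totals (no event synthesis).

    The daily-totals layer is the part of :func:`simulate_paired_events`
    that carries the variance-component structure; this entry point is
    the cheap route for agreement-model simulation studies where
    event-level detail is irrelevant. Totals are rounded and clipped at
    zero exactly as in the event-level generator.

    Returns a long daily table (``participant_id, device, date,
    total_steps``) and the ground-truth record.
    """
    config = config or PairedSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    latent = _latent_daily(config, rng)
    n, K = config.n_participants, config.n_days
    pids = [f"P{i + 1:03d}" for i in range(n)]
    dates = [config.start_date + dt.timedelta(days=k) for k in range(K)]
    totals = np.round(latent).astype(np.int64)
    totals[totals < 10] = 0
    rows = [
        {
            "participant_id": pids[i],
            "device": device,
            "date": dates[k],
            "total_steps": int(totals[i, j, k]),
        }
        for i in range(n)
        for j, device in enumerate(("thigh", "wrist"))
        for k in range(K)
    ]
    daily = pd.DataFrame(rows)
    truth = {
        "components": {
            "var_subject": config.var_subject,
            "var_day": config.var_day,
            "var_subject_device": config.var_subject_device,
            "var_error": config.var_error,
            "device_bias": config.device_bias,
            "mu_total_steps": config.mu_total_steps,
        },
        "config": config,
    }
    return daily, truth


def simulate_paired_events(
    config: PairedSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate paired thigh/wrist event and wear tables with known truth.

    Returns
    -------
    events : DataFrame
        Canonical event columns plus derived ``cadence``; includes the
        injected invalid events.
    wear : DataFrame
        One row per participant-device-date with wear hours.
    truth : dict
        ``latents`` — DataFrame of the latent daily totals per
        participant-device-date (what the valid events on that day sum
        to); ``components`` — the generating variance components and
        bias; ``config`` — an echo of the configuration.
    """
    config = config or PairedSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, K = config.n_participants, config.n_days
    pids = [f"P{i + 1:03d}" for i in range(n)]
    devices = ("thigh", "wrist")
    shift = {"thigh": 0.0, "wrist": config.cadence_shift_wrist}
    latent_all = _latent_daily(config, rng)

    bands = list(config.cadence_mixture)
    shares = np.array([config.cadence_mixture[b].step_share for b in bands])

    event_rows, wear_rows, latent_rows = [], [], []
    for i, pid in enumerate(pids):
        for k in range(K):
            date = config.start_date + dt.timedelta(days=k)
            day_start = dt.datetime.combine(date, dt.time())
            for j, device in enumerate(devices):
                total = max(0, int(round(latent_all[i, j, k])))
                if total < 10:
                    total = 0
                targets = _split_band_targets(rng, total, shares,
                                              config.share_concentration)
                day_events: list[dict] = []
                for band, target in zip(bands, targets):
                    day_events.extend(
                        _events_for_band(rng, int(target),
                                         config.cadence_mixture[band],
                                         shift[device], day_start))
                realised = sum(e["steps"] for e in day_events)
                n_bad = rng.binomial(len(day_events), config.invalid_event_rate)
                for _ in range(n_bad):
                    day_events.append(_invalid_event(rng, day_start))
                for e in day_events:
                    event_rows.append(
                        {"participant_id": pid, "device": device, **e})
                latent_rows.append(
                    {
                        "participant_id": pid,
                        "device": device,
                        "date": date,
                        "latent_total": realised,
                    }
                )
                if rng.random() < config.low_wear_rate:
                    hours = float(rng.uniform(10.0, 19.5))
                else:
                    hours = float(
                        min(24.0, 24.0 - abs(rng.normal(
                            24.0 - config.wear_mean_hours, config.wear_sd_hours))))
                wear_rows.append(
                    {
                        "participant_id": pid,
                        "device": device,
                        "date": date,
                        "wear_hours": hours,
                    }
                )

    events = pd.DataFrame(event_rows).sort_values(
        ["participant_id", "device", "start"], kind="stable").reset_index(drop=True)
    events["steps"] = events["steps"].astype(np.int64)
    events["cadence"] = events["steps"] / (events["duration_s"] / 60.0)
    events = events[
        ["participant_id", "device", "start", "duration_s", "steps", "cadence"]]
    wear = pd.DataFrame(wear_rows)
    truth = {
        "latents": pd.DataFrame(latent_rows),
        "components": {
            "var_subject": config.var_subject,
            "var_day": config.var_day,
            "var_subject_device": config.var_subject_device,
            "var_error": config.var_error,
            "device_bias": config.device_bias,
            "mu_total_steps": config.mu_total_steps,
        },
        "config": config,
    }
    return events, wear, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

def _default_stepping_means() -> dict[str, tuple[float, ...]]:
    # Mean daily steps per band at months 0/6/12/24, declining over
    # follow-up as typical for community-dwelling older adults.
    return {
        "non_walking": (4342.0, 4147.0, 3965.0, 3776.0),
        "slower_walking": (581.0, 555.0, 505.0, 439.0),
        "faster_walking": (892.0, 867.0, 780.0, 656.0),
    }


def _default_stepping_sds() -> dict[str, tuple[float, ...]]:
    return {
        "non_walking": (2371.0, 2386.0, 2259.0, 2353.0),
        "slower_walking": (530.0, 544.0, 484.0, 459.0),
        "faster_walking": (938.0, 996.0, 915.0, 857.0),
    }


def _default_prevalences() -> dict[str, dict[str, float]]:
    return {
        "sex": {"male": 217 / 651, "female": 434 / 651},
        "imd_quintile": {str(q): p for q, p in zip(
            range(1, 6),
            (69 / 651, 130 / 651, 130 / 651, 136 / 651, 186 / 651))},
        "education": {
            "secondary": 291 / 651,
            "some college": 171 / 651,
            "college/degree": 189 / 651,
        },
        "comorbidity": {"none": 549 / 651, "one or more": 102 / 651},
        "sf36_class": {
            "very good/excellent": 99 / 651,
            "good": 310 / 651,
            "fair/poor": 242 / 651,
        },
        "allocation": {"control": 300 / 651, "intervention": 351 / 651},
        "site": {
            "bristol/bath": 278 / 651,
            "birmingham": 152 / 651,
            "exeter": 221 / 651,
        },
    }


def _default_covariate_effects() -> dict[str, float]:
    # SPPB points; references are the first level of each covariate.
    return {
        "age_per_year": -0.03,        # centred at 77
        "sex[female]": -0.20,
        "comorbidity[one or more]": -0.40,
        "sf36_class[good]": -0.30,
        "sf36_class[fair/poor]": -0.70,
        "education[some college]": 0.05,
        "education[college/degree]": 0.10,
        "imd_per_quintile": 0.03,     # centred at quintile 3
        "site[birmingham]": 0.0,
        "site[exeter]": 0.0,
        "allocation[intervention]": 0.0,
        "intervention_x_time": {6: 0.15, 12: 0.15, 24: 0.10},
    }


@dataclass
class CohortSimConfig:
    """Ground-truth parameters for the longitudinal cohort simulation.

    ``theta_slow_by_period`` / ``theta_fast_by_period`` are the *total*
    stepping-SPPB association at each period, in SPPB points per 1000
    steps/day; the fitted interaction contrast at period *t* therefore
    targets ``theta[t] - theta[0]``. Defaults put those contrasts at
    0.13 (slower-paced) and 0.53 (faster-paced walking) at 24 months.
    """

    n_participants: int = 651
    periods: tuple[int, ...] = (0, 6, 12, 24)
    stepping_means_by_period: Mapping[str, Sequence[float]] = field(
        default_factory=_default_stepping_means)
    stepping_sds_by_period: Mapping[str, Sequence[float]] = field(
        default_factory=_default_stepping_sds)
    theta_slow_by_period: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.03, 6: 0.07, 12: 0.09, 24: 0.16})
    theta_fast_by_period: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 6: 0.27, 12: 0.40, 24: 0.58})
    covariate_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_prevalences)
    covariate_effects: Mapping[str, object] = field(
        default_factory=_default_covariate_effects)
    # The outcome model is linear by construction, so defaults place the
    # cohort where the 0-12 score bounds almost never bind (the source
    # trial likewise recruited below the ceiling); raising the intercept
    # toward the ceiling compresses the high-stepping tail instead.
    intercept: float = 7.0
    var_random_intercept: float = 1.00   # SPPB^2
    var_residual: float = 0.81           # SPPB^2
    between_subject_frac: float = 0.65   # share of stepping variance that is stable
    within_day_sd_frac: float = 0.30     # day-to-day spread around the period mean
    missingness: Sequence[float] = (0.066, 0.132, 0.164, 0.226)
    n_days_per_period: int = 7
    wear_mean_hours: float = 22.8
    wear_sd_hours: float = 0.8
    low_wear_rate: float = 0.03
    age_mean: float = 77.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (65.0, 98.0)
    start_date: dt.date = dt.date(2018, 6, 4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        for name in ("var_random_intercept", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for band, means in self.stepping_means_by_period.items():
            if len(means) != len(self.periods):
                raise ConfigError(
                    f"stepping_means_by_period[{band!r}] must have one entry "
                    "per period")
            if any(m < 0 for m in means):
                raise ConfigError(
                    f"stepping_means_by_period[{band!r}] must be >= 0")
        for cov, levels in self.covariate_prevalences.items():
            total = sum(levels.values())
            if not np.isclose(total, 1.0):
                raise ConfigError(
                    f"covariate_prevalences[{cov!r}] probabilities sum to "
                    f"{total:.4f}, not 1")
        if len(self.missingness) not in (1, len(self.periods)):
            raise ConfigError(
                "missingness must be a scalar sequence or one entry per period")
        if any(not 0 <= m <= 1 for m in self.missingness):
            raise ConfigError("missingness entries must be probabilities")


def simulate_cohort(
    config: CohortSimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a longitudinal cohort with banded daily stepping and SPPB.

    Returns
    -------
    cohort : DataFrame
        One row per participant-period with SPPB and covariates
        (invalid/missing periods are absent).
    daily : DataFrame
        Per participant-period-day banded step counts plus wear hours
        and the calendar date (``device`` is the wrist system
        throughout).
    truth : dict
        Generating parameters, per-participant random intercepts, and
        the realised period-mean stepping table the SPPB outcomes were
        generated from.
    """
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_participants
    periods = list(config.periods)
    bands = list(config.stepping_means_by_period)
    pids = [f"R{i + 1:04d}" for i in range(n)]
    miss = list(config.missingness)
    if len(miss) == 1:
        miss = miss * len(periods)

    # Participant covariates.
    cov_levels = {
        "sex": SEX_LEVELS, "education": EDUCATION_LEVELS,
        "comorbidity": COMORBIDITY_LEVELS, "sf36_class": SF36_LEVELS,
        "allocation": ALLOCATION_LEVELS, "site": SITE_LEVELS,
    }
    covariates = {"participant_id": pids}
    prev = config.covariate_prevalences
    for cov, levels in cov_levels.items():
        probs = np.array([prev[cov][lv] for lv in levels])
        covariates[cov] = list(
            np.array(levels)[rng.choice(len(levels), size=n, p=probs)])
    imd_levels = sorted(prev["imd_quintile"])
    imd_probs = np.array([prev["imd_quintile"][lv] for lv in imd_levels])
    covariates["imd_quintile"] = [
        int(imd_levels[idx]) for idx in rng.choice(len(imd_levels), size=n, p=imd_probs)]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                  *config.age_range)
    covariates["age_at_recruitment"] = np.round(age, 1)
    participants = pd.DataFrame(covariates)

    # Stepping is right-skewed and non-negative: per band each
    # participant-period level is a gamma variate whose mean and SD match
    # the configured period targets exactly, linked across periods by a
    # Gaussian copula with a stable participant component (fraction
    # ``between_subject_frac`` of the latent variance), so activity levels
    # persist within person over follow-up.
    from scipy import stats as _stats

    # A common activity factor correlates the bands within person (active
    # people step more in every band), fattening the total-steps spread.
    band_corr = 0.6
    z_common = rng.normal(size=n)
    z_band = {
        band: band_corr * z_common
        + np.sqrt(1 - band_corr ** 2) * rng.normal(size=n)
        for band in bands
    }
    u_sppb = rng.normal(0.0, np.sqrt(config.var_random_intercept), size=n)

    def _band_level(band: str, p_idx: int, i: int) -> float:
        mean = config.stepping_means_by_period[band][p_idx]
        sd = config.stepping_sds_by_period[band][p_idx]
        if mean <= 0:
            return 0.0
        if sd <= 0:
            return float(mean)
        f = config.between_subject_frac
        z = np.sqrt(f) * z_band[band][i] + np.sqrt(1 - f) * rng.normal()
        shape = (mean / sd) ** 2
        return float(_stats.gamma.ppf(_stats.norm.cdf(z), shape,
                                      scale=sd ** 2 / mean))

    eff = config.covariate_effects
    inter_by_time = eff.get("intervention_x_time", {})

    daily_rows, cohort_rows, period_truth = [], [], []
    for i, pid in enumerate(pids):
        row = participants.iloc[i]
        fixed = config.intercept
        fixed += eff["age_per_year"] * (row["age_at_recruitment"] - config.age_mean)
        fixed += eff["imd_per_quintile"] * (row["imd_quintile"] - 3)
        for key in ("sex", "comorbidity", "sf36_class", "education", "site",
                    "allocation"):
            label = f"{key}[{row[key]}]"
            fixed += eff.get(label, 0.0)
        for p_idx, period in enumerate(periods):
            if rng.random() < miss[p_idx]:
                continue
            period_level = {band: _band_level(band, p_idx, i) for band in bands}

            period_start = config.start_date + dt.timedelta(
                days=int(round(period * 30.44)))
            day_records = []
            for d in range(config.n_days_per_period):
                date = period_start + dt.timedelta(days=d)
                if rng.random() < config.low_wear_rate:
                    hours = float(rng.uniform(5.0, 17.9))
                else:
                    hours = float(min(24.0, 24.0 - abs(
                        rng.normal(24.0 - config.wear_mean_hours,
                                   config.wear_sd_hours))))
                rec = {
                    "participant_id": pid,
                    "device": "wrist",
                    "period": period,
                    "date": date,
                    "wear_hours": hours,
                }
                for band in bands:
                    level = period_level[band]
                    if level <= 0:
                        rec[f"{band}_steps"] = 0
                    else:
                        # Gamma day-to-day variation keeps the day mean
                        # unbiased for the period level on a >= 0 support.
                        frac = config.within_day_sd_frac
                        rec[f"{band}_steps"] = int(round(
                            rng.gamma(1.0 / frac ** 2, level * frac ** 2)))
                day_records.append(rec)
            daily_rows.extend(day_records)

            # SPPB is generated from the period-mean stepping over *valid*
            # days (>= 18 h wear), exactly what the pipeline recomputes.
            valid = [r for r in day_records if r["wear_hours"] >= 18.0]
            if len(valid) < 6:
                continue  # period fails the wear rule; no outcome row
            mean_slow_paced = float(np.mean(
                [r["non_walking_steps"] + r["slower_walking_steps"] for r in valid]))
            mean_fast = float(np.mean([r["faster_walking_steps"] for r in valid]))
            theta_s = config.theta_slow_by_period[period]
            theta_f = config.theta_fast_by_period[period]
            linpred = (fixed
                       + (inter_by_time.get(period, 0.0)
                          if row["allocation"] == "intervention" else 0.0)
                       + theta_s * mean_slow_paced / 1000.0
                       + theta_f * mean_fast / 1000.0
                       + u_sppb[i])
            sppb = linpred + rng.normal(0.0, np.sqrt(config.var_residual))
            sppb = int(np.clip(round(sppb), 0, 12))
            cohort_rows.append(
                {
                    "participant_id": pid,
                    "period": period,
                    "sppb": sppb,
                    **{k: row[k] for k in (
                        "age_at_recruitment", "sex", "imd_quintile", "education",
                        "comorbidity", "sf36_class", "allocation", "site")},
                }
            )
            period_truth.append(
                {
                    "participant_id": pid,
                    "period": period,
                    "slower_paced_steps": mean_slow_paced,
                    "faster_walking_steps": mean_fast,
                    "linpred": float(linpred),
                }
            )

    daily = pd.DataFrame(daily_rows)
    if len(daily):
        daily["slower_paced_steps"] = (
            daily["non_walking_steps"] + daily["slower_walking_steps"])
        daily["total_steps"] = (
            daily["slower_paced_steps"] + daily["faster_walking_steps"])
        daily["walking_steps"] = (
            daily["slower_walking_steps"] + daily["faster_walking_steps"])
    cohort = pd.DataFrame(cohort_rows)
    truth = {
        "theta_slow_by_period": dict(config.theta_slow_by_period),
        "theta_fast_by_period": dict(config.theta_fast_by_period),
        "random_intercepts": pd.Series(u_sppb, index=pids),
        "period_stepping": pd.DataFrame(period_truth),
        "config": config,
    }
    return cohort, daily, truth
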
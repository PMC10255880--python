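"""Longitudinal association between stepping and physical function.

Physical function is the Short Physical Performance Battery (SPPB,
integer 0-12) measured at months 0, 6, 12, and 24. Its association with
daily stepping is estimated with linear mixed-effects models: a random
intercept per participant, fixed effects for the covariates (age, sex,
site, trial-arm allocation and its interaction with time, perceived
general health, comorbidity, deprivation quintile, education), time as a
categorical factor with baseline reference, and stepping terms scaled to
1000 steps/day together with stepping x time interactions. Three model
variants differ only in which stepping variables they carry:

* Model 1 — total steps (20-175 steps/min);
* Model 2 — faster-paced walking steps only;
* Model 3 — faster-paced walking steps and slower-paced steps, two
  non-overlapping cadence bands that partition the daily total.

A follow-up stepping coefficient is the interaction contrast relative
to baseline; the *total* association at time *t* is the baseline
coefficient plus that contrast. Coefficients and confidence intervals
use restricted-likelihood variance estimation with large-sample normal
inference; model comparison (AIC, log-likelihood) uses full-likelihood
refits because restricted-likelihood criteria are not comparable across
different fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationSpec",
    "AssociationResult",
    "AssociationError",
    "Scenario",
    "MODEL_STEPPING_TERMS",
    "fit_association",
    "total_effect",
    "stepping_time_wald",
    "project_scenario",
    "relative_increase",
    "sensitivity_suite",
]

MODEL_STEPPING_TERMS: dict[int, tuple[str, ...]] = {
    1: ("total_steps",),
    2: ("faster_walking_steps",),
    3: ("faster_walking_steps", "slower_paced_steps"),
}

HEALTH_COVARIATES = ("sf36_class", "comorbidity", "imd_quintile", "education")
BASE_COVARIATES = ("age_at_recruitment", "sex", "site", "allocation")


class AssociationError(RuntimeError):
    """The association model could not be estimated on the given data."""


@dataclass
class AssociationSpec:
    """Which model to fit and with what adjustments."""

    model_id: int = 3
    include_health_covariates: bool = True
    step_scale: float = 1000.0
    reml: bool = True
    min_periods: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_STEPPING_TERMS:
            raise ValueError("model_id must be 1, 2, or 3")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")

    @property
    def stepping_terms(self) -> tuple[str, ...]:
        return MODEL_STEPPING_TERMS[self.model_id]


@dataclass
class AssociationResult:
    model_id: int
    coefficients: pd.DataFrame     # stepping term x time contrasts
    covariates: pd.DataFrame       # remaining fixed effects
    var_random_intercept: float
    var_residual: float
    aic: float                     # full-likelihood
    loglik: float                  # full-likelihood
    n_participants: int
    n_participant_periods: int
    periods: tuple[int, ...]
    step_scale: float
    fe_params: pd.Series = field(repr=False, default=None)
    fe_cov: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class Scenario:
    """A hypothetical change in daily stepping, in thousands of steps/day,
    combined with stepping coefficients in SPPB points per 1000 steps."""

    delta_slower: float
    delta_faster: float
    theta_slower: float
    theta_faster: float


_SHORT = {
    "total_steps": "total_k",
    "faster_walking_steps": "faster_k",
    "slower_paced_steps": "slower_paced_k",
}


def _prepare(data: pd.DataFrame, spec: AssociationSpec) -> pd.DataFrame:
    needed = (["participant_id", "period", "sppb"] + list(BASE_COVARIATES)
              + (list(HEALTH_COVARIATES) if spec.include_health_covariates else [])
              + list(spec.stepping_terms))
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise AssociationError(f"association table is missing column(s) {missing}")
    frame = data[needed].dropna().copy()
    counts = frame.groupby("participant_id")["period"].nunique()
    keep = counts.index[counts >= spec.min_periods]
    frame = frame[frame["participant_id"].isin(keep)].reset_index(drop=True)
    if frame.empty:
        raise AssociationError(
            f"no participants with >= {spec.min_periods} valid periods")
    for term in spec.stepping_terms:
        frame[_SHORT[term]] = frame[term] / spec.step_scale
    return frame


def _formula(spec: AssociationSpec) -> str:
    parts = ["C(period) * C(allocation)"]
    for term in spec.stepping_terms:
        parts.append(f"{_SHORT[term]} * C(period)")
    parts += ["age_at_recruitment", "C(sex)", "C(site)"]
    if spec.include_health_covariates:
        parts += ["C(sf36_class)", "C(comorbidity)", "C(imd_quintile)",
                  "C(education)"]
    return "sppb ~ " + " + ".join(parts)


def _check_rank(model) -> None:
    exog = np.asarray(model.exog, dtype=float)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        from scipy.linalg import qr

        _, r, piv = qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        aliased = [model.exog_names[piv[i]] for i in range(len(diag))
                   if diag[i] <= tol]
        raise AssociationError(
            "design matrix is rank deficient (empty covariate cell or "
            f"aliased term): {aliased}")


def fit_association(data: pd.DataFrame,
                    spec: AssociationSpec | None = None) -> AssociationResult:
    """Fit one of the three stepping-SPPB mixed models.

    ``data`` holds one row per participant-period: the SPPB outcome,
    the covariates, and period-mean daily stepping in steps/day (the
    model rescales them to thousands). Participants need at least
    ``spec.min_periods`` valid periods to contribute.
    """
    import statsmodels.formula.api as smf

    spec = spec or AssociationSpec()
    frame = _prepare(data, spec)
    formula = _formula(spec)

    def _robust_fit(reml: bool):
        last_exc = None
        for methods in (["lbfgs", "bfgs"], ["cg"], ["powell"], ["nm"]):
            model = smf.mixedlm(formula, frame, groups=frame["participant_id"])
            try:
                candidate = model.fit(reml=reml, method=methods)
            except Exception as exc:  # singular Hessian, optimizer failure
                last_exc = exc
                continue
            if candidate.converged:
                return candidate
        raise AssociationError(
            f"mixed-model estimation failed: {last_exc or 'no optimizer converged'}"
        ) from last_exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, frame, groups=frame["participant_id"])
        _check_rank(model)
        fit = _robust_fit(spec.reml)
        fit_ml = fit if not spec.reml else _robust_fit(False)
    fe = fit.fe_params
    bse = fit.bse_fe
    z = stats.norm.ppf(1 - spec.alpha / 2)
    periods = tuple(sorted(frame["period"].unique()))

    rows = []
    for term in spec.stepping_terms:
        short = _SHORT[term]
        for period in periods:
            name = short if period == periods[0] else \
                f"{short}:C(period)[T.{period}]"
            if name not in fe.index:
                raise AssociationError(f"expected coefficient {name!r} not found")
            est, se = float(fe[name]), float(bse[name])
            pval = 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
            rows.append(
                {
                    "term": term,
                    "period": period,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                    "p_value": pval,
                    "is_baseline": period == periods[0],
                }
            )
    coef = pd.DataFrame(rows)

    stepping_names = set(coef.apply(
        lambda r: _SHORT[r["term"]] if r["is_baseline"]
        else f"{_SHORT[r['term']]}:C(period)[T.{r['period']}]", axis=1))
    cov_rows = []
    for name in fe.index:
        if name in stepping_names:
            continue
        est, se = float(fe[name]), float(bse[name])
        cov_rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "p_value": 2 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan,
            }
        )

    k_params = len(fit_ml.fe_params) + 2  # + random-intercept and residual var
    loglik = float(fit_ml.llf)
    fe_cov = pd.DataFrame(
        np.asarray(fit.cov_params())[:len(fe), :len(fe)],
        index=fe.index, columns=fe.index)
    return AssociationResult(
        model_id=spec.model_id,
        coefficients=coef,
        covariates=pd.DataFrame(cov_rows),
        var_random_intercept=float(fit.cov_re.iloc[0, 0]),
        var_residual=float(fit.scale),
        aic=2 * k_params - 2 * loglik,
        loglik=loglik,
        n_participants=int(frame["participant_id"].nunique()),
        n_participant_periods=len(frame),
        periods=periods,
        step_scale=spec.step_scale,
        fe_params=fe,
        fe_cov=fe_cov,
    )


def total_effect(result: AssociationResult, term: str, period: int) -> float:
    """Total association at ``period``: baseline coefficient plus the
    interaction contrast (the contrast alone at baseline is zero)."""
    coef = result.coefficients
    match = coef[(coef["term"] == term) & (coef["period"] == period)]
    if match.empty:
        known_terms = sorted(coef["term"].unique())
        raise KeyError(
            f"no coefficient for term {term!r} at period {period}; "
            f"model {result.model_id} has terms {known_terms} at periods "
            f"{list(result.periods)}")
    row = match.iloc[0]
    if row["is_baseline"]:
        return float(row["estimate"])
    baseline = coef[(coef["term"] == term) & coef["is_baseline"]].iloc[0]
    return float(baseline["estimate"] + row["estimate"])


def stepping_time_wald(result: AssociationResult,
                       term: str | None = None) -> tuple[float, int, float]:
    """Joint Wald chi-square test that all stepping x time interaction
    contrasts are zero. Returns ``(statistic, df, p_value)``."""
    coef = result.coefficients
    mask = ~coef["is_baseline"]
    if term is not None:
        mask &= coef["term"] == term
    names = [
        f"{_SHORT[r['term']]}:C(period)[T.{r['period']}]"
        for _, r in coef[mask].iterrows()
    ]
    if not names:
        raise AssociationError("no interaction contrasts to test")
    b = result.fe_params[names].to_numpy()
    v = result.fe_cov.loc[names, names].to_numpy()
    stat = float(b @ np.linalg.solve(v, b))
    df = len(names)
    return stat, df, float(stats.chi2.sf(stat, df))


def project_scenario(scenario: Scenario) -> float:
    """Expected SPPB change for a stepping scenario, to 2 decimals.

    ``delta_slower * theta_slower + delta_faster * theta_faster`` with
    deltas in thousands of steps/day and thetas in SPPB points per
    1000 steps/day.
    """
    change = (scenario.delta_slower * scenario.theta_slower
              + scenario.delta_faster * scenario.theta_faster)
    # round half away from zero at 2 decimals (0.465 -> 0.47)
    return float(np.sign(change) * np.floor(abs(change) * 100 + 0.5) / 100)


def relative_increase(step_increase: float, baseline_mean: float) -> int:
    """A step increase as a percentage of the baseline mean, rounded to
    the nearest integer percent."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be > 0")
    return int(np.floor(step_increase / baseline_mean * 100 + 0.5))


def sensitivity_suite(
    data: pd.DataFrame, spec: AssociationSpec | None = None
) -> dict[str, AssociationResult | str]:
    """Primary fit plus the robustness refits.

    Returns a mapping with the primary model, the fit without health and
    socio-economic covariates, and separate fits per allocation arm.
    A stratum too small or degenerate to fit is reported as a string
    reason instead of a result.
    """
    spec = spec or AssociationSpec()
    out: dict[str, AssociationResult | str] = {}
    out["primary"] = fit_association(data, spec)
    try:
        out["no_health_covariates"] = fit_association(
            data, replace(spec, include_health_covariates=False))
    except AssociationError as exc:
        out["no_health_covariates"] = f"skipped: {exc}"
    for arm in sorted(data["allocation"].dropna().unique()):
        stratum = data[data["allocation"] == arm]
        key = f"allocation={arm}"
        if stratum["participant_id"].nunique() < 2:
            out[key] = "skipped: fewer than 2 participants in stratum"
            continue
        try:
            out[key] = fit_association(stratum, spec)
        except AssociationError as exc:
            out[key] = f"skipped: {exc}"
    return out
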
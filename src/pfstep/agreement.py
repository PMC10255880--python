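"""Repeated-measures method agreement via the variance-components CCC.

The concordance correlation coefficient (CCC) measures agreement between
two measurement systems, combining precision (correlation) and accuracy
(systematic bias). For repeated daily measurements on the same
participants the CCC is expressed through the variance components of a
linear mixed model

.. math:: y_{ijk} = \\mu + \\beta_j + \\alpha_i + (\\alpha\\gamma)_{ik}
          + (\\alpha\\beta)_{ij} + \\varepsilon_{ijk}

with participant *i*, device (method) *j*, day *k*; random participant
effects :math:`\\alpha_i \\sim N(0, \\sigma^2_\\alpha)`, participant-day
effects shared between devices
:math:`(\\alpha\\gamma)_{ik} \\sim N(0, \\sigma^2_{\\alpha\\gamma})`,
participant-device interactions
:math:`(\\alpha\\beta)_{ij} \\sim N(0, \\sigma^2_{\\alpha\\beta})`, and a
fixed device offset :math:`\\beta_j`. The agreement index is

.. math:: CCC = \\frac{\\sigma^2_\\alpha + \\sigma^2_{\\alpha\\gamma}}
          {\\sigma^2_\\alpha + \\sigma^2_{\\alpha\\gamma}
           + \\sigma^2_{\\alpha\\beta} + s^2_\\beta + \\sigma^2_\\varepsilon},
          \\qquad s^2_\\beta = (\\beta_{wrist} - \\beta_{thigh})^2 / 2

for two devices. Shared participant and participant-day variation is
concordant; device-linked variation and noise are discordant.

Estimation uses restricted likelihood. For fully balanced designs (every
participant measured by both devices on the same number of days) the
REML solution has a closed form through the balanced ANOVA mean squares,
which this module uses directly; unbalanced data fall back to numerical
REML via :class:`statsmodels` ``MixedLM`` with equivalent structure.
Negative component estimates are truncated at zero, keeping the CCC in
[-1, 1]. Confidence intervals come from a cluster bootstrap that
resamples participants with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgreementSpec",
    "AgreementResult",
    "AgreementError",
    "fit_agreement",
    "ccc_ci",
    "lin_ccc",
    "daily_scatter_stats",
    "variance_share_report",
]

COMPONENT_ORDER = ("subject", "subject_day", "subject_device", "device_bias", "error")


class AgreementError(RuntimeError):
    """The agreement model could not be estimated on the given data."""


@dataclass
class AgreementSpec:
    """What to fit and how.

    ``response`` names the daily band column (``total_steps``,
    ``walking_steps``, ``slower_walking_steps``, ``faster_walking_steps``).
    ``include_subject_day`` / ``include_subject_device`` control the
    random interaction terms; with a single day per participant both must
    be dropped (they are confounded with the residual).
    """

    response: str = "total_steps"
    include_subject_day: bool = True
    include_subject_device: bool = True
    reml: bool = True
    n_bootstrap: int = 500
    seed: int | None = None


@dataclass
class AgreementResult:
    var_subject: float
    var_subject_day: float
    var_subject_device: float
    var_error: float
    device_bias: float            # wrist minus thigh, response units/day
    ccc: float
    pearson_daily: float
    n_participants: int
    n_pairs: int                  # complete participant-device-day pairs / 2
    response: str
    method: str                   # "balanced-anova" or "mixedlm-reml"
    ccc_ci: tuple[float, float] | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def s2_device(self) -> float:
        return self.device_bias ** 2 / 2.0

    @property
    def variance_shares(self) -> dict[str, float]:
        parts = {
            "subject": self.var_subject,
            "subject_day": self.var_subject_day,
            "subject_device": self.var_subject_device,
            "device_bias": self.s2_device,
            "error": self.var_error,
        }
        total = sum(parts.values())
        if total == 0:
            return {k: (1.0 if k == "subject" else 0.0) for k in parts}
        return {k: v / total for k, v in parts.items()}


def _ccc_from_components(var_subject, var_subject_day, var_subject_device,
                         s2_device, var_error) -> float:
    num = var_subject + var_subject_day
    den = num + var_subject_device + s2_device + var_error
    if den == 0:
        return 1.0  # constant data: all pairs identical
    return float(num / den)


def _paired_wide(daily: pd.DataFrame, response: str) -> pd.DataFrame:
    """Complete-pair wide table with columns thigh/wrist per participant-day."""
    if response not in daily.columns:
        raise AgreementError(f"daily table has no column {response!r}")
    devices = sorted(daily["device"].unique())
    if len(devices) != 2:
        raise AgreementError(
            f"agreement needs exactly 2 devices, found {devices}")
    wide = daily.pivot_table(index=["participant_id", "date"], columns="device",
                             values=response, aggfunc="first")
    wide = wide.dropna()
    if len(wide) == 0:
        raise AgreementError("no participant-days with both device values")
    return wide


def _long_from_wide(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack().rename("y").reset_index()
    long.columns = ["participant_id", "date", "device", "y"]
    return long


def _is_balanced(wide: pd.DataFrame) -> bool:
    counts = wide.groupby(level="participant_id").size()
    return counts.nunique() == 1


def _components_balanced(y: np.ndarray, include_day: bool,
                         include_device: bool) -> dict[str, float]:
    """Closed-form balanced-ANOVA (= REML on the interior) estimates.

    ``y`` has shape (n participants, J devices, K days). Mean squares:
    between participants; participant-day (day contrasts averaged over
    devices); participant-device (device contrasts with the fixed device
    effect removed); and the within-cell remainder. Dropped interaction
    terms have their sums of squares pooled into the error.
    """
    n, J, K = y.shape
    if n < 2:
        raise AgreementError("need at least 2 participants")

    grand = y.mean()
    mean_i = y.mean(axis=(1, 2))            # participant means
    mean_ij = y.mean(axis=2)                # participant-device means
    mean_ik = y.mean(axis=1)                # participant-day means
    mean_j = y.mean(axis=(0, 2))            # device means

    ss_subject = J * K * float(((mean_i - grand) ** 2).sum())
    df_subject = n - 1
    ss_day = J * float(((mean_ik - mean_i[:, None]) ** 2).sum())
    df_day = n * (K - 1)
    dev_dev = mean_ij - mean_i[:, None] - (mean_j - grand)[None, :]
    ss_device = K * float((dev_dev ** 2).sum())
    df_device = (n - 1) * (J - 1)
    resid = (y - mean_ij[:, :, None] - mean_ik[:, None, :] + mean_i[:, None, None])
    ss_error = float((resid ** 2).sum())
    df_error = n * (J - 1) * (K - 1)

    if not include_day:
        ss_error += ss_day
        df_error += df_day
    if not include_device:
        ss_error += ss_device
        df_error += df_device

    ms_error = ss_error / df_error if df_error > 0 else 0.0
    var_error = ms_error
    var_day = ((ss_day / df_day - ms_error) / J) if include_day else 0.0
    var_device = ((ss_device / df_device - ms_error) / K) if include_device else 0.0
    ms_subject = ss_subject / df_subject
    var_subject = (ms_subject - ms_error
                   - (J * var_day if include_day else 0.0)
                   - (K * var_device if include_device else 0.0)) / (J * K)
    return {
        "var_subject": max(var_subject, 0.0),
        "var_subject_day": max(var_day, 0.0),
        "var_subject_device": max(var_device, 0.0),
        "var_error": max(var_error, 0.0),
    }


def _components_mixedlm(long: pd.DataFrame, include_day: bool,
                        include_device: bool, reml: bool) -> dict[str, float]:
    import statsmodels.formula.api as smf

    vc = {}
    if include_day:
        vc["subject_day"] = "0 + C(date)"
    if include_device:
        vc["subject_device"] = "0 + C(device)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("y ~ C(device)", long, groups=long["participant_id"],
                            re_formula="1", vc_formula=vc or None)
        try:
            fit = model.fit(reml=reml, method=["lbfgs", "bfgs", "cg"])
        except Exception as exc:  # pragma: no cover - optimizer failure path
            raise AgreementError(f"mixed-model estimation failed: {exc}") from exc
    if not fit.converged:
        raise AgreementError(
            "mixed-model estimation did not converge; "
            f"gradient norm diagnostics: {getattr(fit, 'hist', None)}")
    comp = {
        "var_subject": float(fit.cov_re.iloc[0, 0]),
        "var_subject_day": 0.0,
        "var_subject_device": 0.0,
        "var_error": float(fit.scale),
    }
    for name, value in zip(vc, np.atleast_1d(fit.vcomp)):
        comp[f"var_{name}"] = float(value)
    return {k: max(v, 0.0) for k, v in comp.items()}


def _fit_once(wide: pd.DataFrame, spec: AgreementSpec) -> tuple[dict, float, str]:
    devices = list(wide.columns)
    bias = float(wide[devices[-1]].mean() - wide[devices[0]].mean())
    if _is_balanced(wide):
        counts = wide.groupby(level="participant_id").size()
        n, K = len(counts), int(counts.iloc[0])
        # With a single day per participant both interaction terms are
        # confounded with the residual; they are dropped automatically.
        include_day = spec.include_subject_day and K >= 2
        include_device = spec.include_subject_device and K >= 2
        y = np.empty((n, 2, K))
        for idx, (_, grp) in enumerate(wide.groupby(level="participant_id")):
            y[idx] = grp.to_numpy().T
        comp = _components_balanced(y, include_day, include_device)
        return comp, bias, "balanced-anova"
    comp = _components_mixedlm(_long_from_wide(wide), spec.include_subject_day,
                               spec.include_subject_device, spec.reml)
    return comp, bias, "mixedlm-reml"


def fit_agreement(daily: pd.DataFrame, spec: AgreementSpec | None = None,
                  ci: bool = False) -> AgreementResult:
    """Estimate the repeated-measures CCC for one daily band.

    Parameters
    ----------
    daily : DataFrame
        Long daily aggregates with ``participant_id, device, date`` and
        the band columns; only complete participant-days (both devices)
        enter the model.
    spec : AgreementSpec
        Model structure, estimation, and bootstrap settings.
    ci : bool
        Also compute the cluster-bootstrap confidence interval
        (equivalent to calling :func:`ccc_ci`).
    """
    spec = spec or AgreementSpec()
    wide = _paired_wide(daily, spec.response)
    n_participants = wide.index.get_level_values("participant_id").nunique()
    if n_participants < 2:
        raise AgreementError("need at least 2 participants with paired days")

    comp, bias, method = _fit_once(wide, spec)
    s2_device = bias ** 2 / 2.0
    ccc = _ccc_from_components(comp["var_subject"], comp["var_subject_day"],
                               comp["var_subject_device"], s2_device,
                               comp["var_error"])
    cols = list(wide.columns)
    pearson = float(np.corrcoef(wide[cols[0]], wide[cols[1]])[0, 1]) \
        if wide[cols[0]].std() > 0 and wide[cols[1]].std() > 0 else (
            1.0 if np.allclose(wide[cols[0]], wide[cols[1]]) else np.nan)
    result = AgreementResult(
        var_subject=comp["var_subject"],
        var_subject_day=comp["var_subject_day"],
        var_subject_device=comp["var_subject_device"],
        var_error=comp["var_error"],
        device_bias=bias,
        ccc=ccc,
        pearson_daily=pearson,
        n_participants=int(n_participants),
        n_pairs=len(wide),
        response=spec.response,
        method=method,
    )
    if ci:
        result.ccc_ci = ccc_ci(daily, spec, _wide=wide, _result=result)
    return result


def ccc_ci(daily: pd.DataFrame, spec: AgreementSpec | None = None,
           _wide: pd.DataFrame | None = None,
           _result: AgreementResult | None = None) -> tuple[float, float]:
    """Percentile cluster-bootstrap 95% CI for the CCC.

    Participants are resampled with replacement (each draw becomes a new
    cluster), the model is refitted per replicate, and the 2.5/97.5
    percentiles of the replicate CCCs form the interval. Deterministic
    for a fixed ``spec.seed``. If more than 20% of replicates fail to
    converge a warning is recorded on the result (when supplied).
    """
    spec = spec or AgreementSpec()
    wide = _wide if _wide is not None else _paired_wide(daily, spec.response)
    rng = np.random.default_rng(spec.seed)
    pids = wide.index.get_level_values("participant_id").unique().to_numpy()

    if _is_balanced(wide):
        # Resample participants directly on the (n, device, day) array;
        # every replicate stays balanced, so the closed form applies.
        counts = wide.groupby(level="participant_id").size()
        n, K = len(counts), int(counts.iloc[0])
        include_day = spec.include_subject_day and K >= 2
        include_device = spec.include_subject_device and K >= 2
        y = np.empty((n, 2, K))
        for idx, (_, grp) in enumerate(wide.groupby(level="participant_id")):
            y[idx] = grp.to_numpy().T
        cccs = []
        for _ in range(spec.n_bootstrap):
            yb = y[rng.integers(0, n, size=n)]
            comp = _components_balanced(yb, include_day, include_device)
            bias = float(yb[:, 1].mean() - yb[:, 0].mean())
            cccs.append(_ccc_from_components(
                comp["var_subject"], comp["var_subject_day"],
                comp["var_subject_device"], bias ** 2 / 2.0,
                comp["var_error"]))
        lo, hi = np.percentile(cccs, [2.5, 97.5])
        return float(lo), float(hi)

    groups = {pid: grp.droplevel("participant_id")
              for pid, grp in wide.groupby(level="participant_id")}

    cccs, failures = [], 0
    for _ in range(spec.n_bootstrap):
        chosen = rng.choice(pids, size=len(pids), replace=True)
        parts = []
        for clone, pid in enumerate(chosen):
            block = groups[pid].copy()
            block.index = pd.MultiIndex.from_product(
                [[f"b{clone}"], block.index], names=["participant_id", "date"])
            parts.append(block)
        boot = pd.concat(parts)
        try:
            comp, bias, _ = _fit_once(boot, spec)
        except AgreementError:
            failures += 1
            continue
        cccs.append(_ccc_from_components(
            comp["var_subject"], comp["var_subject_day"],
            comp["var_subject_device"], bias ** 2 / 2.0, comp["var_error"]))
    if not cccs:
        raise AgreementError("all bootstrap replicates failed")
    if failures > 0.2 * spec.n_bootstrap and _result is not None:
        _result.warnings.append(
            f"{failures}/{spec.n_bootstrap} bootstrap replicates failed to fit")
    lo, hi = np.percentile(cccs, [2.5, 97.5])
    return float(lo), float(hi)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's moment concordance correlation coefficient.

    ``2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)`` with biased
    (1/n) moment estimators. Used as the single-replicate oracle for the
    variance-components estimator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2 = np.mean((x - x.mean()) ** 2)
    sy2 = np.mean((y - y.mean()) ** 2)
    den = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if den == 0:
        return 1.0
    return float(2 * sxy / den)


def daily_scatter_stats(daily: pd.DataFrame,
                        responses: list[str] | None = None) -> pd.DataFrame:
    """Paired-day summary per band: Pearson correlation and deviation
    from the line of identity (each point is one participant-day)."""
    responses = responses or ["total_steps", "walking_steps",
                              "slower_walking_steps", "faster_walking_steps"]
    rows = []
    for response in responses:
        wide = _paired_wide(daily, response)
        if len(wide) < 3:
            raise AgreementError(
                f"{response}: need >= 3 paired days for scatter statistics")
        cols = list(wide.columns)
        x, y = wide[cols[0]].to_numpy(float), wide[cols[1]].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            pcc = 1.0 if np.allclose(x, y) else np.nan
        else:
            pcc = float(np.corrcoef(x, y)[0, 1])
        diff = y - x
        rows.append(
            {
                "response": response,
                "n_days": len(wide),
                "pearson": pcc,
                "mean_diff": float(diff.mean()),
                "sd_diff": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
                "rmse_identity": float(np.sqrt(np.mean(diff ** 2))),
            }
        )
    return pd.DataFrame(rows)


def variance_share_report(result: AgreementResult) -> pd.DataFrame:
    """Variance components as ordered shares of total disagreement."""
    shares = result.variance_shares
    values = {
        "subject": result.var_subject,
        "subject_day": result.var_subject_day,
        "subject_device": result.var_subject_device,
        "device_bias": result.s2_device,
        "error": result.var_error,
    }
    table = pd.DataFrame(
        {
            "component": list(COMPONENT_ORDER),
            "variance": [values[c] for c in COMPONENT_ORDER],
            "share": [shares[c] for c in COMPONENT_ORDER],
        }
    )
    return table.sort_values("share", ascending=False, kind="stable").reset_index(
        drop=True)
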
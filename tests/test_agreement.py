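"""Variance-components CCC: oracles, invariants, intervals, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pfstep.agreement import (
    AgreementError,
    AgreementSpec,
    ccc_ci,
    daily_scatter_stats,
    fit_agreement,
    lin_ccc,
    variance_share_report,
)
from pfstep.simulate import PairedSimConfig, simulate_paired_daily


def spec(**kw) -> AgreementSpec:
    kw.setdefault("response", "total_steps")
    kw.setdefault("n_bootstrap", 0)
    return AgreementSpec(**kw)


def perfect_daily(n=6, k=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for d in range(k):
            y = int(rng.integers(3000, 12000))
            for device in ("thigh", "wrist"):
                rows.append({"participant_id": f"P{i}", "device": device,
                             "date": d, "total_steps": y})
    return pd.DataFrame(rows)


class TestCCCOracles:
    def test_perfect_agreement_is_one(self):
        daily = perfect_daily()
        result = fit_agreement(daily, spec())
        assert result.ccc == pytest.approx(1.0, abs=1e-12)
        assert result.pearson_daily == pytest.approx(1.0)
        lo, hi = ccc_ci(daily, spec(n_bootstrap=50, seed=1))
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_matches_lin_moment_ccc_single_replicate(self):
        """Balanced one-day-per-participant data: the variance-components
        CCC equals Lin's moment formula within 0.01 at n = 200."""
        config = PairedSimConfig(
            n_participants=200, n_days=1, var_subject=9e5, var_day=0.0,
            var_subject_device=0.0, var_error=3e5, device_bias=400.0, seed=21)
        daily, _ = simulate_paired_daily(config)
        result = fit_agreement(daily, spec(include_subject_day=False))
        wide = daily.pivot_table(index=["participant_id", "date"],
                                 columns="device", values="total_steps")
        assert result.ccc == pytest.approx(
            lin_ccc(wide["thigh"], wide["wrist"]), abs=0.01)

    def test_closed_form_agrees_with_numerical_reml(self):
        """Dual route: the balanced closed form and statsmodels MixedLM
        estimate the same model; their CCCs agree."""
        from pfstep.agreement import _components_mixedlm, _long_from_wide, \
            _paired_wide

        config = PairedSimConfig(n_participants=25, n_days=4, seed=33)
        daily, _ = simulate_paired_daily(config)
        result = fit_agreement(daily, spec())
        assert result.method == "balanced-anova"
        wide = _paired_wide(daily, "total_steps")
        comp = _components_mixedlm(_long_from_wide(wide), True, True, True)
        bias = result.device_bias
        num = comp["var_subject"] + comp["var_subject_day"]
        den = num + comp["var_subject_device"] + bias ** 2 / 2 + comp["var_error"]
        assert result.ccc == pytest.approx(num / den, abs=0.01)

    def test_known_components_give_expected_ccc(self):
        """Generating components (9, 0, 0.5, 0.5)e5 with zero bias imply
        CCC = 0.90; a single 56 x 7 estimate lands nearby."""
        config = PairedSimConfig(
            n_participants=56, n_days=7, var_subject=9e5, var_day=0.0,
            var_subject_device=0.5e5, var_error=0.5e5, device_bias=0.0, seed=3)
        daily, _ = simulate_paired_daily(config)
        result = fit_agreement(daily, spec())
        assert result.ccc == pytest.approx(0.90, abs=0.05)

    def test_zero_bias_zero_device_matches_icc(self):
        """Without device effects the CCC is the intraclass correlation
        computed analytically from the generating components."""
        components = dict(var_subject=8e5, var_day=4e5,
                          var_subject_device=0.0, var_error=2e5)
        config = PairedSimConfig(n_participants=300, n_days=7,
                                 device_bias=0.0, seed=51, **components)
        daily, _ = simulate_paired_daily(config)
        result = fit_agreement(daily, spec())
        icc = (8e5 + 4e5) / (8e5 + 4e5 + 2e5)
        assert result.ccc == pytest.approx(icc, abs=0.02)


class TestCCCInvariants:
    def test_bias_monotonically_reduces_ccc(self):
        """Adding a larger fixed device offset to the same latent data
        strictly decreases the estimated CCC."""
        base, _ = simulate_paired_daily(
            PairedSimConfig(n_participants=56, n_days=7, device_bias=0.0,
                            seed=61))
        cccs = []
        for bias in (0.0, 1000.0, 2500.0, 5000.0):
            shifted = base.copy()
            wrist = shifted["device"] == "wrist"
            shifted.loc[wrist, "total_steps"] += int(bias)
            cccs.append(fit_agreement(shifted, spec()).ccc)
        assert all(a > b for a, b in zip(cccs, cccs[1:]))

    def test_bounded_on_arbitrary_data(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            rows = []
            for i in range(4):
                for d in range(3):
                    for device in ("thigh", "wrist"):
                        rows.append({
                            "participant_id": f"P{i}", "device": device,
                            "date": d,
                            "total_steps": float(rng.normal(0, 10 ** trial)),
                        })
            result = fit_agreement(pd.DataFrame(rows), spec())
            assert -1.0 <= result.ccc <= 1.0

    def test_requires_two_devices_and_two_participants(self):
        daily = perfect_daily(n=1)
        with pytest.raises(AgreementError, match="2 participants"):
            fit_agreement(daily, spec())
        single = perfect_daily()
        with pytest.raises(AgreementError, match="2 devices"):
            fit_agreement(single[single["device"] == "wrist"], spec())


class TestBootstrapCI:
    def test_null_data_interval_sits_at_zero(self):
        """Independent devices: no concordance. Because negative variance
        estimates are truncated at zero the CCC estimator is non-negative,
        so the interval's lower edge sits at ~0 and the whole interval
        stays near zero."""
        rng = np.random.default_rng(5)
        rows = []
        for i in range(60):
            for d in range(5):
                for device in ("thigh", "wrist"):
                    rows.append({"participant_id": f"P{i}", "device": device,
                                 "date": d,
                                 "total_steps": float(rng.normal(9000, 3000))})
        daily = pd.DataFrame(rows)
        lo, hi = ccc_ci(daily, spec(n_bootstrap=300, seed=2))
        assert lo == pytest.approx(0.0, abs=0.02)
        assert hi < 0.15
        assert fit_agreement(daily, spec()).ccc == pytest.approx(0.0, abs=0.05)

    def test_deterministic_per_seed(self, paired_daily):
        daily, _ = paired_daily
        a = ccc_ci(daily, spec(n_bootstrap=100, seed=4))
        b = ccc_ci(daily, spec(n_bootstrap=100, seed=4))
        c = ccc_ci(daily, spec(n_bootstrap=100, seed=5))
        assert a == b and a != c

    def test_unbalanced_panel_uses_numerical_reml(self):
        """Dropping one participant-day forces the numerical-REML route;
        the bootstrap still yields a sane interval around the estimate."""
        daily, _ = simulate_paired_daily(
            PairedSimConfig(n_participants=8, n_days=3, seed=13))
        unbalanced = daily.drop(index=daily.index[:2]).reset_index(drop=True)
        result = fit_agreement(unbalanced, spec())
        assert result.method == "mixedlm-reml"
        lo, hi = ccc_ci(unbalanced, spec(n_bootstrap=20, seed=3))
        assert -1 <= lo <= hi <= 1

    def test_interval_brackets_point_estimate(self, paired_daily):
        daily, _ = paired_daily
        result = fit_agreement(daily, spec(n_bootstrap=200, seed=8), ci=True)
        lo, hi = result.ccc_ci
        assert lo <= result.ccc <= hi


class TestReporting:
    def test_scatter_stats_hand_examples(self):
        rows = []
        for i, (x, y) in enumerate([(1, 3), (2, 2), (3, 1)]):
            rows.append({"participant_id": f"P{i}", "device": "thigh",
                         "date": 0, "total_steps": x})
            rows.append({"participant_id": f"P{i}", "device": "wrist",
                         "date": 0, "total_steps": y})
        out = daily_scatter_stats(pd.DataFrame(rows), ["total_steps"])
        assert out["pearson"].iloc[0] == pytest.approx(-1.0)

    def test_scatter_matches_scipy_oracle(self, paired_daily):
        daily, _ = paired_daily
        out = daily_scatter_stats(daily, ["total_steps"])
        wide = daily.pivot_table(index=["participant_id", "date"],
                                 columns="device", values="total_steps").dropna()
        expect, _ = stats.pearsonr(wide["thigh"], wide["wrist"])
        assert out["pearson"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_scatter_needs_three_pairs(self):
        daily = perfect_daily(n=2, k=1)
        with pytest.raises(AgreementError, match=">= 3 paired days"):
            daily_scatter_stats(daily, ["total_steps"])

    def test_variance_shares_sum_to_one(self, paired_daily):
        daily, truth = paired_daily
        result = fit_agreement(daily, spec())
        table = variance_share_report(result)
        assert table["share"].sum() == pytest.approx(1.0)
        assert (table["share"] >= 0).all()
        # defaults put participants first, then day-to-day behaviour
        assert table["component"].iloc[0] == "subject"
        assert table["component"].iloc[1] == "subject_day"

    def test_known_components_give_expected_shares(self):
        """Components (9, 6, 0.5, 0.5) with no bias imply shares
        (0.5625, 0.375, 0.03125, 0, 0.03125)."""
        config = PairedSimConfig(
            n_participants=400, n_days=7, var_subject=9e5, var_day=6e5,
            var_subject_device=0.5e5, var_error=0.5e5, device_bias=0.0,
            seed=71)
        daily, _ = simulate_paired_daily(config)
        result = fit_agreement(daily, spec())
        shares = result.variance_shares
        assert shares["subject"] == pytest.approx(0.5625, abs=0.04)
        assert shares["subject_day"] == pytest.approx(0.375, abs=0.04)
        assert shares["subject_device"] == pytest.approx(0.03125, abs=0.02)
        assert shares["error"] == pytest.approx(0.03125, abs=0.02)

    def test_degenerate_constant_data(self):
        rows = [{"participant_id": f"P{i}", "device": dev, "date": d,
                 "total_steps": 5000}
                for i in range(3) for dev in ("thigh", "wrist") for d in range(2)]
        result = fit_agreement(pd.DataFrame(rows), spec())
        assert result.ccc == 1.0
        assert result.variance_shares["subject"] == 1.0
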
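"""Event filtering, validity rules, cadence banding, and the biomarker."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfstep import banding
from pfstep.banding import CadenceBands, filter_events, pfstep

from conftest import make_events


def _ev(pid, day, steps, cadence, device="wrist"):
    duration = steps / cadence * 60.0
    return (pid, device, f"2022-03-{7 + day:02d}T10:00:00", duration, steps)


class TestFilterEvents:
    def test_rule_counts_on_mixed_fixture(self):
        """2 low-step, 1 slow, 1 fast, 1 beyond-day-7 events are removed;
        counts match an exhaustive per-event check."""
        rows = [
            _ev("A", 0, 9, 60),          # < 10 steps
            _ev("A", 0, 5, 80),          # < 10 steps
            _ev("A", 1, 50, 19.0),       # cadence < 20
            _ev("A", 2, 50, 176.0),      # cadence > 175
            _ev("A", 0, 100, 60),
            _ev("A", 1, 100, 70),
            _ev("A", 2, 100, 80),
            _ev("A", 3, 100, 90),
            _ev("A", 4, 100, 100),
            _ev("A", 7, 100, 60),        # 8th distinct date
        ]
        events = make_events(rows)
        # brute force: dates for A are days 0,1,2,3,4,7 (6 distinct) plus
        # none beyond; max_days=5 keeps dates up to the 5th distinct date
        kept, report = filter_events(events, max_days=5)
        expect_kept = {(100, 60.0), (100, 70.0), (100, 80.0), (100, 90.0),
                       (100, 100.0)}
        got = {(s, round(c, 6)) for s, c in zip(kept["steps"], kept["cadence"])}
        assert got == expect_kept
        assert report.removed_low_steps == 2
        assert report.removed_low_cadence == 1
        assert report.removed_high_cadence == 1
        assert report.removed_extra_days == 1
        assert report.n_input == report.n_kept + 5

    @pytest.mark.parametrize("cadence,kept", [(20.0, True), (175.0, True),
                                              (19.99, False), (175.01, False)])
    def test_cadence_boundaries_inclusive(self, cadence, kept):
        events = make_events([_ev("A", 0, 50, cadence)])
        out, _ = filter_events(events)
        assert (len(out) == 1) is kept

    def test_wear_dates_count_toward_first_days(self):
        """A wear-only date occupies a slot in the first-days window."""
        events = make_events([_ev("A", 3, 100, 60)])
        wear = pd.DataFrame(
            {
                "participant_id": ["A"] * 3,
                "device": ["wrist"] * 3,
                "date": [dt.date(2022, 3, 7 + d) for d in range(3)],
                "wear_hours": [23.0] * 3,
            }
        )
        out, report = filter_events(events, max_days=3, wear=wear)
        assert len(out) == 0 and report.removed_extra_days == 1

    def test_idempotent(self, small_paired):
        events, wear, _ = small_paired
        once, r1 = filter_events(events, wear=wear)
        twice, r2 = filter_events(once, wear=wear)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.n_input == r2.n_kept

    def test_invalid_events_do_not_change_aggregates(self, small_paired):
        """Appending filter-violating events leaves daily sums unchanged."""
        events, wear, _ = small_paired
        extra = make_events([_ev("P001", 0, 5, 60), _ev("P001", 1, 50, 10.0),
                             _ev("P001", 2, 50, 200.0)])
        kept_a, _ = filter_events(events, wear=wear)
        kept_b, _ = filter_events(
            pd.concat([events, extra], ignore_index=True), wear=wear)
        bands = CadenceBands().with_median(75.0)
        agg_a = banding.aggregate_daily(kept_a, bands)
        agg_b = banding.aggregate_daily(kept_b, bands)
        pd.testing.assert_frame_equal(agg_a, agg_b)


class TestValidity:
    def test_paired_day_requires_both_devices(self):
        wear = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B", "B"],
                "device": ["thigh", "wrist"] * 2,
                "date": [dt.date(2022, 3, 7)] * 4,
                "wear_hours": [21.0, 19.5, 20.0, 20.0],
            }
        )
        valid = banding.valid_days_paired(wear)
        assert ("A", dt.date(2022, 3, 7)) not in valid
        assert ("B", dt.date(2022, 3, 7)) in valid  # exactly 20 h is enough

    def test_paired_days_match_set_oracle(self, small_paired):
        _, wear, _ = small_paired
        valid = banding.valid_days_paired(wear, min_hours=20.0)
        oracle = set()
        for (pid, date), grp in wear.groupby(["participant_id", "date"]):
            ok = grp.set_index("device")["wear_hours"]
            if len(ok) == 2 and (ok >= 20.0).all():
                oracle.add((pid, date))
        assert valid == oracle

    @pytest.mark.parametrize(
        "hours,days,valid",
        [(18.0, 6, True), (17.9, 7, False), (18.5, 5, False)],
    )
    def test_cohort_period_rule_boundaries(self, hours, days, valid):
        wear = pd.DataFrame(
            {
                "participant_id": ["A"] * days,
                "device": ["wrist"] * days,
                "period": [0] * days,
                "date": [dt.date(2022, 3, 7 + d) for d in range(days)],
                "wear_hours": [hours] * days,
            }
        )
        got = banding.valid_period_cohort(wear)
        assert (("A", 0) in got) is valid

    def test_cohort_periods_match_counting_oracle(self, small_cohort):
        _, daily, _, _ = small_cohort
        wear = daily[["participant_id", "device", "period", "date", "wear_hours"]]
        valid = banding.valid_period_cohort(wear)
        oracle = {
            (pid, period)
            for (pid, period), grp in wear.groupby(["participant_id", "period"])
            if (grp["wear_hours"] >= 18.0).sum() >= 6
        }
        assert valid == oracle


class TestMedianCadence:
    def test_constant_and_textbook_median(self):
        events = make_events([_ev("A", 0, 50, c) for c in (50, 60, 70, 80)])
        assert banding.median_walking_cadence(events) == 65.0
        constant = make_events([_ev("A", 0, 50, 77.0)] * 3)
        assert banding.median_walking_cadence(constant) == pytest.approx(77.0)

    def test_sub_threshold_events_ignored(self):
        events = make_events(
            [_ev("A", 0, 50, 30), _ev("A", 0, 50, 44.9), _ev("A", 0, 50, 90)])
        assert banding.median_walking_cadence(events) == pytest.approx(90.0)

    def test_no_walking_events_is_an_error(self):
        events = make_events([_ev("A", 0, 50, 30.0)])
        with pytest.raises(ValueError, match="no walking events"):
            banding.median_walking_cadence(events)

    def test_invariant_to_order_and_duplication(self, small_paired):
        events, _, _ = small_paired
        m = banding.median_walking_cadence(events)
        shuffled = events.sample(frac=1, random_state=3).reset_index(drop=True)
        doubled = pd.concat([events, events], ignore_index=True)
        assert banding.median_walking_cadence(shuffled) == pytest.approx(m)
        assert banding.median_walking_cadence(doubled) == pytest.approx(m)


class TestAggregateDaily:
    def test_event_above_median_is_faster_paced(self):
        events = make_events([_ev("A", 0, 100, 80.0)])
        bands = CadenceBands().with_median(76.0)
        daily = banding.aggregate_daily(events, bands)
        row = daily.iloc[0]
        assert row["faster_walking_steps"] == 100
        assert row["slower_walking_steps"] == 0
        assert row["total_steps"] == 100

    def test_no_valid_days_gives_empty(self):
        events = make_events([_ev("A", 0, 100, 80.0)])
        daily = banding.aggregate_daily(
            events, CadenceBands().with_median(76.0), valid_days=set())
        assert len(daily) == 0

    def test_band_sums_match_per_event_assignment(self):
        """12 events over 2 days: band sums equal a brute-force loop."""
        rng = np.random.default_rng(5)
        rows = []
        for day in range(2):
            for _ in range(6):
                cadence = float(rng.uniform(20, 175))
                rows.append(_ev("A", day, int(rng.integers(10, 200)), cadence))
        events = make_events(rows)
        median = 74.0
        daily = banding.aggregate_daily(events, CadenceBands().with_median(median))
        for _, row in daily.iterrows():
            day_events = events[pd.to_datetime(events["start"]).dt.date
                                == row["date"]]
            nw = sw = fw = 0
            for _, e in day_events.iterrows():
                if e["cadence"] < 45:
                    nw += e["steps"]
                elif e["cadence"] <= median:
                    sw += e["steps"]
                else:
                    fw += e["steps"]
            assert (row["non_walking_steps"], row["slower_walking_steps"],
                    row["faster_walking_steps"]) == (nw, sw, fw)

    def test_band_partition_conservation(self, small_paired):
        """Every kept event lands in exactly one band: band sums rebuild
        the exact integer totals for all bands on simulated data."""
        events, wear, _ = small_paired
        kept, _ = filter_events(events, wear=wear)
        bands = {
            device: CadenceBands().with_median(
                banding.median_walking_cadence(grp))
            for device, grp in kept.groupby("device")
        }
        daily = banding.aggregate_daily(kept, bands)
        assert (daily["total_steps"]
                == daily["non_walking_steps"] + daily["walking_steps"]).all()
        assert (daily["walking_steps"] == daily["slower_walking_steps"]
                + daily["faster_walking_steps"]).all()
        assert (daily["total_steps"] == daily["slower_paced_steps"]
                + daily["faster_walking_steps"]).all()
        assert daily["total_steps"].sum() == kept["steps"].sum()

    def test_zero_fill_for_valid_day_without_events(self):
        events = make_events([_ev("A", 0, 100, 80.0, device="thigh"),
                              _ev("A", 0, 90, 80.0, device="wrist")])
        valid = {("A", dt.date(2022, 3, 7)), ("A", dt.date(2022, 3, 8))}
        daily = banding.aggregate_daily(
            events, CadenceBands().with_median(76.0), valid_days=valid)
        assert len(daily) == 4  # 2 devices x 2 valid days
        day2 = daily[daily["date"] == dt.date(2022, 3, 8)]
        assert (day2["total_steps"] == 0).all()


class TestAggregatePeriod:
    def test_single_day_and_two_day_mean(self):
        daily = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B"],
                "period": [0, 0, 0],
                **{c: [4000, 6000, 1234] if c == "total_steps" else [0, 0, 0]
                   for c in banding.BAND_COLUMNS},
            }
        )
        out = banding.aggregate_period(daily)
        assert out.loc[out["participant_id"] == "A", "total_steps"].iloc[0] == 5000
        assert out.loc[out["participant_id"] == "B", "total_steps"].iloc[0] == 1234

    def test_matches_brute_force_means(self, small_cohort):
        _, daily, _, _ = small_cohort
        good = daily[daily["wear_hours"] >= 18.0]
        out = banding.aggregate_period(good)
        sample = out.sample(10, random_state=0)
        for _, row in sample.iterrows():
            grp = good[(good["participant_id"] == row["participant_id"])
                       & (good["period"] == row["period"])]
            assert row["faster_walking_steps"] == pytest.approx(
                grp["faster_walking_steps"].mean())
            assert row["n_days"] == len(grp)


class TestPfStep:
    def test_reference_rendering(self):
        bm = pfstep(6931.0, 428.0, split_cadence=62.0)
        assert (bm.slower_paced_steps, bm.faster_paced_steps) == (6931, 428)
        assert bm.render() == "(6931; 428)"
        assert pfstep(0.0, 0.0, 62.0).render() == "(0; 0)"

    def test_tie_adjustment_preserves_total(self):
        bm = pfstep(100.5, 100.5, 62.0)
        assert bm.total_steps == 201

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        slower=st.floats(0, 2e4, allow_nan=False),
        faster=st.floats(0, 1e4, allow_nan=False),
    )
    def test_components_always_sum_to_rounded_total(self, slower, faster):
        bm = pfstep(slower, faster, 62.0)
        assert bm.total_steps == int(np.floor(slower + faster + 0.5))
        assert bm.slower_paced_steps >= 0 and bm.faster_paced_steps >= 0


class TestPeriodChange:
    # Published-style period means, used here purely as numeric inputs.
    BASELINE = {"total_steps": 5815.0, "slower_paced_steps": 4923.0,
                "faster_walking_steps": 892.0}
    MONTH24 = {"total_steps": 4871.0, "slower_paced_steps": 4215.0,
               "faster_walking_steps": 656.0}

    def test_declines_and_percents(self):
        out = banding.period_change(self.BASELINE, self.MONTH24)
        by_band = out.set_index("band")
        assert by_band.loc["total_steps", "change"] == 944
        assert by_band.loc["slower_paced_steps", "change"] == 708
        assert by_band.loc["faster_walking_steps", "change"] == 236
        assert by_band.loc["total_steps", "percent"] == 16
        assert by_band.loc["faster_walking_steps", "percent"] == 26

    def test_identical_summaries_zero_change(self):
        out = banding.period_change(self.BASELINE, self.BASELINE)
        assert (out["change"] == 0).all() and (out["percent"] == 0).all()

    def test_zero_baseline_flagged(self):
        out = banding.period_change({"b": 0.0}, {"b": 10.0})
        assert not out["percent_defined"].iloc[0]
        assert np.isnan(out["percent"].iloc[0])
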
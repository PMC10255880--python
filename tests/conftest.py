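"""Shared fixtures: small simulated datasets reused across test modules."""

import pandas as pd
import pytest

from pfstep.simulate import (
    CohortSimConfig,
    PairedSimConfig,
    simulate_cohort,
    simulate_paired_daily,
    simulate_paired_events,
)


@pytest.fixture(scope="session")
def small_paired():
    """A small paired-device event study (10 participants x 5 days)."""
    config = PairedSimConfig(n_participants=10, n_days=5, seed=42)
    events, wear, truth = simulate_paired_events(config)
    return events, wear, truth


@pytest.fixture(scope="session")
def paired_daily():
    """Balanced paired daily totals at study scale (56 x 7), no events."""
    daily, truth = simulate_paired_daily(PairedSimConfig(seed=7))
    return daily, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (150 participants) with its analysis table."""
    from pfstep.pipeline import cohort_analysis_table

    config = CohortSimConfig(n_participants=150, seed=11)
    cohort, daily, truth = simulate_cohort(config)
    merged = cohort_analysis_table(cohort, daily)
    return cohort, daily, merged, truth


def make_events(rows):
    """Build a validated-looking event frame from (pid, device, start,
    duration_s, steps) tuples, deriving cadence."""
    frame = pd.DataFrame(
        rows, columns=["participant_id", "device", "start", "duration_s", "steps"])
    frame["start"] = pd.to_datetime(frame["start"])
    frame["cadence"] = frame["steps"] / (frame["duration_s"] / 60.0)
    return frame
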
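import numpy as np
import pandas as pd
import pytest

from faerspv.io import DrugMention, SafetyReport
from faerspv.simulate import (
    InjectedEffect,
    SimConfig,
    fixture_table1_case_table,
    simulate_case_truth,
    truth_to_case_table,
)


def make_report(
    primary_id="1001",
    case_id="100",
    fda_date="20200101",
    event_date=None,
    drugs=(),
    pts=(("Hepatic failure", None),),
    outcomes=(),
    **kwargs,
):
    """Handcraft a SafetyReport for unit tests."""
    return SafetyReport(
        primary_id=primary_id,
        case_id=case_id,
        fda_date=fda_date,
        event_date=event_date,
        drugs=[DrugMention(*d) if isinstance(d, tuple) else d for d in drugs],
        reaction_pts=frozenset(pts),
        outcomes=frozenset(outcomes),
        **kwargs,
    )


@pytest.fixture(scope="session")
def table1_cases() -> pd.DataFrame:
    """The deterministic 654-case published-table fixture, run through the
    real ingestion path (assemble -> dedup -> classify)."""
    return fixture_table1_case_table()


def study_config(theta: float, seed: int, n_cases: int = 50_000) -> SimConfig:
    """Simulation-study conditions for calibration/recovery experiments:
    one drug at 8% exposure, 2% background event rate, injected odds ratio
    theta."""
    return SimConfig(
        n_cases=n_cases,
        background_event_rate=0.02,
        drug_exposure_rates={"nivolumab": 0.08},
        injected_effects=[InjectedEffect("any", theta)],
        combo_rate=0.0,
        concomitant_profiles={},
        duplicate_rate=0.0,
        partial_date_rate=0.0,
        seed=seed,
    )


def replicate_signals(theta: float, n_reps: int, base_seed: int, n_cases: int = 50_000):
    """Run the screen on ``n_reps`` independent simulated databases and
    return the per-replicate SignalResults for the any-ICI vs rest contrast."""
    from faerspv.signals import build_table, signal_from_table

    seeds = np.random.SeedSequence(base_seed).generate_state(n_reps) % (2**31)
    results = []
    for s in seeds:
        cfg = study_config(theta, int(s), n_cases)
        case_table = truth_to_case_table(simulate_case_truth(cfg))
        results.append(
            signal_from_table(build_table(case_table, "class_vs_all", "any"))
        )
    return results
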
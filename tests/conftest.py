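import numpy as np
import pytest

from optobias import SimConfig, compute_delta_r, generate_sessions


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no injected behavioral shift (s0 = 0) but real neural
    suppression on laser trials; delta_r attached."""
    cfg = SimConfig(n_sessions=6, trials_per_session=900, s0=0.0, seed=101)
    table, _, truth = generate_sessions(cfg)
    df, _ = compute_delta_r(table.trials)
    return df, truth


@pytest.fixture(scope="session")
def shifted_cohort():
    """Cohort with a constant -3% coh injected shift on laser trials."""
    cfg = SimConfig(n_sessions=10, trials_per_session=1000, s0=-3.0, seed=202)
    table, _, truth = generate_sessions(cfg)
    df, _ = compute_delta_r(table.trials)
    return df, truth


@pytest.fixture(scope="session")
def tiny_table():
    """Six hand-written valid trials across two sessions."""
    import pandas as pd

    from optobias import TrialTable

    rows = [
        # session, T, C, D, laser, ts, outcome, correct, rewarded, count
        ("A", 1, 51.2, 400.0, 0, 0, "pref_choice", 1.0, 1, 20),
        ("A", 2, -12.8, 300.0, 1, 1, "sure_bet", np.nan, 1, 9),
        ("A", 3, 0.0, 200.0, 0, 1, "null_choice", np.nan, 0, 8),
        ("B", 1, 6.4, 500.0, 1, 0, "null_choice", 0.0, 0, 12),
        ("B", 2, -25.6, 150.0, 0, 1, "pref_choice", 0.0, 0, 5),
        ("B", 3, 3.2, 925.0, 1, 1, "pref_choice", 1.0, 1, 30),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "session_id", "trial_index", "signed_coherence", "duration_ms",
            "laser_on", "ts_available", "outcome", "correct", "rewarded",
            "mu_count",
        ],
    )
    df["mu_rate"] = df["mu_count"] / (df["duration_ms"] / 1000.0)
    return TrialTable(df)
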
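import numpy as np
import pandas as pd
import pytest

from blinksdt import (DesignConfig, EEGGenConfig, default_truth, generate_eeg_dataset,
                      generate_trial_design, simulate_responses, tabulate_responses)


@pytest.fixture(scope="session")
def blink_truth():
    """Generating parameters of the synthetic cohort (Model III structure)."""
    return default_truth()


@pytest.fixture(scope="session")
def session_records(blink_truth):
    """One simulated 936-trial session of 3-AFC responses."""
    design = generate_trial_design(DesignConfig(), seed=101)
    return simulate_responses(blink_truth, design, t1_accuracy=0.875, seed=102)


@pytest.fixture(scope="session")
def contingency(session_records):
    return tabulate_responses(session_records)


def balanced_design(n_per_lag: int, lags=(100, 300, 500, 700, 900)) -> pd.DataFrame:
    """Fully balanced design: 2/3 present split over 4 cells, 1/3 absent."""
    rows = []
    for lag in lags:
        n_present = int(round(n_per_lag * 2 / 3))
        per_cell = n_present // 4
        for state in ("CW", "CCW"):
            for contrast in ("low", "high"):
                rows += [(lag, state, contrast)] * per_cell
        rows += [(lag, "absent", None)] * (n_per_lag - 4 * per_cell)
    return pd.DataFrame(rows, columns=["lag_ms", "t2_state", "contrast"])


@pytest.fixture(scope="session")
def small_eeg(session_records):
    """300-trial synthetic EEG dataset with the default planted markers."""
    rng = np.random.default_rng(7)
    take = np.sort(rng.choice(len(session_records), size=300, replace=False))
    return generate_eeg_dataset(session_records.iloc[take], EEGGenConfig(), seed=8)
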
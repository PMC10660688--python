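import numpy as np
import pandas as pd
import pytest

from rarliver.synthetic import RhythmTruth, simulate_actigraphy


@pytest.fixture(scope="session")
def default_truth():
    return RhythmTruth.with_nadir_sleep(
        minimum=10.0, amplitude=100.0, acrophase=14.0, alpha=0.0, beta=8.0,
        noise_sd=5.0, n_days=7)


@pytest.fixture(scope="session")
def simulated_epochs(default_truth):
    """One participant's 7-day minute series with moderate noise."""
    return simulate_actigraphy(default_truth, participant_id=1, seed=42)


@pytest.fixture(scope="session")
def simulated_bins(simulated_epochs):
    from rarliver.actigraphy import aggregate_5min, classify_valid_days

    validity = classify_valid_days(simulated_epochs)
    return aggregate_5min(simulated_epochs, validity)


@pytest.fixture(scope="session")
def simulated_fit(simulated_bins):
    from rarliver.cosinor import ExtendedCosineModel

    return ExtendedCosineModel.from_bins(simulated_bins).fit()


def make_epochs(participant_id=1, n_days=1, activity=1.0, state="wake"):
    """Minimal epoch frame with uniform activity and state."""
    n = 1440 * n_days
    minute = np.arange(n) % 1440
    return pd.DataFrame({
        "participant_id": participant_id,
        "day_index": np.arange(n) // 1440 + 1,
        "minute_of_day": minute,
        "activity": np.full(n, activity, dtype=float),
        "state": state,
    })


@pytest.fixture
def epoch_builder():
    return make_epochs
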
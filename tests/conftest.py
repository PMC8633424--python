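import numpy as np
import pytest

from metanoise import (
    GenerativeParams,
    discretize_confidence,
    sigma_for_accuracy,
    simulate_session,
)
from metanoise.measures import RatingCounts


def session_counts(accuracy, sigma_m, n_trials, rng, k=6):
    """Simulate one session and tabulate its rating counts."""
    params = GenerativeParams(1.0, sigma_for_accuracy(accuracy), sigma_m)
    trials = simulate_session(params, n_trials, rng)
    ratings = discretize_confidence(trials["confidence"].to_numpy(), k)
    return RatingCounts.from_trials(trials["stimulus"], trials["choice"], ratings, k)


@pytest.fixture(scope="session")
def ideal_session():
    """A large noiseless-metacognition session (sigma_m = 0) at 80% accuracy."""
    rng = np.random.default_rng(11)
    params = GenerativeParams(1.0, sigma_for_accuracy(0.8), 0.0)
    return simulate_session(params, 100_000, rng)
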
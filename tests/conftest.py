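import numpy as np
import pytest

from traceddm.measures import aggregate
from traceddm.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants x 40 trials: enough for pipeline-level tests."""
    cfg = CohortConfig(n_participants=12, n_trials=40)
    trials, truth = generate_cohort(cfg, seed=11)
    return trials, truth


@pytest.fixture(scope="session")
def participant_table(small_cohort):
    """Participant-level measures joined to the true DDM parameters."""
    trials, truth = small_cohort
    pm = aggregate(trials)
    table = pm.merge(
        truth.participants[["participant", "v", "a", "t0"]], on="participant"
    )
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
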
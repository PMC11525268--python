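import numpy as np
import pytest

from srmotion import CohortConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort shared by experiment/inference tests."""
    config = CohortConfig(n_recruited=60)
    participants, block1, block2 = generate_dataset(config, seed=77)
    kept = participants[~participants.excluded]
    trials = block2[block2.participant_id.isin(kept.participant_id)]
    return {"config": config, "participants": participants, "kept": kept,
            "block1": block1, "block2": trials}
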
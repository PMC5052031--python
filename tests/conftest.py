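import pandas as pd
import pytest

from nts.io_core import SessionDataset
from nts.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_coding_dataset():
    """Small all-epoch cohort with sustained value coding (shared, read-only)."""
    cfg = GeneratorConfig(
        n_neurons={"DLPFC": 4, "OFC": 4, "ACC": 4},
        n_trials=80,
        coding_profile="sustained",
        seed=2024,
    )
    ds, truth = generate_dataset(cfg)
    return cfg, ds, truth


@pytest.fixture()
def tiny_dataset():
    """Hand-built dataset: one neuron, three trials, known spike times."""
    spikes = pd.DataFrame(
        {
            "neuron_id": ["n1"] * 4,
            "trial_id": [0, 0, 1, 2],
            "event": ["fixation_on"] * 4,
            "spike_time": [0.049, 0.050, 0.999, 1.000],
        }
    )
    trials = pd.DataFrame(
        {
            "session_id": "S1",
            "trial_id": [0, 1, 2],
            "trial_index_in_session": [0, 1, 2],
            "completed": True,
            "chosen_value": [1.0, 2.0, 3.0],
            "chosen_benefit": [2.0, 3.0, 4.0],
            "chosen_cost": [1.0, 1.0, 1.0],
        }
    )
    neurons = pd.DataFrame(
        {"neuron_id": ["n1"], "session_id": ["S1"], "area": ["OFC"]}
    )
    return SessionDataset(spikes=spikes, trials=trials, neurons=neurons)
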
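import numpy as np
import pytest

import reachlearn as rl
from reachlearn import synth


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulated experiment shared across tests."""
    return rl.SimConfig(
        trials_per_session=12,
        neuron_counts={"type1_pn": 2, "type2_pn": 4, "type3_pn": 3,
                       "interneuron": 2},
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def day0_session(small_config):
    kin, table = synth.generate_session_kinematics(small_config, 0, 0)
    trains, gt = synth.generate_ensemble_spikes(small_config, kin, 0, session=0)
    wfs = synth.generate_waveform_series(small_config, trains)
    return {"kin": kin, "table": table, "trains": trains, "gt": gt, "wfs": wfs}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
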
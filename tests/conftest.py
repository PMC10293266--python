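import numpy as np
import pytest

from deltatrack.synthetic import SyntheticConfig, gen_delta_neuron, gen_tonic_neuron


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Two short trials: enough structure for unit tests, fast to generate."""
    return SyntheticConfig(seed=11, n_trials=2, trial_len_ms=8000.0)


@pytest.fixture(scope="session")
def delta_neuron(small_cfg):
    return gen_delta_neuron(small_cfg)


@pytest.fixture(scope="session")
def tonic_neuron(small_cfg):
    return gen_tonic_neuron(small_cfg)


def match_spikes(detected_ms, truth_ms, tol_ms=2.0):
    """(sensitivity, precision) of detected vs true spike times."""
    detected_ms = np.asarray(detected_ms)
    truth_ms = np.asarray(truth_ms)
    if truth_ms.size == 0 or detected_ms.size == 0:
        return 0.0, 0.0
    d = np.abs(detected_ms[:, None] - truth_ms[None, :])
    sens = float((d.min(axis=0) <= tol_ms).mean())
    prec = float((d.min(axis=1) <= tol_ms).mean())
    return sens, prec
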
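import numpy as np
import pytest

from glidernet import network as net


@pytest.fixture(scope="session")
def tiny_net():
    """A small untrained network for probing-surface tests."""
    params = net.init_network(6, 5, 1, seed=0)
    model = net.RecurrentFormAnalysis(
        np.zeros((1, 256)), np.zeros((1, 5, 1)), 6, 5
    )
    return net.RFAMResults(
        model, params, {"epoch": np.array([]), "probe_error": np.array([])},
        net.TrainConfig(n_epochs=1),
    )
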
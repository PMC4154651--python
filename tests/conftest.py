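import numpy as np
import pytest

import burstnet as bn


@pytest.fixture
def three_node_burst_train():
    """One burst: nodes a, b, c igniting at 0, 0.03, 0.08 s."""
    return bn.EventTrain(
        np.array(["a", "b", "c"], dtype=object), np.array([0.0, 0.03, 0.08])
    )


@pytest.fixture
def planted_net():
    return bn.generate_planted_network(
        30, 5, target_assortativity=0.5, seed=0, weight_sigma=0.25
    )


@pytest.fixture
def small_random_net():
    rng = np.random.default_rng(7)
    w = rng.random((8, 8)) * (rng.random((8, 8)) < 0.4)
    np.fill_diagonal(w, 0)
    return bn.DirectedWeightedNetwork([f"n{i}" for i in range(8)], w)
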
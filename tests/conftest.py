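import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scworkflow import build_experiment

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_exp():
    """3 genes x 2 cells with gene3 as a control set (hand-checkable)."""
    counts = np.array([[10, 0], [5, 5], [0, 1]])
    exp = build_experiment(counts, ["gene1", "gene2", "gene3"], ["c1", "c2"])
    exp.control_sets["ctrl"] = np.array([False, False, True])
    return exp


@pytest.fixture
def spiked_exp(rng):
    """20 genes + 5 spikes x 30 cells with declared spike set."""
    counts = rng.poisson(20, size=(25, 30))
    ids = [f"g{i}" for i in range(20)] + [f"ERCC-{i}" for i in range(5)]
    exp = build_experiment(counts, ids, None)
    mask = np.zeros(25, dtype=bool)
    mask[20:] = True
    exp.control_sets["ERCC"] = mask
    exp.declare_spike_set("ERCC", general_use=False)
    return exp
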
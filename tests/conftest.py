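from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtpaths.network import load_network
from mtpaths.objective import ObjectiveParams
from mtpaths.synth import SynthConfig, generate_instance


@pytest.fixture
def chain_edge_table() -> pd.DataFrame:
    """S -A- B -> T chain plus a branch, probabilities chosen by hand."""
    return pd.DataFrame(
        [
            ("S", "A", 0.9, "ppi"),
            ("A", "B", 0.8, "ppi"),
            ("B", "T", 0.9, "regulatory"),
            ("S", "C", 0.5, "ppi"),
            ("C", "T", 0.4, "regulatory"),
        ],
        columns=["node_a", "node_b", "probability", "edge_type"],
    )


@pytest.fixture
def chain_network(chain_edge_table):
    return load_network(chain_edge_table)


@pytest.fixture
def default_params() -> ObjectiveParams:
    return ObjectiveParams()


@pytest.fixture(scope="session")
def small_instance():
    """One default synthetic instance shared by read-only tests."""
    return generate_instance(SynthConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
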
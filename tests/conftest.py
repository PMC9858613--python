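import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cimap.cohort import Cohort, VariableDictionary, VariableSpec
from cimap.fixtures import paper_network, table1_fixture
from cimap.network import CPT, GroundTruthNetwork


@pytest.fixture(scope="session")
def paper_net():
    return paper_network()


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def make_binary_cohort(columns: dict) -> Cohort:
    """Cohort of 0/1-valued columns from python lists (None = missing)."""
    specs = [
        VariableSpec(name, "binary", ("0", "1")) for name in columns
    ]
    data = pd.DataFrame(
        {k: [None if v is None else str(v) for v in vals] for k, vals in columns.items()},
        dtype=object,
    )
    return Cohort(data, VariableDictionary(specs))


def chain_network(p_root=0.5, flip=0.1) -> GroundTruthNetwork:
    """x -> z -> y chain of binaries with strong CPTs (flip = noise rate)."""
    specs = [VariableSpec(n, "binary", ("0", "1")) for n in ("x", "y", "z")]
    cond = np.array([[1 - flip, flip], [flip, 1 - flip]])
    cpts = {
        "x": CPT("x", (), np.array([1 - p_root, p_root])),
        "z": CPT("z", ("x",), cond),
        "y": CPT("y", ("z",), cond),
    }
    return GroundTruthNetwork(VariableDictionary(specs), cpts)
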
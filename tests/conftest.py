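import numpy as np
import pytest

from twinconn.io_model import (
    BinaryFCMatrix,
    ParcellationLabels,
    TwinPair,
    TwinPairManifest,
    WeightedFCMatrix,
)


@pytest.fixture
def parc4() -> ParcellationLabels:
    return ParcellationLabels(("A", "B", "C", "D"))


@pytest.fixture
def small_manifest() -> TwinPairManifest:
    return TwinPairManifest(
        (
            TwinPair("MZ001", "MZ", "s1", "s2", 14.5, "F"),
            TwinPair("DZ001", "DZ", "s3", "s4", 22.0, "M"),
        )
    )


def binary_from_graph(g, parcellation=None):
    """BinaryFCMatrix from a networkx graph (nodes must be 0..n-1)."""
    import networkx as nx

    n = g.number_of_nodes()
    parc = parcellation or ParcellationLabels(tuple(f"R{i}" for i in range(n)))
    return BinaryFCMatrix(nx.to_numpy_array(g), parc)


def weighted_from_array(values, parcellation=None):
    values = np.asarray(values, dtype=float)
    parc = parcellation or ParcellationLabels(
        tuple(f"R{i}" for i in range(values.shape[0]))
    )
    return WeightedFCMatrix(values, parc)
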
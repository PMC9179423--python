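import numpy as np
import pytest

from markermine.model import (
    PathwayDB,
    PathwayRecord,
    RegulatoryNetwork,
    TFInteraction,
)


@pytest.fixture
def small_network():
    return RegulatoryNetwork(
        [
            TFInteraction("TFX", "S1", "activation"),
            TFInteraction("TFY", "S1", "repression"),
            TFInteraction("TFY", "S2"),
            TFInteraction("TFX", "G1"),
            TFInteraction("TFX", "G2"),
            TFInteraction("TFY", "G2"),
            TFInteraction("TFZ", "G3"),
        ]
    )


@pytest.fixture
def small_db():
    return PathwayDB(
        [
            PathwayRecord("P1", "small with seed", frozenset({"S1", "G1", "G4"})),
            PathwayRecord("P2", "no seeds", frozenset({"G5", "G6"})),
            PathwayRecord("P3", "second seed", frozenset({"S2", "G2"})),
        ]
    )


def random_network(rng: np.random.Generator, n_tfs=20, n_genes=60, n_edges=200):
    tfs = [f"TF{i}" for i in range(n_tfs)]
    genes = [f"G{i}" for i in range(n_genes)]
    edges = set()
    while len(edges) < n_edges:
        edges.add((str(rng.choice(tfs)), str(rng.choice(genes))))
    return RegulatoryNetwork(TFInteraction(t, g) for t, g in sorted(edges))


def random_pathway_db(rng: np.random.Generator, n_pathways=30, n_genes=80):
    genes = [f"G{i}" for i in range(n_genes)]
    records = []
    for i in range(n_pathways):
        size = int(rng.integers(1, 25))
        members = frozenset(map(str, rng.choice(genes, size=size, replace=False)))
        records.append(PathwayRecord(f"P{i}", f"pathway {i}", members))
    return PathwayDB(records)
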
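from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from immunome_net.core import CellSample
from immunome_net.network import SignedNetwork
from immunome_net.simulate import CohortSimSpec, PanelSpec, SubsetSpec


def make_signed_network(n_nodes, signed_edges, lineages=None, threshold=0.6):
    """Build a SignedNetwork directly from (u, v, r) triples."""
    g = nx.Graph()
    for i in range(n_nodes):
        lin = lineages[i] if lineages is not None else "other"
        g.add_node(i, lineage=lin)
    for u, v, r in signed_edges:
        g.add_edge(u, v, r=float(r), sign=1 if r > 0 else -1)
    return SignedNetwork(graph=g, threshold=threshold)


def random_graph_cases(n_graphs=50, max_n=12, seed=1234):
    """Seeded random graphs (node lists + edge lists) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    cases = []
    while len(cases) < n_graphs:
        n = int(rng.integers(4, max_n + 1))
        p = float(rng.uniform(0.15, 0.7))
        edges = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if len(edges) < 2:
            continue
        cases.append((list(range(n)), edges))
    return cases


def single_panel_spec(corr, n_subsets=None, base=None, sd=0.5, seed=0):
    """Minimal one-panel simulation spec around a given subset-frequency
    correlation matrix (markers are irrelevant for frequency-level tests)."""
    corr = np.asarray(corr, float)
    k = corr.shape[0] if n_subsets is None else n_subsets
    panel = PanelSpec("P1", ("m1", "m2"))
    if base is None:
        base = [1.0 / k] * k
    subsets = tuple(
        SubsetSpec(
            subset_id=f"s{i}",
            lineage="other",
            panel_id="P1",
            mean_profile=(1.0 + i, 2.0),
            dispersion=(0.3, 0.3),
            base_proportion=base[i],
            between_subject_sd=sd,
        )
        for i in range(k)
    )
    return CohortSimSpec(
        panels=(panel,),
        subsets=subsets,
        n_subjects={"A": 10},
        frequency_correlation={"*": corr},
        n_cells_per_sample=100,
        n_batches=1,
        seed=seed,
    )


@pytest.fixture
def toy_sample():
    rng = np.random.default_rng(7)
    return CellSample(
        subject_id="s1",
        cohort="HC",
        batch="0",
        panel="P1",
        matrix=rng.uniform(0, 200, size=(50, 3)),
        marker_names=("CD3", "CD4", "CD8"),
    )
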
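"""Cohort-wise signed correlation networks over node frequencies and the
comparative topology suite.

T/NK nodes from panel 1 and B/monocyte-DC nodes from panel 2 are combined
into one subjects x nodes matrix; within each cohort, node pairs whose
frequency correlation exceeds an absolute threshold (default |r| > 0.6,
strict) become edges carrying the correlation's sign. Topological metrics
(edge density, Freeman betweenness centralization, transitivity,
Newman-Girvan modularity of greedily detected communities, average shortest
path over reachable pairs) are computed on the unweighted, sign-blind
graph; signs contribute only the positive/negative edge counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import FrequencyMatrix, subjects_matching
from .core import B_MYELOID_LINEAGES, T_NK_LINEAGES

__all__ = [
    "CombinedFrequencyMatrix",
    "SignedNetwork",
    "NetworkProperties",
    "combine_panels",
    "correlation_matrix",
    "build_network",
    "edge_density",
    "signed_edge_summary",
    "degree_summary",
    "classify_edges",
    "betweenness_centralization",
    "transitivity",
    "average_path_length",
    "modularity_q",
    "detect_communities",
    "network_properties",
    "network_compare",
]

log = logging.getLogger(__name__)

#: Row order of the comparative property table.
PROPERTY_ROWS = (
    "edge_density",
    "centralization_betweenness",
    "transitivity",
    "modularity",
    "average_path_length",
    "no_neg_edges",
    "no_pos_edges",
)


@dataclass
class CombinedFrequencyMatrix:
    """Panel-combined subjects x nodes frequencies with retained lineages."""

    values: pd.DataFrame  # subjects x node ids (panel-prefixed)
    node_meta: pd.DataFrame  # index node_id; columns panel, lineage
    subject_meta: pd.DataFrame  # index subject_id; column cohort


@dataclass
class SignedNetwork:
    """Undirected graph over phenotype nodes; edges carry the correlation
    value and its sign, nodes carry their lineage."""

    graph: nx.Graph
    threshold: float = 0.6

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def lineage(self, node) -> str:
        return self.graph.nodes[node]["lineage"]


def combine_panels(
    freq_p1: FrequencyMatrix,
    freq_p2: FrequencyMatrix,
    p1_lineages: frozenset[str] = T_NK_LINEAGES,
    p2_lineages: frozenset[str] = B_MYELOID_LINEAGES,
) -> CombinedFrequencyMatrix:
    """Join the two panels' frequency matrices into one analysis matrix.

    Keeps panel-1 nodes of T/NK lineages and panel-2 nodes of B and
    monocyte/DC lineages; subjects are restricted to those measured in both
    panels (others are dropped with a log message). Node ids are prefixed
    with their panel to stay unique.
    """
    shared = freq_p1.values.index.intersection(freq_p2.values.index)
    if len(shared) == 0:
        raise ValueError("no subjects present in both panels")
    dropped = set(freq_p1.values.index).symmetric_difference(freq_p2.values.index)
    if dropped:
        log.info("excluding %d subjects present in only one panel: %s", len(dropped), sorted(dropped))

    parts, meta_parts = [], []
    for freq, keep in ((freq_p1, p1_lineages), (freq_p2, p2_lineages)):
        panel = str(freq.node_meta["panel"].iloc[0])
        cols = freq.node_meta.index[freq.node_meta["lineage"].isin(keep)]
        block = freq.values.loc[shared, cols]
        block.columns = [f"{panel}.{c}" for c in cols]
        parts.append(block)
        nm = freq.node_meta.loc[cols].copy()
        nm.index = block.columns
        meta_parts.append(nm)
    values = pd.concat(parts, axis=1)
    node_meta = pd.concat(meta_parts)
    if node_meta.index.duplicated().any():
        raise ValueError("duplicated node ids after panel combination")
    meta_cols = ["cohort"] + (["group"] if "group" in freq_p1.subject_meta.columns else [])
    return CombinedFrequencyMatrix(
        values=values,
        node_meta=node_meta,
        subject_meta=freq_p1.subject_meta.loc[shared, meta_cols].copy(),
    )


def correlation_matrix(
    freq: CombinedFrequencyMatrix, cohort: str, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise node-frequency correlations within one cohort.

    Zero-variance columns yield NaN correlations (recorded as missing,
    never an edge). ``method`` is "pearson" (default) or "spearman".
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    subjects = subjects_matching(freq.subject_meta, cohort)
    if len(subjects) < 3:
        raise ValueError(f"cohort {cohort!r} has {len(subjects)} subjects; need >= 3")
    sub = freq.values.loc[subjects]
    corr = sub.corr(method=method)
    # pandas fills the diagonal of constant columns with 1; keep those NaN
    const = sub.std().to_numpy() == 0
    corr.iloc[const, :] = np.nan
    corr.iloc[:, const] = np.nan
    return corr


def build_network(
    corr: pd.DataFrame,
    lineages: Mapping[str, str] | pd.Series,
    threshold: float = 0.6,
    strict: bool = True,
) -> SignedNetwork:
    """Threshold a correlation matrix into a signed network.

    Edge (u, v) iff |r_uv| > threshold (or >= when ``strict`` is False);
    isolated nodes are kept. NaN correlations never form edges.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    g = nx.Graph()
    for node in corr.columns:
        g.add_node(node, lineage=str(lineages[node]))
    cols = list(corr.columns)
    mat = corr.to_numpy(float)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = mat[i, j]
            if np.isnan(r):
                continue
            if abs(r) > threshold or (not strict and abs(r) >= threshold):
                g.add_edge(cols[i], cols[j], r=float(r), sign=1 if r > 0 else -1)
    return SignedNetwork(graph=g, threshold=threshold)


def edge_density(net: SignedNetwork) -> float:
    """Edges divided by possible node pairs, m / (n(n-1)/2)."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return net.n_edges / (n * (n - 1) / 2)


def signed_edge_summary(net: SignedNetwork) -> tuple[int, int, float | None]:
    """(n_pos, n_neg, pct_neg); pct_neg is None for an edgeless network."""
    signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    pct = 100.0 * n_neg / len(signs) if signs else None
    return n_pos, n_neg, pct


def degree_summary(net: SignedNetwork) -> tuple[pd.Series, pd.Series]:
    """Per-node degree and per-lineage mean degree (unnormalized counts)."""
    deg = pd.Series(dict(net.graph.degree()), name="degree", dtype=float)
    lin = pd.Series({v: net.lineage(v) for v in net.graph.nodes}, name="lineage")
    by_lineage = deg.groupby(lin).mean()
    by_lineage.name = "mean_degree"
    return deg, by_lineage


def classify_edges(net: SignedNetwork) -> tuple[int, int, pd.DataFrame]:
    """Split edges into intra-lineage vs inter-lineage.

    Returns (intra count, inter count, per-lineage breakdown counting each
    lineage's incident intra and inter edges).
    """
    intra = inter = 0
    rows: dict[str, dict[str, int]] = {}
    for u, v in net.graph.edges:
        lu, lv = net.lineage(u), net.lineage(v)
        if lu is None or lv is None:
            raise ValueError(f"edge ({u}, {v}) touches an unlabeled node")
        kind = "intra" if lu == lv else "inter"
        if kind == "intra":
            intra += 1
        else:
            inter += 1
        for lineage in {lu, lv}:
            rows.setdefault(lineage, {"intra": 0, "inter": 0})[kind] += 1
    breakdown = pd.DataFrame(rows).T.fillna(0).astype(int)
    breakdown.index.name = "lineage"
    return intra, inter, breakdown


def betweenness_centralization(net: SignedNetwork) -> float:
    """Freeman centralization of vertex betweenness.

    Betweenness counts shortest paths on the unweighted graph with the
    endpoints excluded (each unordered pair counted once); the sum of
    (b_max - b_i) is normalized by its maximum over graphs of the same
    order, attained by the star: (n-1)^2 (n-2) / 2.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("betweenness centralization needs at least 3 nodes")
    b = nx.betweenness_centrality(net.graph, normalized=False)
    bmax = max(b.values())
    denom = (n - 1) ** 2 * (n - 2) / 2.0
    return sum(bmax - bi for bi in b.values()) / denom


def transitivity(net: SignedNetwork) -> float | None:
    """Global clustering coefficient, 3 x triangles / connected triples;
    None when the graph has no connected triples."""
    n_triples = sum(d * (d - 1) // 2 for _, d in net.graph.degree())
    if n_triples == 0:
        return None
    return float(nx.transitivity(net.graph))


def average_path_length(net: SignedNetwork) -> float:
    """Mean unweighted shortest-path length over all reachable unordered
    pairs (disconnected pairs are excluded; edge signs are ignored)."""
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(net.graph):
        sub = net.graph.subgraph(comp)
        nc = sub.number_of_nodes()
        if nc < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += nc * (nc - 1) // 2
    if pairs == 0:
        raise ValueError("no reachable pairs (edgeless network)")
    return (total / 2.0) / pairs


def modularity_q(net: SignedNetwork, partition: Mapping) -> float:
    """Newman-Girvan modularity of a node partition on the unweighted graph:
    Q = sum_c [ m_c/m - (d_c / 2m)^2 ]."""
    if net.n_edges == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    missing = set(net.graph.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    groups: dict = {}
    for node, com in partition.items():
        groups.setdefault(com, set()).add(node)
    return float(nx.community.modularity(net.graph, groups.values()))


def detect_communities(net: SignedNetwork, seed: int | None = None) -> dict:
    """Greedy agglomerative modularity maximization (Clauset-Newman-Moore).

    Deterministic for a given graph; ``seed`` is accepted for interface
    symmetry with the stochastic stages. An edgeless graph yields singleton
    communities (Q = 0 by convention). Communities are numbered by their
    smallest node id.
    """
    if net.n_edges == 0:
        return {v: i for i, v in enumerate(sorted(net.graph.nodes))}
    comms = nx.community.greedy_modularity_communities(net.graph)
    comms = sorted(comms, key=lambda c: sorted(c)[0])
    return {v: i for i, c in enumerate(comms) for v in c}


@dataclass
class NetworkProperties:
    """The comparative metric vector for one cohort's network."""

    cohort: str
    n_nodes: int
    n_edges: int
    edge_density: float
    centralization_betweenness: float
    transitivity: float | None
    modularity: float
    average_path_length: float | None
    no_neg_edges: int
    no_pos_edges: int
    pct_neg_edges: float | None
    lineage_mean_degree: dict[str, float] = field(default_factory=dict)
    intra_lineage_edges: int = 0
    inter_lineage_edges: int = 0

    def to_series(self) -> pd.Series:
        base = {
            "edge_density": self.edge_density,
            "centralization_betweenness": self.centralization_betweenness,
            "transitivity": self.transitivity,
            "modularity": self.modularity,
            "average_path_length": self.average_path_length,
            "no_neg_edges": self.no_neg_edges,
            "no_pos_edges": self.no_pos_edges,
            "pct_neg_edges": self.pct_neg_edges,
            "intra_lineage_edges": self.intra_lineage_edges,
            "inter_lineage_edges": self.inter_lineage_edges,
        }
        for lineage, d in sorted(self.lineage_mean_degree.items()):
            base[f"mean_degree_{lineage}"] = d
        return pd.Series(base, name=self.cohort)


def network_properties(net: SignedNetwork, cohort: str = "") -> NetworkProperties:
    """Compute the full property vector for one network."""
    n_pos, n_neg, pct_neg = signed_edge_summary(net)
    intra, inter, _ = classify_edges(net)
    _, lineage_deg = degree_summary(net)
    partition = detect_communities(net)
    q = modularity_q(net, partition) if net.n_edges else 0.0
    return NetworkProperties(
        cohort=cohort,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        edge_density=edge_density(net),
        centralization_betweenness=betweenness_centralization(net),
        transitivity=transitivity(net),
        modularity=q,
        average_path_length=average_path_length(net) if net.n_edges else None,
        no_neg_edges=n_neg,
        no_pos_edges=n_pos,
        pct_neg_edges=pct_neg,
        lineage_mean_degree=lineage_deg.to_dict(),
        intra_lineage_edges=intra,
        inter_lineage_edges=inter,
    )


def network_compare(
    freq: CombinedFrequencyMatrix,
    cohorts: Sequence[str] = ("HC", "HF"),
    threshold: float = 0.6,
    strict: bool = True,
    method: str = "pearson",
) -> tuple[dict[str, SignedNetwork], pd.DataFrame]:
    """Build each cohort's network and tabulate properties side by side.

    Returns the networks and a DataFrame whose leading rows follow the
    standard comparative layout (edge_density, centralization_betweenness,
    transitivity, modularity, average_path_length, no_neg_edges,
    no_pos_edges) followed by the extensions, one column per cohort plus a
    delta column (first minus second) when exactly two cohorts are given.
    """
    nets: dict[str, SignedNetwork] = {}
    columns = []
    for cohort in cohorts:
        corr = correlation_matrix(freq, cohort, method=method)
        net = build_network(corr, freq.node_meta["lineage"], threshold=threshold, strict=strict)
        nets[cohort] = net
        columns.append(network_properties(net, cohort).to_series())
    table = pd.concat(columns, axis=1)
    lead = [r for r in PROPERTY_ROWS if r in table.index]
    rest = [r for r in table.index if r not in PROPERTY_ROWS]
    table = table.loc[lead + rest]
    if len(cohorts) == 2:
        table["delta"] = table[cohorts[0]] - table[cohorts[1]]
    table.index.name = "property"
    return nets, table
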
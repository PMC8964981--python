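"""Signed correlation networks and the topology suite, cross-checked against
brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import make_signed_network, random_graph_cases, single_panel_spec
from immunome_net.abundance import FrequencyMatrix
from immunome_net.network import (
    CombinedFrequencyMatrix,
    average_path_length,
    betweenness_centralization,
    build_network,
    classify_edges,
    combine_panels,
    correlation_matrix,
    degree_summary,
    detect_communities,
    edge_density,
    modularity_q,
    network_compare,
    signed_edge_summary,
    transitivity,
)
from immunome_net.simulate import sample_subject_proportions


def _freq(values, cohorts, lineages, panel="P1"):
    subjects = [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=subjects,
                      columns=[f"n{j}" for j in range(values.shape[1])])
    df = df.div(df.sum(axis=1), axis=0)
    return FrequencyMatrix(
        values=df,
        subject_meta=pd.DataFrame({"cohort": cohorts, "batch": "0"}, index=subjects),
        node_meta=pd.DataFrame({"panel": panel, "lineage": lineages}, index=df.columns),
    )


class TestCombinePanels:
    def _pair(self):
        rng = np.random.default_rng(0)
        f1 = _freq(rng.uniform(1, 2, (6, 4)), ["HC"] * 6,
                   ["NK", "CD4T", "B", "MonoDC"], panel="P1")
        f2 = _freq(rng.uniform(1, 2, (5, 3)), ["HC"] * 5,
                   ["B", "MonoDC", "CD8T"], panel="P2")
        return f1, f2

    def test_lineage_filter_and_subject_intersection(self):
        f1, f2 = self._pair()
        combined = combine_panels(f1, f2)
        # P1 keeps NK+CD4T (2 nodes), P2 keeps B+MonoDC (2 nodes)
        assert list(combined.values.columns) == ["P1.n0", "P1.n1", "P2.n0", "P2.n1"]
        assert set(combined.values.index) == {f"s{i}" for i in range(5)}

    def test_empty_intersection_rejected(self):
        f1, f2 = self._pair()
        f2.values.index = [f"t{i}" for i in range(5)]
        f2.subject_meta.index = f2.values.index
        with pytest.raises(ValueError, match="both panels"):
            combine_panels(f1, f2)


class TestCorrelationMatrix:
    def _combined(self, values, cohorts):
        subjects = [f"s{i}" for i in range(values.shape[0])]
        df = pd.DataFrame(values, index=subjects,
                          columns=[f"n{j}" for j in range(values.shape[1])])
        return CombinedFrequencyMatrix(
            values=df,
            node_meta=pd.DataFrame({"panel": "P1", "lineage": "NK"}, index=df.columns),
            subject_meta=pd.DataFrame({"cohort": cohorts}, index=subjects),
        )

    def test_duplicated_and_negated_columns(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        combined = self._combined(np.column_stack([x, x, -x]), ["HC"] * 4)
        corr = correlation_matrix(combined, "HC")
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        combined = self._combined(np.column_stack([x, y]), ["HC"] * 4)
        corr = correlation_matrix(combined, "HC")
        assert corr.iloc[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_zero_variance_column_is_missing_never_an_edge(self):
        vals = np.column_stack([np.ones(5), np.arange(5.0), np.arange(5.0) * 2])
        combined = self._combined(vals, ["HC"] * 5)
        corr = correlation_matrix(combined, "HC")
        assert corr.iloc[0].isna().all()
        net = build_network(corr, combined.node_meta["lineage"])
        assert not any("n0" in e for e in net.graph.edges)

    def test_too_few_subjects_rejected(self):
        combined = self._combined(np.random.default_rng(0).uniform(size=(4, 2)),
                                  ["HC", "HC", "HF", "HF"])
        with pytest.raises(ValueError, match="need >= 3"):
            correlation_matrix(combined, "HC")


class TestBuildNetwork:
    def _corr(self, r_ab, r_ac, r_bc):
        c = np.array([[1.0, r_ab, r_ac], [r_ab, 1.0, r_bc], [r_ac, r_bc, 1.0]])
        return pd.DataFrame(c, index=["a", "b", "c"], columns=["a", "b", "c"])

    def test_threshold_and_signs(self):
        corr = self._corr(0.7, -0.65, 0.5)
        net = build_network(corr, {"a": "NK", "b": "B", "c": "NK"})
        assert net.n_edges == 2
        assert net.graph.edges[("a", "b")]["sign"] == 1
        assert net.graph.edges[("a", "c")]["sign"] == -1

    def test_identity_matrix_keeps_isolated_nodes(self):
        corr = self._corr(0.0, 0.0, 0.0)
        net = build_network(corr, {"a": "NK", "b": "B", "c": "NK"})
        assert net.n_edges == 0 and net.n_nodes == 3

    def test_boundary_strict_vs_inclusive(self):
        corr = self._corr(0.6, 0.0, 0.0)
        assert build_network(corr, dict.fromkeys("abc", "NK"), strict=True).n_edges == 0
        assert build_network(corr, dict.fromkeys("abc", "NK"), strict=False).n_edges == 1

    def test_threshold_domain_checked(self):
        corr = self._corr(0.5, 0.5, 0.5)
        with pytest.raises(ValueError, match="threshold"):
            build_network(corr, dict.fromkeys("abc", "NK"), threshold=1.5)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(-1, 1, (8, 8))
        c = np.clip((m + m.T) / 2, -0.99, 0.99)
        np.fill_diagonal(c, 1.0)
        corr = pd.DataFrame(c, index=list("abcdefgh"), columns=list("abcdefgh"))
        lineages = dict.fromkeys("abcdefgh", "NK")
        prev = None
        for t in (0.3, 0.5, 0.7, 0.9):
            edges = set(map(frozenset, build_network(corr, lineages, threshold=t).graph.edges))
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestGraphMetricsTrivial:
    def test_edge_density_examples(self):
        star = make_signed_network(5, [(0, i, 0.9) for i in range(1, 5)])
        assert edge_density(star) == pytest.approx(0.4)
        k4 = make_signed_network(4, [(i, j, 0.9) for i in range(4) for j in range(i + 1, 4)])
        assert edge_density(k4) == 1.0

    def test_signed_edge_summary_and_edgeless(self):
        net = make_signed_network(4, [(0, 1, 0.8), (1, 2, -0.7), (2, 3, 0.9)])
        assert signed_edge_summary(net) == (2, 1, pytest.approx(100 / 3))
        empty = make_signed_network(3, [])
        assert signed_edge_summary(empty) == (0, 0, None)

    def test_degree_star_and_lineage_means(self):
        net = make_signed_network(
            5,
            [(0, 1, 0.9), (0, 2, 0.9), (0, 3, 0.9), (3, 4, 0.9)],
            lineages=["NK", "NK", "NK", "B", "B"],
        )
        deg, by_lineage = degree_summary(net)
        assert deg[0] == 3
        assert deg.sum() == 2 * net.n_edges
        assert by_lineage["NK"] == pytest.approx((3 + 1 + 1) / 3)
        assert by_lineage["B"] == pytest.approx((2 + 1) / 2)

    def test_classify_edges_conservation(self):
        net = make_signed_network(
            5,
            [(0, 1, 0.9), (1, 2, 0.9), (0, 3, -0.8), (3, 4, 0.9), (2, 4, 0.7)],
            lineages=["NK", "NK", "NK", "B", "B"],
        )
        intra, inter, breakdown = classify_edges(net)
        assert (intra, inter) == (3, 2)
        n_pos, n_neg, _ = signed_edge_summary(net)
        assert intra + inter == n_pos + n_neg
        assert breakdown.loc["NK", "intra"] == 2

    def test_betweenness_centralization_star_and_complete(self):
        star = make_signed_network(6, [(0, i, 0.9) for i in range(1, 6)])
        assert betweenness_centralization(star) == pytest.approx(1.0)
        k5 = make_signed_network(5, [(i, j, 0.9) for i in range(5) for j in range(i + 1, 5)])
        assert betweenness_centralization(k5) == pytest.approx(0.0)

    def test_transitivity_examples(self):
        k3 = make_signed_network(3, [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9)])
        assert transitivity(k3) == 1.0
        star = make_signed_network(4, [(0, i, 0.9) for i in range(1, 4)])
        assert transitivity(star) == 0.0
        one_edge = make_signed_network(3, [(0, 1, 0.9)])
        assert transitivity(one_edge) is None

    def test_average_path_length_examples(self):
        k4 = make_signed_network(4, [(i, j, 0.9) for i in range(4) for j in range(i + 1, 4)])
        assert average_path_length(k4) == 1.0
        p3 = make_signed_network(3, [(0, 1, 0.9), (1, 2, 0.9)])
        assert average_path_length(p3) == pytest.approx(4 / 3)
        two_k2 = make_signed_network(4, [(0, 1, 0.9), (2, 3, -0.9)])
        assert average_path_length(two_k2) == 1.0
        with pytest.raises(ValueError):
            average_path_length(make_signed_network(3, []))

    def test_modularity_examples(self):
        two_k3 = make_signed_network(
            6,
            [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9), (3, 4, 0.9), (4, 5, 0.9), (3, 5, 0.9)],
        )
        assert modularity_q(two_k3, dict.fromkeys(range(6), 0)) == pytest.approx(0.0)
        natural = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity_q(two_k3, natural) == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        shuffled = dict(zip(range(6), rng.permutation([0, 0, 0, 1, 1, 1])))
        if shuffled != natural and shuffled != {k: 1 - v for k, v in natural.items()}:
            assert modularity_q(two_k3, shuffled) < 0.5

    def test_detect_communities_two_cliques(self):
        edges = [(i, j, 0.9) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j, 0.9) for i in range(4, 8) for j in range(i + 1, 8)]
        edges.append((0, 4, 0.9))
        net = make_signed_network(8, edges)
        part = detect_communities(net)
        assert {part[i] for i in range(4)} != {part[i] for i in range(4, 8)}
        assert len({part[i] for i in range(4)}) == 1
        assert len({part[i] for i in range(4, 8)}) == 1
        assert detect_communities(net) == part  # deterministic

    def test_complete_graph_single_community(self):
        k5 = make_signed_network(5, [(i, j, 0.9) for i in range(5) for j in range(i + 1, 5)])
        assert len(set(detect_communities(k5).values())) == 1

    def test_edgeless_graph_singletons(self):
        net = make_signed_network(4, [])
        part = detect_communities(net)
        assert len(set(part.values())) == 4


class TestOracleEquivalence:
    """Graph metrics agree with independent brute-force computations on
    seeded random graphs with n <= 12."""

    @pytest.mark.parametrize("case_idx", range(50))
    def test_all_metrics_match_brute_force(self, case_idx):
        nodes, edges = random_graph_cases(50)[case_idx]
        net = make_signed_network(len(nodes), [(u, v, 0.9) for u, v in edges])
        m = net.n_edges
        assert edge_density(net) * (len(nodes) * (len(nodes) - 1) / 2) == pytest.approx(m)
        assert betweenness_centralization(net) == pytest.approx(
            _oracles.betweenness_centralization_oracle(nodes, edges), abs=1e-10
        )
        t_pkg, t_oracle = transitivity(net), _oracles.transitivity_oracle(nodes, edges)
        if t_oracle is None:
            assert t_pkg is None
        else:
            assert t_pkg == pytest.approx(t_oracle, abs=1e-10)
        assert average_path_length(net) == pytest.approx(
            _oracles.average_path_length_oracle(nodes, edges), abs=1e-10
        )
        part = detect_communities(net)
        assert modularity_q(net, part) == pytest.approx(
            _oracles.modularity_oracle(nodes, edges, part), abs=1e-10
        )


class TestPlantedStructureRecovery:
    def test_lineage_blocks_recovered_as_communities(self):
        """Block-diagonal planted frequency correlation (within-lineage 0.8)
        yields detected communities aligned with lineages (>= 0.9 majority
        agreement at 200 subjects)."""
        n_lineage, per = 4, 4
        k = n_lineage * per + 4  # 4 independent filler subsets
        corr = np.eye(k)
        for b in range(n_lineage):
            for i in range(b * per, (b + 1) * per):
                for j in range(b * per, (b + 1) * per):
                    if i != j:
                        corr[i, j] = 0.8
        spec = single_panel_spec(corr, sd=0.5)
        props = sample_subject_proportions(spec, "A", 200, seed=12)
        cols = [f"s{i}" for i in range(n_lineage * per)]
        lineages = {c: f"L{i // per}" for i, c in enumerate(cols)}
        sample_corr = props[cols].corr()
        net = build_network(sample_corr, lineages, threshold=0.6)
        part = detect_communities(net)
        # majority community per lineage must claim >= 0.9 of nodes overall
        agree = 0
        for lin in {f"L{b}" for b in range(n_lineage)}:
            members = [c for c in cols if lineages[c] == lin]
            counts = pd.Series([part[c] for c in members]).value_counts()
            agree += counts.iloc[0]
        assert agree / len(cols) >= 0.9


class TestNetworkCompare:
    def test_identical_cohorts_identical_properties(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 1.5, size=(10, 6))
        values = pd.DataFrame(
            np.vstack([vals, vals]),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
            columns=[f"n{j}" for j in range(6)],
        )
        combined = CombinedFrequencyMatrix(
            values=values,
            node_meta=pd.DataFrame({"panel": "P1", "lineage": "NK"}, index=values.columns),
            subject_meta=pd.DataFrame(
                {"cohort": ["HC"] * 10 + ["HF"] * 10}, index=values.index
            ),
        )
        _, table = network_compare(combined, cohorts=("HC", "HF"))
        hc, hf = table["HC"], table["HF"]
        pd.testing.assert_series_equal(hc, hf, check_names=False)

    def test_property_table_rows(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.5, 1.5, size=(12, 6))
        combined = CombinedFrequencyMatrix(
            values=pd.DataFrame(vals, index=[f"s{i}" for i in range(12)],
                                columns=[f"n{j}" for j in range(6)]),
            node_meta=pd.DataFrame({"panel": "P1", "lineage": "NK"},
                                   index=[f"n{j}" for j in range(6)]),
            subject_meta=pd.DataFrame({"cohort": ["HC"] * 6 + ["HF"] * 6},
                                      index=[f"s{i}" for i in range(12)]),
        )
        _, table = network_compare(combined, cohorts=("HC", "HF"))
        expected_lead = [
            "edge_density",
            "centralization_betweenness",
            "transitivity",
            "modularity",
            "average_path_length",
            "no_neg_edges",
            "no_pos_edges",
        ]
        assert list(table.index[:7]) == expected_lead
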
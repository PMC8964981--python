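"""Frequency matrices and the Wilcoxon rank-sum machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import _oracles
from immunome_net.abundance import (
    FrequencyMatrix,
    differential_nodes,
    frequency_matrix,
    rank_sum_test,
)
from immunome_net.cluster import NodeModel


def _model(assignments, k):
    return NodeModel(
        k=k,
        centroids=np.zeros((k, 2)),
        assignments=assignments,
        marker_names=("m0", "m1"),
        wcss=0.0,
    )


def _sheet(entries):
    return pd.DataFrame(entries, columns=["subject_id", "cohort", "batch", "panel"])


class TestFrequencyMatrix:
    def test_direct_counts(self):
        model = _model({("s1", "P1"): np.array([0, 0, 1, 2])}, k=3)
        sheet = _sheet([("s1", "HC", "0", "P1")])
        freq = frequency_matrix(model, sheet, panel="P1")
        np.testing.assert_allclose(
            freq.values.loc["s1"].to_numpy(), [0.5, 0.25, 0.25]
        )

    def test_unassigned_node_gets_zero_and_rows_close(self):
        model = _model(
            {("s1", "P1"): np.array([0, 0]), ("s2", "P1"): np.array([1, 1, 1])}, k=3
        )
        sheet = _sheet([("s1", "HC", "0", "P1"), ("s2", "HF", "0", "P1")])
        freq = frequency_matrix(model, sheet, panel="P1")
        assert freq.values.loc["s1", "n3"] == 0.0
        np.testing.assert_allclose(freq.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_cell_subject_rejected(self):
        model = _model({("s1", "P1"): np.array([], dtype=int)}, k=2)
        with pytest.raises(ValueError, match="zero cells"):
            frequency_matrix(model, _sheet([("s1", "HC", "0", "P1")]), panel="P1")

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            FrequencyMatrix(
                values=pd.DataFrame({"n1": [1.5], "n2": [-0.5]}, index=["s1"]),
                subject_meta=pd.DataFrame({"cohort": ["HC"], "batch": ["0"]}, index=["s1"]),
                node_meta=pd.DataFrame(
                    {"panel": ["P1", "P1"], "lineage": ["NK", "B"]}, index=["n1", "n2"]
                ),
            )


class TestRankSum:
    def test_exact_small_example(self):
        res = rank_sum_test([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "approx"  # ties force the approximation
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, m = rng.integers(2, 9, size=2)
        pooled = rng.choice(1000, size=n + m, replace=False).astype(float)
        x, y = pooled[:n], pooled[n:]
        res = rank_sum_test(x, y, mode="exact")
        assert res.p_value == pytest.approx(_oracles.exact_ranksum_oracle(x, y), abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n, m = rng.integers(2, 9, size=2)
            pooled = rng.choice(10_000, size=n + m, replace=False).astype(float)
            x, y = pooled[:n], pooled[n:]
            ours = rank_sum_test(x, y, mode="exact").p_value
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_approx_agrees_with_exact_rejection(self):
        """Normal approximation reaches the same alpha=0.05 decision as the
        exact test in >= 95% of small untied instances."""
        rng = np.random.default_rng(11)
        agree = total = 0
        for _ in range(300):
            n, m = rng.integers(3, 9, size=2)
            pooled = rng.normal(size=n + m) + np.linspace(0, 1e-9, n + m)
            x, y = pooled[:n], pooled[n:] + rng.uniform(0, 1.5)
            p_exact = rank_sum_test(x, y, mode="exact").p_value
            p_approx = rank_sum_test(x, y, mode="approx").p_value
            agree += (p_exact < 0.05) == (p_approx < 0.05)
            total += 1
        assert agree / total >= 0.95

    def test_label_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=9) + 0.8
        assert rank_sum_test(x, y).p_value == pytest.approx(
            rank_sum_test(y, x).p_value, abs=1e-12
        )


def _freq_from_values(values, cohorts):
    subjects = [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=subjects,
                      columns=[f"n{j}" for j in range(values.shape[1])])
    df = df.div(df.sum(axis=1), axis=0)
    return FrequencyMatrix(
        values=df,
        subject_meta=pd.DataFrame({"cohort": cohorts, "batch": "0"}, index=subjects),
        node_meta=pd.DataFrame(
            {"panel": "P1", "lineage": "other"}, index=df.columns
        ),
    )


class TestDifferentialNodes:
    def _planted(self, shift, n_nodes=20, seed=0):
        rng = np.random.default_rng(seed)
        n_a, n_b = 32, 18
        base = np.full(n_nodes, 1.0)
        a = rng.lognormal(mean=0, sigma=0.15, size=(n_a, n_nodes)) * base
        b = rng.lognormal(mean=0, sigma=0.15, size=(n_b, n_nodes)) * base
        a[:, 0] *= shift  # planted fold change on node 0
        values = np.vstack([a, b])
        cohorts = ["HF"] * n_a + ["HC"] * n_b
        return _freq_from_values(values, cohorts)

    def test_planted_shift_detected_with_direction(self):
        freq = self._planted(shift=2.0, seed=1)
        res = differential_nodes(freq, ("HF", "HC"))
        assert bool(res.loc["n0", "significant"])
        assert res.loc["n0", "direction"] == "expanded"

    def test_swapping_groups_flips_direction_keeps_p(self):
        freq = self._planted(shift=2.0, seed=2)
        a = differential_nodes(freq, ("HF", "HC"))
        b = differential_nodes(freq, ("HC", "HF"))
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)
        assert b.loc["n0", "direction"] == "reduced"

    def test_alpha_zero_flags_nothing(self):
        freq = self._planted(shift=3.0, seed=3)
        res = differential_nodes(freq, ("HF", "HC"), alpha=0.0)
        assert not res["significant"].any()

    def test_null_false_positive_rate_matches_alpha(self):
        """Without a planted shift, ~5% of 80 nodes reject at alpha=0.05."""
        counts = []
        for rep in range(40):
            freq = self._planted(shift=1.0, n_nodes=80, seed=100 + rep)
            res = differential_nodes(freq, ("HF", "HC"))
            counts.append(int(res["significant"].sum()))
        mean_fp = np.mean(counts)
        # binomial(80, 0.05) mean 4, sd ~1.95; 40 reps give se ~0.31
        assert 2.5 < mean_fp < 5.5

    def test_monotone_power_in_effect_size(self):
        rejections = []
        for shift in (1.0, 1.5, 2.5):
            hits = 0
            for rep in range(30):
                freq = self._planted(shift=shift, n_nodes=5, seed=500 + rep)
                hits += bool(
                    differential_nodes(freq, ("HF", "HC")).loc["n0", "significant"]
                )
            rejections.append(hits)
        assert rejections[0] <= rejections[1] <= rejections[2]

    def test_bh_adjustment_is_more_conservative(self):
        freq = self._planted(shift=1.0, n_nodes=40, seed=9)
        raw = differential_nodes(freq, ("HF", "HC"), adjust="none")
        bh = differential_nodes(freq, ("HF", "HC"), adjust="BH")
        assert bh["significant"].sum() <= raw["significant"].sum()
        assert (bh["p_adjusted"] >= bh["p_value"] - 1e-12).all()

    def test_unknown_group_label_rejected(self):
        freq = self._planted(shift=1.0, seed=4)
        with pytest.raises(ValueError, match="absent"):
            differential_nodes(freq, ("HFpEF", "HC"))
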
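"""Subject x node frequency matrices and differential-abundance testing.

Node frequencies are compositional: within each panel, a subject's node
proportions sum to one. Group comparisons use the two-sided Wilcoxon
rank-sum (Mann-Whitney) test, exact by enumeration for small untied groups
and a tie/continuity-corrected normal approximation otherwise; significance
defaults to raw p < 0.05 with no multiplicity correction, with
Benjamini-Hochberg available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, erf, sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import NodeModel

__all__ = [
    "FrequencyMatrix",
    "RankSumResult",
    "frequency_matrix",
    "rank_sum_test",
    "differential_nodes",
]

log = logging.getLogger(__name__)


@dataclass
class FrequencyMatrix:
    """Subjects x nodes proportion matrix plus subject and node metadata.

    ``subject_meta`` is indexed by subject_id (columns: cohort, batch);
    ``node_meta`` is indexed by node_id (columns: panel, lineage).
    """

    values: pd.DataFrame
    subject_meta: pd.DataFrame
    node_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(float)
        if ((v < -1e-12) | (v > 1 + 1e-12)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        for panel in self.node_meta["panel"].unique():
            cols = self.node_meta.index[self.node_meta["panel"] == panel]
            sums = self.values[cols].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"panel {panel!r} node frequencies do not sum to 1 per subject")

    def cohort_of(self, subject_id: str) -> str:
        return str(self.subject_meta.loc[subject_id, "cohort"])


def frequency_matrix(
    model: NodeModel,
    sample_sheet: pd.DataFrame,
    panel: str | None = None,
    lineages: Mapping[str, str] | pd.Series | None = None,
) -> FrequencyMatrix:
    """Per-subject node frequencies from a fitted node model's assignments.

    Entry (s, v) is the fraction of subject s's retained cells assigned to
    node v, over all cells of that subject in the model's panel.
    """
    rows, index = [], []
    sheet = sample_sheet.set_index(["subject_id", "panel"])
    for (subject_id, sample_panel), labels in model.assignments.items():
        if panel is not None and sample_panel != panel:
            continue
        if labels.size == 0:
            raise ValueError(f"subject {subject_id} has zero cells in panel {sample_panel}")
        counts = np.bincount(labels, minlength=model.k)
        rows.append(counts / counts.sum())
        index.append((subject_id, sample_panel))
    if not rows:
        raise ValueError("no assignments matched the requested panel")
    panel_id = index[0][1]
    values = pd.DataFrame(
        np.asarray(rows), index=[s for s, _ in index], columns=list(model.node_ids)
    )
    values.index.name = "subject_id"
    meta_cols = {
        "cohort": [str(sheet.loc[key, "cohort"]) for key in index],
        "batch": [str(sheet.loc[key, "batch"]) for key in index],
    }
    if "group" in sheet.columns:
        meta_cols["group"] = [str(sheet.loc[key, "group"]) for key in index]
    meta = pd.DataFrame(meta_cols, index=values.index)
    if lineages is None:
        lin = ["other"] * model.k
    else:
        lin = [lineages[n] for n in model.node_ids]
    node_meta = pd.DataFrame(
        {"panel": panel_id, "lineage": lin}, index=pd.Index(model.node_ids, name="node_id")
    )
    return FrequencyMatrix(values=values, subject_meta=meta, node_meta=node_meta)


def subjects_matching(meta: pd.DataFrame, label: str) -> pd.Index:
    """Subjects whose cohort — or analysis group, if present — equals ``label``."""
    mask = meta["cohort"] == label
    if "group" in meta.columns:
        mask = mask | (meta["group"] == label)
    return meta.index[mask]


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum W of the first group
    p_value: float
    method: str  # "exact" or "approx"


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for the rank sum of x, by full null enumeration.

    Under H0 every assignment of the n ranks of the pooled sample to group x
    is equally likely; the null distribution of W is built by dynamic
    programming over C(n+m, n) subsets. Two-sided p doubles the smaller
    tail (capped at 1).
    """
    n, m = len(x), len(y)
    N = n + m
    ranks = np.arange(1, N + 1)
    w_obs = int(round(_rank_sum_of_x(x, y)))
    # table[j][s] = number of j-subsets of ranks seen so far with sum s
    max_sum = int(ranks[-n:].sum()) if n else 0
    table = np.zeros((n + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for r in ranks:
        for j in range(min(n, r) - 1, -1, -1):
            row = table[j]
            nz = np.nonzero(row)[0]
            valid = nz[nz + r <= max_sum]
            table[j + 1, valid + r] += row[valid]
    dist = table[n] / comb(N, n)
    sums = np.arange(max_sum + 1)
    lower = dist[sums <= w_obs].sum()
    upper = dist[sums >= w_obs].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _rank_sum_of_x(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    # midranks for ties
    vals, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        cum = np.cumsum(counts)
        mid = cum - (counts - 1) / 2.0
        ranks = mid[inv]
    return float(ranks[: len(x)].sum())


def _approx_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Normal approximation with midranks, tie-corrected variance, and a
    0.5 continuity correction."""
    n, m = len(x), len(y)
    N = n + m
    w = _rank_sum_of_x(x, y)
    mean = n * (N + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = max(0.0, abs(w - mean) - 0.5) / sqrt(var)
    # two-sided p from the standard normal survival function
    return float(min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))))


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    ``mode`` is "exact" (full enumeration; requires no ties), "approx"
    (normal approximation), or "auto": exact when min(|x|, |y|) <= 8 and the
    pooled sample has no ties, approx otherwise.
    """
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires an untied pooled sample")
        p = _exact_ranksum_p(x, y)
    elif mode == "approx":
        p = _approx_ranksum_p(x, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return RankSumResult(statistic=_rank_sum_of_x(x, y), p_value=p, method=mode)


def differential_nodes(
    freq: FrequencyMatrix,
    grouping: tuple[str, str],
    alpha: float = 0.05,
    adjust: str = "none",
    mode: str = "auto",
) -> pd.DataFrame:
    """Test every node for a frequency difference between two cohorts.

    ``grouping`` = (case label, reference label); the direction is
    "expanded" when the case-group median exceeds the reference median.
    ``adjust`` is "none" (raw p < alpha, mirroring a per-node significance
    call) or "BH" (Benjamini-Hochberg across nodes).
    """
    case, ref = grouping
    idx_a = subjects_matching(freq.subject_meta, case)
    idx_b = subjects_matching(freq.subject_meta, ref)
    for label, idx in zip(grouping, (idx_a, idx_b)):
        if len(idx) == 0:
            raise ValueError(f"grouping label {label!r} absent from sample sheet")
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need at least 2 subjects")

    rows = []
    for node in freq.values.columns:
        a = freq.values.loc[idx_a, node].to_numpy(float)
        b = freq.values.loc[idx_b, node].to_numpy(float)
        res = rank_sum_test(a, b, mode=mode)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "node_id": node,
                "panel": freq.node_meta.loc[node, "panel"],
                "lineage": freq.node_meta.loc[node, "lineage"],
                f"median_{case}": med_a,
                f"median_{ref}": med_b,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "direction": "expanded" if med_a > med_b else ("reduced" if med_a < med_b else "unchanged"),
            }
        )
    out = pd.DataFrame(rows).set_index("node_id")
    if adjust == "BH":
        from statsmodels.stats.multitest import multipletests

        log.warning(
            "BH adjustment enabled; the default analysis uses raw p-values"
        )
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
    elif adjust == "none":
        out["p_adjusted"] = np.nan
        out["significant"] = out["p_value"] < alpha
    else:
        raise ValueError(f"unknown adjust {adjust!r}")
    return out
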
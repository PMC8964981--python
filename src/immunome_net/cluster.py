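"""Phenotype-node discovery: pooled k-means, elbow k selection, node
phenotyping, and marker-gate lineage annotation.

Cells are pooled across all subjects and cohorts of one panel before
clustering so that node identities are shared across cohorts; each node
(cluster) is summarized by its per-marker median intensity, the medians are
scaled across nodes (z-score per marker) for display and gating, and each
node is assigned a major immune lineage by an ordered marker-gate table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import CellSample

__all__ = [
    "NodeModel",
    "GatingRule",
    "GatingTable",
    "DEFAULT_GATES",
    "pool_cells",
    "kmeans_cluster",
    "elbow_select_k",
    "knee_point",
    "node_phenotype",
    "annotate_lineage",
]


@dataclass
class NodeModel:
    """A fitted phenotype-node clustering for one panel."""

    k: int
    centroids: np.ndarray  # k x markers, transformed scale
    assignments: dict[tuple[str, str], np.ndarray]  # (subject, panel) -> node idx per cell
    marker_names: tuple[str, ...]
    wcss: float
    node_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.centroids.shape[0] != self.k:
            raise ValueError("centroid count does not match k")
        if not self.node_ids:
            width = len(str(self.k))
            self.node_ids = tuple(f"n{i + 1:0{width}d}" for i in range(self.k))


def pool_cells(samples: Sequence[CellSample]) -> tuple[np.ndarray, list[tuple[str, str]], np.ndarray]:
    """Stack all samples' matrices; return (matrix, sample keys, row offsets)."""
    if not samples:
        raise ValueError("no samples to pool")
    names = samples[0].marker_names
    for s in samples:
        if s.marker_names != names:
            raise ValueError("samples to pool have differing marker sets")
    offsets = np.cumsum([0] + [s.n_cells for s in samples])
    return np.vstack([s.matrix for s in samples]), [s.key for s in samples], offsets


def kmeans_cluster(
    cells: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 30,
    sample_keys: Sequence[tuple[str, str]] | None = None,
    offsets: np.ndarray | None = None,
    marker_names: tuple[str, ...] = (),
) -> NodeModel:
    """k-means with careful seeding and ``n_restarts`` restarts; the restart
    with the lowest within-cluster sum of squares wins. Deterministic given
    ``seed``."""
    cells = np.asarray(cells, float)
    if k < 1 or k > cells.shape[0]:
        raise ValueError(f"k={k} outside [1, n_cells={cells.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(cells)
    labels = km.labels_.astype(int)
    if sample_keys is not None and offsets is not None:
        assignments = {
            key: labels[offsets[i] : offsets[i + 1]] for i, key in enumerate(sample_keys)
        }
    else:
        assignments = {("pooled", "pooled"): labels}
    return NodeModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=assignments,
        marker_names=tuple(marker_names) or tuple(f"m{j}" for j in range(cells.shape[1])),
        wcss=float(km.inertia_),
    )


def knee_point(k_grid: Sequence[int], wcss: Sequence[float]) -> int:
    """Elbow of a WCSS-vs-k curve: the k maximizing perpendicular distance
    from the (normalized) curve to the chord joining its endpoints.

    A flat (linear) curve has no knee; the smallest interior k is returned
    with a warning.
    """
    ks = np.asarray(k_grid, float)
    ws = np.asarray(wcss, float)
    if len(ks) < 3:
        raise ValueError("need at least 3 grid points to locate an elbow")
    # normalize both axes to [0,1] so the distance is scale-free
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    wspan = ws[0] - ws[-1]
    if abs(wspan) < 1e-300:
        warnings.warn("WCSS curve is constant; no elbow, returning smallest interior k")
        return int(k_grid[1])
    y = (ws - ws[-1]) / wspan
    # chord runs (0,1) -> (1,0); distance of (x,y) to x + y = 1
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    if dist.max() < 1e-9:
        warnings.warn("WCSS curve is linear in k; no clear elbow, returning smallest interior k")
        return int(k_grid[1])
    return int(np.asarray(k_grid)[int(np.argmax(dist))])


def elbow_select_k(
    cells: np.ndarray,
    k_grid: Sequence[int] = tuple(range(10, 121, 10)),
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[int, pd.DataFrame]:
    """Fit k-means over ``k_grid`` and pick k by the elbow criterion.

    Returns the selected k and the WCSS curve as a DataFrame (k, wcss).
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if len(k_grid) < 3:
        raise ValueError("k_grid must contain at least 3 distinct values")
    cells = np.asarray(cells, float)
    wcss = []
    for k in k_grid:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(cells)
        wcss.append(float(km.inertia_))
    curve = pd.DataFrame({"k": k_grid, "wcss": wcss})
    return knee_point(k_grid, wcss), curve


def node_phenotype(model: NodeModel, cells: np.ndarray) -> pd.DataFrame:
    """Per-node per-marker median intensities plus across-node scaled medians.

    ``cells`` must be the pooled matrix the model was fitted on (same row
    order as the concatenated assignments). Scaled medians are z-scores per
    marker across nodes: (median - mean over nodes) / sd over nodes. Empty
    nodes get NaN medians and are flagged.

    Returns a DataFrame indexed by node_id with columns ``n_cells``,
    ``empty``, ``median_<marker>`` and ``scaled_<marker>``.
    """
    cells = np.asarray(cells, float)
    labels = np.concatenate([model.assignments[k] for k in model.assignments])
    if labels.shape[0] != cells.shape[0]:
        raise ValueError("cells row count does not match stored assignments")
    medians = np.full((model.k, cells.shape[1]), np.nan)
    counts = np.zeros(model.k, dtype=int)
    for j in range(model.k):
        mask = labels == j
        counts[j] = int(mask.sum())
        if counts[j]:
            medians[j] = np.median(cells[mask], axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(medians, axis=0)
        sd = np.nanstd(medians, axis=0)
    scaled = (medians - mu) / np.where(sd > 0, sd, 1.0)

    out = pd.DataFrame(index=pd.Index(model.node_ids, name="node_id"))
    out["n_cells"] = counts
    out["empty"] = counts == 0
    for j, m in enumerate(model.marker_names):
        out[f"median_{m}"] = medians[:, j]
    for j, m in enumerate(model.marker_names):
        out[f"scaled_{m}"] = scaled[:, j]
    return out


@dataclass(frozen=True)
class GatingRule:
    lineage: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()


@dataclass(frozen=True)
class GatingTable:
    """Ordered marker gates; the first matching rule labels the node,
    unmatched nodes fall through to "other"."""

    rules: tuple[GatingRule, ...]

    def markers(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= set(r.positive) | set(r.negative)
        return out


#: Lineage gates on scaled medians; a marker is "positive" above the
#: positivity threshold (default 0, i.e. above the across-node mean).
#: More specific phenotypes precede broader ones; monocyte/DC admission is
#: split over CD14/CD16/CD11c so each rule stays (positive, negative) only.
DEFAULT_GATES = GatingTable(
    rules=(
        GatingRule("Treg", positive=("CD3", "CD4", "CD25", "FOXP3")),
        GatingRule("MAIT", positive=("CD3", "TCR-Va7.2", "CD161")),
        GatingRule("CD8T", positive=("CD3", "CD8")),
        GatingRule("CD4T", positive=("CD3", "CD4"), negative=("CD8",)),
        GatingRule("NK", positive=("CD56",), negative=("CD3",)),
        GatingRule("B", positive=("CD19",), negative=("CD3",)),
        GatingRule("MonoDC", positive=("CD14",), negative=("CD3", "CD19")),
        GatingRule("MonoDC", positive=("CD16",), negative=("CD3", "CD19")),
        GatingRule("MonoDC", positive=("CD11c",), negative=("CD3", "CD19")),
    )
)


def annotate_lineage(
    phenotypes: pd.DataFrame,
    gates: GatingTable = DEFAULT_GATES,
    positivity_threshold: float = 0.0,
) -> pd.Series:
    """Assign a lineage to each node from its scaled medians.

    Pure function of the phenotype table and the gate table: a marker is
    positive iff its scaled median exceeds ``positivity_threshold``; rules
    are evaluated in order and the first match wins; no match -> "other".
    Raises KeyError if a gate references a marker absent from the panel.
    """
    available = {c.removeprefix("scaled_") for c in phenotypes.columns if c.startswith("scaled_")}
    # gates restricted to rules whose markers all exist would silently change
    # semantics; absent markers are an error instead
    missing = gates.markers() - available
    if missing:
        raise KeyError(f"gating markers absent from panel: {sorted(missing)}")

    labels = []
    for _, row in phenotypes.iterrows():
        label = "other"
        for rule in gates.rules:
            pos_ok = all(row[f"scaled_{m}"] > positivity_threshold for m in rule.positive)
            neg_ok = all(row[f"scaled_{m}"] <= positivity_threshold for m in rule.negative)
            if pos_ok and neg_ok:
                label = rule.lineage
                break
        labels.append(label)
    return pd.Series(labels, index=phenotypes.index, name="lineage")
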
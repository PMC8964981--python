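"""Synthetic two-panel CyTOF-like cohort generator with known ground truth.

The generator emulates a case/control mass-cytometry study design: two
antibody panels sharing a core of lineage markers, multi-batch acquisition,
planted immune-cell subsets (Gaussian mixture in arcsinh space), planted
case/control abundance shifts on the logit-proportion scale, and a planted
between-subject frequency correlation structure ("interactome") imposed via
a Gaussian copula on logit-proportions followed by closure to the simplex.

Cells are emitted on the raw dual-count scale by inverting the arcsinh
transform (sinh(y) * cofactor, clipped at zero), so the preprocessing stage
exactly inverts the generative model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_COFACTOR, LINEAGES, CellSample

__all__ = [
    "PanelSpec",
    "SubsetSpec",
    "CohortSimSpec",
    "GroundTruth",
    "sample_subject_proportions",
    "synthesize_cells",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class PanelSpec:
    """One antibody panel: an ordered marker list plus the cross-panel core."""

    panel_id: str
    marker_names: tuple[str, ...]
    shared_markers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError(f"duplicate marker names in panel {self.panel_id}")
        missing = set(self.shared_markers) - set(self.marker_names)
        if missing:
            raise ValueError(
                f"shared markers absent from panel {self.panel_id}: {sorted(missing)}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)


@dataclass(frozen=True)
class SubsetSpec:
    """A planted immune-cell subset: phenotype, abundance, and cohort shifts.

    ``mean_profile`` and ``dispersion`` are per-marker location/scale of the
    subset's Gaussian in arcsinh space, ordered as its panel's markers.
    ``cohort_logit_shift`` moves the subset's expected abundance on the
    logit-proportion scale per cohort; ``between_subject_sd`` scales the
    copula-driven subject-to-subject variability on the same scale.
    """

    subset_id: str
    lineage: str
    panel_id: str
    mean_profile: tuple[float, ...]
    dispersion: tuple[float, ...]
    base_proportion: float
    cohort_logit_shift: Mapping[str, float] = field(default_factory=dict)
    between_subject_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if len(self.mean_profile) != len(self.dispersion):
            raise ValueError("mean_profile and dispersion lengths differ")
        if not all(d > 0 for d in self.dispersion):
            raise ValueError(f"dispersions must be strictly positive ({self.subset_id})")
        if not 0.0 < self.base_proportion < 1.0:
            raise ValueError("base_proportion must lie in (0, 1)")


@dataclass
class CohortSimSpec:
    """Full design of a simulated cohort study.

    ``frequency_correlation`` maps a cohort label to a correlation matrix
    over *all* subsets (both panels, in ``subsets`` order); a single matrix
    may be supplied under the key ``"*"`` to apply to every cohort.
    ``batch_marker_shift`` maps (panel_id, batch index) to an additive
    per-marker offset applied in arcsinh space.
    """

    panels: tuple[PanelSpec, ...]
    subsets: tuple[SubsetSpec, ...]
    n_subjects: Mapping[str, int]
    frequency_correlation: Mapping[str, np.ndarray]
    n_cells_per_sample: int = 20_000
    n_batches: int = 3
    batch_marker_shift: Mapping[tuple[str, int], np.ndarray] = field(default_factory=dict)
    #: optional cohort -> analysis-group mapping (e.g. HFpEF/HFrEF/HFmrEF -> HF)
    cohort_groups: Mapping[str, str] = field(default_factory=dict)
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0

    def __post_init__(self) -> None:
        panel_ids = {p.panel_id for p in self.panels}
        for s in self.subsets:
            if s.panel_id not in panel_ids:
                raise ValueError(f"subset {s.subset_id} references unknown panel {s.panel_id}")
            panel = self.panel(s.panel_id)
            if len(s.mean_profile) != panel.n_markers:
                raise ValueError(
                    f"subset {s.subset_id}: profile length {len(s.mean_profile)} "
                    f"!= panel {s.panel_id} marker count {panel.n_markers}"
                )
        for pid in panel_ids:
            total = sum(s.base_proportion for s in self.subsets if s.panel_id == pid)
            if abs(total - 1.0) > 1e-8:
                raise ValueError(
                    f"base proportions for panel {pid} sum to {total:.6f}, not 1"
                )
        for cohort, corr in self.frequency_correlation.items():
            _check_correlation_matrix(np.asarray(corr, float), len(self.subsets), cohort)
        if self.n_cells_per_sample <= 0:
            raise ValueError("n_cells_per_sample must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")

    def panel(self, panel_id: str) -> PanelSpec:
        for p in self.panels:
            if p.panel_id == panel_id:
                return p
        raise KeyError(panel_id)

    def subset_ids(self) -> list[str]:
        return [s.subset_id for s in self.subsets]

    def correlation_for(self, cohort: str) -> np.ndarray:
        corr = self.frequency_correlation.get(cohort, self.frequency_correlation.get("*"))
        if corr is None:
            raise KeyError(f"no frequency correlation defined for cohort {cohort!r}")
        return np.asarray(corr, float)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside a simulated cohort."""

    #: (subject_id, panel_id) -> per-cell subset index into ``subset_ids``
    cell_labels: dict[tuple[str, str], np.ndarray]
    #: subjects x subsets true sampled proportions (closure applied per panel)
    proportions: pd.DataFrame
    #: cohort label -> planted correlation matrix over subsets
    planted_correlation: dict[str, np.ndarray]
    subset_ids: list[str]
    subset_lineages: dict[str, str]


def _check_correlation_matrix(corr: np.ndarray, n: int, label: str) -> None:
    if corr.shape != (n, n):
        raise ValueError(f"correlation matrix for {label!r} has shape {corr.shape}, expected ({n},{n})")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError(f"correlation matrix for {label!r} is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError(f"correlation matrix for {label!r} does not have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-8:
        raise ValueError(
            f"correlation matrix for {label!r} is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3e})"
        )


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def sample_subject_proportions(
    spec: CohortSimSpec,
    cohort: str,
    n_subjects: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw subjects x subsets proportion matrices for one cohort.

    A Gaussian copula with the cohort's planted correlation matrix drives
    correlated logit-scale deviations around each subset's (cohort-shifted)
    baseline abundance; closure to the simplex is applied within each panel,
    so each row sums to 1 over every panel's subsets.
    """
    corr = spec.correlation_for(cohort)
    _check_correlation_matrix(corr, len(spec.subsets), cohort)
    subset_ids = spec.subset_ids()
    if n_subjects == 0:
        return pd.DataFrame(np.empty((0, len(subset_ids))), columns=subset_ids)

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    # eigen decomposition is robust to the semi-definite boundary case
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_subjects, len(subset_ids))) @ root.T

    base = np.array([s.base_proportion for s in spec.subsets])
    shift = np.array([s.cohort_logit_shift.get(cohort, 0.0) for s in spec.subsets])
    sd = np.array([s.between_subject_sd for s in spec.subsets])
    eta = _logit(base)[None, :] + shift[None, :] + z * sd[None, :]
    p = _expit(eta)

    out = np.empty_like(p)
    for panel in spec.panels:
        cols = [i for i, s in enumerate(spec.subsets) if s.panel_id == panel.panel_id]
        block = p[:, cols]
        out[:, cols] = block / block.sum(axis=1, keepdims=True)
    return pd.DataFrame(out, columns=subset_ids)


def synthesize_cells(
    proportions: pd.DataFrame,
    subsets: Sequence[SubsetSpec],
    panel: PanelSpec,
    n_cells: int,
    subject_meta: pd.DataFrame,
    batch_shifts: Mapping[tuple[str, int], np.ndarray] | None = None,
    seed: int = 0,
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[list[CellSample], dict[tuple[str, str], np.ndarray]]:
    """Emit raw-scale cell matrices for one panel from per-subject proportions.

    Cell counts per subset are multinomial; cells are Gaussian around the
    subset's arcsinh-space mean profile; batch offsets are added in arcsinh
    space; the matrix is mapped to the raw scale by sinh(y) * cofactor and
    clipped at zero. Returns the samples and per-sample true subset labels
    (indices into ``subsets`` order).

    ``subject_meta`` must be indexed by subject_id with columns
    ``cohort`` and ``batch`` (integer batch index).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    panel_subsets = [s for s in subsets if s.panel_id == panel.panel_id]
    sub_ids = [s.subset_id for s in panel_subsets]
    means = np.array([s.mean_profile for s in panel_subsets])
    disps = np.array([s.dispersion for s in panel_subsets])
    batch_shifts = batch_shifts or {}

    rng = np.random.default_rng(seed)
    samples: list[CellSample] = []
    labels: dict[tuple[str, str], np.ndarray] = {}
    for subject_id in proportions.index:
        p = proportions.loc[subject_id, sub_ids].to_numpy(float)
        p = p / p.sum()
        counts = rng.multinomial(n_cells, p)
        blocks, labs = [], []
        for j, c in enumerate(counts):
            if c == 0:
                continue
            blocks.append(means[j] + rng.standard_normal((c, means.shape[1])) * disps[j])
            labs.append(np.full(c, j, dtype=int))
        y = np.vstack(blocks)
        lab = np.concatenate(labs)
        order = rng.permutation(n_cells)
        y, lab = y[order], lab[order]

        batch = int(subject_meta.loc[subject_id, "batch"])
        shift = batch_shifts.get((panel.panel_id, batch))
        if shift is not None:
            y = y + np.asarray(shift, float)[None, :]
        raw = np.clip(np.sinh(y) * cofactor, 0.0, None)
        samples.append(
            CellSample(
                subject_id=str(subject_id),
                cohort=str(subject_meta.loc[subject_id, "cohort"]),
                batch=str(batch),
                panel=panel.panel_id,
                matrix=raw,
                marker_names=panel.marker_names,
                scale="raw",
            )
        )
        labels[(str(subject_id), panel.panel_id)] = lab
    return samples, labels


def simulate_cohort(
    spec: CohortSimSpec, seed: int | None = None
) -> tuple[list[CellSample], pd.DataFrame, GroundTruth]:
    """Simulate the full study: all cohorts, both panels, all batches.

    Returns (samples, sample_sheet, ground_truth). The sample sheet has one
    row per subject-panel file with columns subject_id, cohort, batch, panel.
    Subjects are allocated to batches round-robin within cohort.
    """
    master = np.random.default_rng(spec.seed if seed is None else seed)
    prop_frames, meta_rows = [], []
    for cohort, n in spec.n_subjects.items():
        props = sample_subject_proportions(
            spec, cohort, n, seed=int(master.integers(2**31))
        )
        props.index = [f"{cohort}_{i + 1:03d}" for i in range(n)]
        prop_frames.append(props)
        for i, sid in enumerate(props.index):
            meta_rows.append({"subject_id": sid, "cohort": cohort, "batch": i % spec.n_batches})
    proportions = pd.concat(prop_frames) if prop_frames else pd.DataFrame()
    subject_meta = pd.DataFrame(meta_rows).set_index("subject_id")

    samples: list[CellSample] = []
    cell_labels: dict[tuple[str, str], np.ndarray] = {}
    for panel in spec.panels:
        panel_samples, labels = synthesize_cells(
            proportions,
            spec.subsets,
            panel,
            spec.n_cells_per_sample,
            subject_meta,
            spec.batch_marker_shift,
            seed=int(master.integers(2**31)),
            cofactor=spec.cofactor,
        )
        samples.extend(panel_samples)
        cell_labels.update(labels)

    sheet = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "cohort": s.cohort,
                "group": spec.cohort_groups.get(s.cohort, s.cohort),
                "batch": s.batch,
                "panel": s.panel,
            }
            for s in samples
        ]
    )
    truth = GroundTruth(
        cell_labels=cell_labels,
        proportions=proportions,
        planted_correlation={c: spec.correlation_for(c) for c in spec.n_subjects},
        subset_ids=spec.subset_ids(),
        subset_lineages={s.subset_id: s.lineage for s in spec.subsets},
    )
    return samples, sheet, truth


def write_cohort(
    samples: Sequence[CellSample],
    out_dir: str | Path,
    format: str = "csv",
) -> pd.DataFrame:
    """Write per-sample matrices plus a TSV sample sheet; return the manifest.

    ``format`` is "csv" (header row of marker names) or "fcs" (FCS 3.1,
    marker names in $PnS). The manifest has one row per written file.
    """
    if format not in {"csv", "fcs"}:
        raise ValueError(f"unsupported format {format!r} (use 'csv' or 'fcs')")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"{s.subject_id}_{s.panel}.{format}"
        path = out / fname
        if format == "csv":
            pd.DataFrame(s.matrix, columns=list(s.marker_names)).to_csv(path, index=False)
        else:
            from .fcs import write_fcs

            write_fcs(path, s.matrix, list(s.marker_names))
        rows.append(
            {
                "subject_id": s.subject_id,
                "cohort": s.cohort,
                "batch": s.batch,
                "panel": s.panel,
                "file": fname,
                "n_cells": s.n_cells,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest[["subject_id", "cohort", "batch", "panel", "file"]].to_csv(
        out / "sample_sheet.tsv", sep="\t", index=False
    )
    (out / "manifest.json").write_text(json.dumps(rows, indent=1))
    return manifest


def read_cohort(in_dir: str | Path) -> list[CellSample]:
    """Read a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    sheet = pd.read_csv(in_dir / "sample_sheet.tsv", sep="\t", dtype=str)
    samples = []
    for _, row in sheet.iterrows():
        path = in_dir / row["file"]
        if path.suffix == ".csv":
            df = pd.read_csv(path)
            matrix, names = df.to_numpy(float), tuple(df.columns)
        elif path.suffix == ".fcs":
            from .fcs import read_fcs

            matrix, names = read_fcs(path)
        else:
            raise ValueError(f"unsupported sample file {path}")
        samples.append(
            CellSample(
                subject_id=row["subject_id"],
                cohort=row["cohort"],
                batch=row["batch"],
                panel=row["panel"],
                matrix=matrix,
                marker_names=names,
                scale="raw",
            )
        )
    return samples
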
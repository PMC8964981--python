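"""Shared containers and constants for the immunome-network pipeline.

A *sample* is one subject's cell x marker matrix from one antibody panel.
Raw intensities are on the mass-cytometry dual-count scale (nonnegative);
the transformed scale is arcsinh(x / cofactor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Divisor applied to raw intensities before the arcsinh transform.
DEFAULT_COFACTOR = 5.0

#: Major immune lineages a phenotype node can be assigned to.
LINEAGES = ("NK", "CD4T", "CD8T", "MAIT", "Treg", "B", "MonoDC", "other")

#: Lineages whose nodes enter the combined network from panel 1 (T/NK panel).
T_NK_LINEAGES = frozenset({"CD4T", "CD8T", "MAIT", "Treg", "NK"})

#: Lineages whose nodes enter the combined network from panel 2 (B/myeloid panel).
B_MYELOID_LINEAGES = frozenset({"B", "MonoDC"})


@dataclass
class CellSample:
    """One subject-panel matrix of cells x markers plus acquisition metadata."""

    subject_id: str
    cohort: str
    batch: str
    panel: str
    matrix: np.ndarray
    marker_names: tuple[str, ...]
    #: "raw" (dual-count scale), "arcsinh", or "normalized"
    scale: str = "raw"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x markers)")
        if self.matrix.shape[1] != len(self.marker_names):
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.marker_names)} marker names were given"
            )
        if np.isnan(self.matrix).any():
            raise ValueError("cell matrix contains missing values")
        self.marker_names = tuple(self.marker_names)

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    def with_matrix(self, matrix: np.ndarray, scale: str | None = None) -> "CellSample":
        """Copy of this sample with a new matrix (and optionally a new scale tag)."""
        return replace(self, matrix=matrix, scale=self.scale if scale is None else scale)

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.panel)
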
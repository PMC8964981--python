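"""Per-sample preprocessing: arcsinh transform, batch normalization, downsampling.

The pipeline order is fixed: arcsinh(x / cofactor) with cofactor 5, then
per-batch per-marker standardization of the pooled cells (which removes
additive batch offsets in transformed space), then seeded uniform
downsampling to a fixed cell count per sample.
"""

from __future__ import annotations

import warnings
import zlib
from collections import defaultdict
from typing import Sequence

import numpy as np

from .core import DEFAULT_COFACTOR, CellSample

__all__ = [
    "arcsinh_transform",
    "batch_scale_normalize",
    "downsample_cells",
    "preprocess_samples",
]


def arcsinh_transform(sample: CellSample, cofactor: float = DEFAULT_COFACTOR) -> CellSample:
    """Replace every intensity x by asinh(x / cofactor).

    The transform is strictly monotone and zero-preserving; it compresses the
    heavy right tail of dual-count intensities while staying ~linear near 0.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return sample.with_matrix(np.arcsinh(sample.matrix / cofactor), scale="arcsinh")


def inverse_arcsinh(matrix: np.ndarray, cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Inverse of the arcsinh transform: sinh(y) * cofactor."""
    return np.sinh(matrix) * cofactor


def batch_scale_normalize(samples: Sequence[CellSample]) -> list[CellSample]:
    """Standardize each marker to zero mean / unit sd within each (panel, batch).

    Statistics are pooled over all cells of a batch (never per sample, which
    would erase between-subject abundance signal). Constant columns map to
    all zeros. Samples must already be on the arcsinh scale.
    """
    groups: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, s in enumerate(samples):
        if s.scale != "arcsinh":
            raise ValueError(
                f"sample {s.subject_id}/{s.panel} is on scale {s.scale!r}; "
                "apply arcsinh_transform first"
            )
        groups[(s.panel, s.batch)].append(i)

    out: list[CellSample | None] = [None] * len(samples)
    for (panel, batch), idx in groups.items():
        pooled = np.vstack([samples[i].matrix for i in idx])
        if pooled.shape[0] == 0:
            raise ValueError(f"batch {batch!r} of panel {panel!r} has zero cells")
        mean = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns -> exactly zero
        for i in idx:
            out[i] = samples[i].with_matrix(
                (samples[i].matrix - mean) / sd_safe, scale="normalized"
            )
    return [s for s in out if s is not None]


def downsample_cells(sample: CellSample, target: int = 10_000, seed: int = 0) -> CellSample:
    """Uniform sample without replacement of ``target`` cells.

    Samples with fewer than ``target`` cells are kept whole with a warning;
    rows are never fabricated.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    n = sample.n_cells
    if n < target:
        warnings.warn(
            f"sample {sample.subject_id}/{sample.panel} has only {n} cells "
            f"(< target {target}); keeping all",
            stacklevel=2,
        )
        return sample
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(n, size=target, replace=False))
    out = sample.with_matrix(sample.matrix[rows])
    out.meta = dict(sample.meta, downsampled_rows=rows)
    return out


def preprocess_samples(
    samples: Sequence[CellSample],
    cofactor: float = DEFAULT_COFACTOR,
    target: int = 10_000,
    seed: int = 0,
) -> tuple[list[CellSample], list[dict]]:
    """Run transform -> batch-normalize -> downsample; return samples + log.

    Downsampling seeds are derived per sample from ``seed`` so the result
    does not depend on sample order.
    """
    transformed = [arcsinh_transform(s, cofactor) for s in samples]
    normalized = batch_scale_normalize(transformed)
    out, log = [], []
    for s in normalized:
        key_hash = zlib.crc32(f"{s.subject_id}|{s.panel}".encode())
        sub_seed = int(np.random.default_rng([seed, key_hash]).integers(2**31))
        d = downsample_cells(s, target=target, seed=sub_seed)
        out.append(d)
        log.append(
            {
                "subject_id": s.subject_id,
                "panel": s.panel,
                "batch": s.batch,
                "cofactor": cofactor,
                "cells_before": s.n_cells,
                "cells_after": d.n_cells,
                "seed": sub_seed,
            }
        )
    return out, log
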
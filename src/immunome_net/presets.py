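"""Ready-made simulation designs.

``study_spec`` mirrors the study conditions: two 36-marker panels sharing a
19-marker core, cohorts of 18 healthy controls and 32 heart-failure
subjects (14 preserved-EF, 14 reduced-EF, 4 mid-range), three acquisition
batches with additive marker offsets, planted case/control subset shifts,
and cohort-specific frequency-correlation structure: the control cohort is
block-modular (subsets co-vary tightly within lineage, bridged by a few
hub subsets), the case cohort is dispersed (weak within-lineage coupling,
scattered cross-lineage couplings, more negative couplings).

``small_spec`` is a seconds-scale smoke design (2 panels x 8 markers,
3 subsets per panel, 10+10 subjects).
"""

from __future__ import annotations

import numpy as np

from .cluster import GatingRule, GatingTable
from .simulate import CohortSimSpec, PanelSpec, SubsetSpec

__all__ = [
    "study_spec",
    "small_spec",
    "frequency_level_cohort",
    "SMALL_GATES",
    "block_correlation",
    "modular_correlation",
    "dispersed_correlation",
    "nearest_correlation",
]

_HI = 3.5  # arcsinh-space location of a "positive" marker
_LO = 0.7  # baseline (resting) location of a "negative" marker
_DISP = 0.35  # per-marker cell-level dispersion (separation/dispersion ~ 9)

SHARED_MARKERS = (
    "CD45", "CD3", "CD4", "CD8", "CD19", "CD14", "CD16", "CD56", "CD11c",
    "HLA-DR", "CD25", "CD45RO", "CD69", "CCR7", "CD161", "TNFa", "IFNg",
    "TCR-Va7.2", "FOXP3",
)
P1_ONLY = (
    "CD27", "CD28", "CD57", "NKG2D", "CX3CR1", "GNZB", "Perforin", "IL-21",
    "IL-10", "IL-4", "IL-17A", "IL-2", "CTLA4", "PD-1", "LAG3", "CD95", "KLRG1",
)
P2_ONLY = (
    "CD20", "IgD", "IgM", "CXCR5", "CD38", "CD123", "CD1c", "CCR2", "CD86",
    "CD163", "CD64", "CD11b", "CD36", "CD33", "IL-6", "IL-1b", "CD40",
)


def study_panels() -> tuple[PanelSpec, PanelSpec]:
    p1 = PanelSpec("P1", SHARED_MARKERS + P1_ONLY, SHARED_MARKERS)
    p2 = PanelSpec("P2", SHARED_MARKERS + P2_ONLY, SHARED_MARKERS)
    return p1, p2


def _profile(panel: PanelSpec, positives: dict[str, float]) -> tuple[float, ...]:
    prof = {m: _LO for m in panel.marker_names}
    prof["CD45"] = _HI  # all planted subsets are leukocytes
    for m, level in positives.items():
        prof[m] = level
    return tuple(prof[m] for m in panel.marker_names)


def _subset(
    panel: PanelSpec,
    subset_id: str,
    lineage: str,
    positives: dict[str, float] | tuple[str, ...],
    base: float,
    shifts: dict[str, float] | None = None,
) -> SubsetSpec:
    if not isinstance(positives, dict):
        positives = {m: _HI for m in positives}
    return SubsetSpec(
        subset_id=subset_id,
        lineage=lineage,
        panel_id=panel.panel_id,
        mean_profile=_profile(panel, positives),
        dispersion=(_DISP,) * panel.n_markers,
        base_proportion=base,
        cohort_logit_shift=shifts or {},
    )


def _hf_shift(delta: float) -> dict[str, float]:
    """The same logit shift in every heart-failure subgroup."""
    return {"HFpEF": delta, "HFrEF": delta, "HFmrEF": delta}


def study_subsets() -> tuple[SubsetSpec, ...]:
    """28-per-study planted subsets.

    Each panel resolves its focal lineages into several subsets that enter
    the combined network (T/NK from panel 1, B and monocyte/DC from panel 2)
    and carries the complementary lineages as larger independent "filler"
    subsets; keeping the co-varying network subsets individually small
    limits compositional-closure artifacts in the planted correlations.
    """
    p1, p2 = study_panels()
    s = [
        # --- panel 1: T / NK resolution (network subsets) ---
        _subset(p1, "NK_bright", "NK", ("CD56", "NKG2D", "GNZB"), 0.04),
        _subset(p1, "NK_cyto", "NK", ("CD56", "CD16", "CX3CR1", "GNZB", "IL-21"),
                0.04, _hf_shift(+0.8)),
        _subset(p1, "NK_reg", "NK", ("CD56", "IL-10", "IL-4"), 0.03),
        _subset(p1, "CD4_naive", "CD4T", ("CD3", "CD4", "CCR7", "CD27", "CD28"), 0.07),
        _subset(p1, "CD4_mem", "CD4T", ("CD3", "CD4", "CD45RO", "CD69", "CD28"),
                0.06, _hf_shift(-0.6)),
        _subset(p1, "CD4_th17", "CD4T", ("CD3", "CD4", "IL-17A", "CD45RO"), 0.04),
        _subset(p1, "Treg_p1", "Treg", ("CD3", "CD4", "CD25", "FOXP3"), 0.03),
        _subset(p1, "MAIT_p1", "MAIT", ("CD3", "TCR-Va7.2", "CD161", "TNFa", "IFNg"),
                0.04, {"HFpEF": +0.7}),
        _subset(p1, "CD8_naive", "CD8T", ("CD3", "CD8", "CCR7", "CD27"), 0.06),
        _subset(p1, "CD8_eff", "CD8T", ("CD3", "CD8", "GNZB", "IFNg", "TNFa", "LAG3"),
                0.05, _hf_shift(+0.5)),
        _subset(p1, "CD8_mem", "CD8T", ("CD3", "CD8", "CD45RO", "CD28"),
                0.05, _hf_shift(-0.6)),
        # --- panel 1: independent fillers (not in the combined network) ---
        _subset(p1, "B_p1", "B", ("CD19", "HLA-DR"), 0.09),
        _subset(p1, "Mono_cl_p1", "MonoDC", ("CD14", "CD11c", "HLA-DR"), 0.09),
        _subset(p1, "Mono_nc_p1", "MonoDC", ("CD16", "CD11c", "HLA-DR"), 0.07),
        _subset(p1, "DC_p1", "MonoDC", {"CD11c": _HI, "HLA-DR": 4.3, "IFNg": _HI, "CD95": _HI}, 0.06),
        _subset(p1, "gdT_p1", "other", ("CD3", "CD161"), 0.09),
        _subset(p1, "debris_p1", "other", {"CD45": 1.5}, 0.09),
        # --- panel 2: B / myeloid resolution (network subsets) ---
        _subset(p2, "B_naive", "B", ("CD19", "CD20", "IgD", "IgM", "CXCR5", "HLA-DR"),
                0.06, _hf_shift(+0.6)),
        _subset(p2, "B_mem", "B", ("CD19", "CD20", "CD40", "HLA-DR"), 0.05),
        _subset(p2, "B_act", "B", ("CD19", "CD20", "CXCR5", "CD86", "HLA-DR"),
                0.04, _hf_shift(+0.5)),
        _subset(p2, "Plasma", "B", {"CD19": _HI, "CD38": 4.3, "IgM": _HI}, 0.03),
        _subset(p2, "Mono_classical", "MonoDC",
                ("CD14", "CCR2", "CD36", "CD64", "CD33", "CD11b"),
                0.08, _hf_shift(-0.7)),
        _subset(p2, "Mono_nonclassical", "MonoDC", ("CD16", "CD11c", "CD86"), 0.06),
        _subset(p2, "Mono_inter", "MonoDC", ("CD14", "CD16", "CD11c", "HLA-DR"), 0.05),
        _subset(p2, "cDC", "MonoDC", ("CD11c", "CD1c", "CD16", "IFNg", "HLA-DR"),
                0.04, _hf_shift(+0.8)),
        _subset(p2, "pDC", "MonoDC", {"CD123": _HI, "HLA-DR": _HI, "CD11c": 1.8}, 0.03),
        # --- panel 2: independent fillers ---
        _subset(p2, "T4a_p2", "CD4T", ("CD3", "CD4", "CCR7"), 0.08),
        _subset(p2, "T4b_p2", "CD4T", ("CD3", "CD4", "CD45RO", "CD69"), 0.08),
        _subset(p2, "T8a_p2", "CD8T", ("CD3", "CD8", "CCR7"), 0.07),
        _subset(p2, "T8b_p2", "CD8T", ("CD3", "CD8", "CD45RO", "CD69"), 0.07),
        _subset(p2, "NK_p2", "NK", ("CD56", "CD16", "CD11b"), 0.08),
        _subset(p2, "NKbright_p2", "NK", {"CD56": _HI, "CCR7": _HI}, 0.05),
        _subset(p2, "Treg_p2", "Treg", ("CD3", "CD4", "CD25", "FOXP3"), 0.06),
        _subset(p2, "debris_p2", "other", {"CD45": 1.5}, 0.07),
    ]
    return tuple(s)


def nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone (eigenvalue clipping) and
    rescale to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    c = (vecs * np.clip(vals, 1e-6, None)) @ vecs.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return (c + c.T) / 2.0


def block_correlation(
    n: int, blocks: list[list[int]], r_within: float, r_between: float = 0.0
) -> np.ndarray:
    """Block-structured correlation matrix (PSD-repaired)."""
    c = np.full((n, n), r_between, dtype=float)
    for block in blocks:
        for i in block:
            for j in block:
                c[i, j] = r_within
    np.fill_diagonal(c, 1.0)
    return nearest_correlation(c)


def _network_subset_ids(subsets) -> list[str]:
    from .core import B_MYELOID_LINEAGES, T_NK_LINEAGES

    return [
        s.subset_id
        for s in subsets
        if (s.panel_id == "P1" and s.lineage in T_NK_LINEAGES)
        or (s.panel_id == "P2" and s.lineage in B_MYELOID_LINEAGES)
    ]


def _lineage_blocks(subsets, restrict_to: set[str] | None = None) -> dict[str, list[int]]:
    merge = {"Treg": "CD4T", "MAIT": "CD8T"}  # small lineages ride with their parent block
    blocks: dict[str, list[int]] = {}
    for i, s in enumerate(subsets):
        if s.lineage == "other":
            continue
        if restrict_to is not None and s.subset_id not in restrict_to:
            continue
        blocks.setdefault(merge.get(s.lineage, s.lineage), []).append(i)
    return blocks


def _corr_from_loadings(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix of a factor model (PSD by construction)."""
    c = loadings @ loadings.T
    resid = 1.0 - np.diag(c)
    if resid.min() < -1e-9:
        raise ValueError("factor loadings imply variance > 1")
    return c + np.diag(np.clip(resid, 0.0, None))


def modular_correlation(
    subsets, block_loading: float = 0.95, hub_loading: float = 0.7
) -> np.ndarray:
    """Control-cohort structure, built as a factor model.

    One latent factor per lineage block (network subsets load ~0.95, giving
    within-block r ~ 0.9); three designated hub subsets leave their block
    and load on two blocks each, bridging them (the source of high
    betweenness centralization); one NK subset anti-loads on the monocyte
    factor, planting a single negative coupling. Filler subsets stay
    independent.
    """
    ids = [s.subset_id for s in subsets]
    n = len(ids)
    kept = set(_network_subset_ids(subsets))
    blocks = _lineage_blocks(subsets, restrict_to=kept)
    fnames = list(blocks)
    loadings = np.zeros((n, len(fnames)))
    for f, block in enumerate(blocks.values()):
        for i in block:
            loadings[i, f] = block_loading
    bridges = [("CD4_mem", ("NK", "B")), ("Mono_inter", ("MonoDC", "B")),
               ("CD8_eff", ("CD8T", "MonoDC"))]
    for hub_id, (a, b) in bridges:
        h = ids.index(hub_id)
        loadings[h, :] = 0.0
        loadings[h, fnames.index(a)] = hub_loading
        loadings[h, fnames.index(b)] = hub_loading
    r = ids.index("NK_reg")
    loadings[r, :] = 0.0
    loadings[r, fnames.index("NK")] = 0.6
    loadings[r, fnames.index("MonoDC")] = -0.7
    return _corr_from_loadings(loadings)


def dispersed_correlation(
    subsets,
    core_size: int = 6,
    n_negative: int = 3,
    seed: int = 20240117,
) -> np.ndarray:
    """Case-cohort structure: one diffuse global factor.

    A random subset of network nodes loads strongly (0.82-0.95) on a single
    latent factor, forming a dense low-modularity cross-lineage core; a few
    nodes anti-load (negative couplings to the core); the rest load weakly.
    The per-structure seed is part of the design, not a run seed.
    """
    ids = [s.subset_id for s in subsets]
    n = len(ids)
    kept = _network_subset_ids(subsets)
    rng = np.random.default_rng(seed)
    loadings = np.zeros((n, 1))
    kidx = [ids.index(c) for c in kept]
    rng.shuffle(kidx)
    for i in kidx[:core_size]:
        loadings[i, 0] = rng.uniform(0.82, 0.95)
    for i in kidx[core_size : core_size + n_negative]:
        loadings[i, 0] = rng.uniform(-0.9, -0.8)
    for i in kidx[core_size + n_negative :]:
        loadings[i, 0] = rng.uniform(0.25, 0.5)
    for i in range(n):
        if ids[i] not in kept:
            loadings[i, 0] = rng.uniform(0.2, 0.4)
    return _corr_from_loadings(loadings)


def _batch_shifts(panels, n_batches: int, scale: float = 0.25, seed: int = 977) -> dict:
    """Additive arcsinh-space batch offsets; batch 0 is the reference."""
    rng = np.random.default_rng(seed)
    shifts = {}
    for p in panels:
        for b in range(n_batches):
            shifts[(p.panel_id, b)] = (
                np.zeros(p.n_markers) if b == 0 else rng.normal(0.0, scale, p.n_markers)
            )
    return shifts


def study_spec(
    n_cells_per_sample: int = 20_000,
    seed: int = 0,
) -> CohortSimSpec:
    """The full study-condition design (see module docstring)."""
    panels = study_panels()
    subsets = study_subsets()
    c_hc = modular_correlation(subsets)
    c_hf = dispersed_correlation(subsets)
    return CohortSimSpec(
        panels=panels,
        subsets=subsets,
        n_subjects={"HC": 18, "HFpEF": 14, "HFrEF": 14, "HFmrEF": 4},
        cohort_groups={"HFpEF": "HF", "HFrEF": "HF", "HFmrEF": "HF"},
        frequency_correlation={
            "HC": c_hc, "HFpEF": c_hf, "HFrEF": c_hf, "HFmrEF": c_hf
        },
        n_cells_per_sample=n_cells_per_sample,
        n_batches=3,
        batch_marker_shift=_batch_shifts(panels, 3),
        seed=seed,
    )


def frequency_level_cohort(spec: CohortSimSpec, n_subjects, seed: int = 0):
    """Sample subject proportions for each cohort and assemble the
    panel-combined node-frequency matrix directly, treating planted subsets
    as perfectly recovered phenotype nodes.

    This is the fast route for network-level experiments: it exercises the
    copula and the combination/network stages without synthesizing cells.
    ``n_subjects`` maps cohort label -> count.
    """
    import pandas as pd

    from .network import CombinedFrequencyMatrix
    from .simulate import sample_subject_proportions

    kept = _network_subset_ids(spec.subsets)
    lineage = {s.subset_id: s.lineage for s in spec.subsets}
    panel = {s.subset_id: s.panel_id for s in spec.subsets}
    rng = np.random.default_rng(seed)
    frames, meta = [], []
    for cohort, count in n_subjects.items():
        props = sample_subject_proportions(
            spec, cohort, count, seed=int(rng.integers(2**31))
        )
        props.index = [f"{cohort}_{i + 1:03d}" for i in range(count)]
        frames.append(props)
        group = spec.cohort_groups.get(cohort, cohort)
        meta += [(sid, cohort, group) for sid in props.index]
    values = pd.concat(frames)[kept]
    node_meta = pd.DataFrame(
        {"panel": [panel[c] for c in kept], "lineage": [lineage[c] for c in kept]},
        index=pd.Index(kept, name="node_id"),
    )
    subject_meta = pd.DataFrame(
        {"cohort": [c for _, c, _ in meta], "group": [g for _, _, g in meta]},
        index=[s for s, _, _ in meta],
    )
    return CombinedFrequencyMatrix(
        values=values, node_meta=node_meta, subject_meta=subject_meta
    )


SMALL_MARKERS = ("CD45", "CD3", "CD4", "CD56", "CD19", "CD14", "HLA-DR", "TNFa")

#: Reduced gate table matching the smoke design's 8-marker panels.
SMALL_GATES = GatingTable(
    rules=(
        GatingRule("CD4T", positive=("CD3", "CD4")),
        GatingRule("CD8T", positive=("CD3",), negative=("CD4",)),
        GatingRule("NK", positive=("CD56",), negative=("CD3",)),
        GatingRule("B", positive=("CD19",), negative=("CD3",)),
        GatingRule("MonoDC", positive=("CD14",), negative=("CD3", "CD19")),
    )
)


def small_spec(n_cells_per_sample: int = 2_000, seed: int = 0) -> CohortSimSpec:
    """Smoke-test design: 2 panels x 8 markers, 3 subsets each, 10+10 subjects."""
    p1 = PanelSpec("P1", SMALL_MARKERS, SMALL_MARKERS[:6])
    p2 = PanelSpec("P2", SMALL_MARKERS, SMALL_MARKERS[:6])
    subsets = (
        _subset(p1, "T4", "CD4T", ("CD3", "CD4"), 0.5),
        _subset(p1, "NK", "NK", ("CD56",), 0.3, {"HF": +0.6}),
        _subset(p1, "B1", "B", ("CD19", "HLA-DR"), 0.2),
        _subset(p2, "B2", "B", ("CD19", "HLA-DR"), 0.4, {"HF": +0.5}),
        _subset(p2, "Mono", "MonoDC", ("CD14", "HLA-DR", "TNFa"), 0.35),
        _subset(p2, "T4b", "CD4T", ("CD3", "CD4"), 0.25),
    )
    n = len(subsets)
    corr = block_correlation(n, [[0, 1], [3, 4]], 0.75)
    return CohortSimSpec(
        panels=(p1, p2),
        subsets=subsets,
        n_subjects={"HC": 10, "HF": 10},
        frequency_correlation={"*": corr},
        n_cells_per_sample=n_cells_per_sample,
        n_batches=2,
        batch_marker_shift=_batch_shifts((p1, p2), 2, seed=31),
        seed=seed,
    )
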
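# Methods

## Scope and data model

The package analyzes a two-panel mass-cytometry case/control cohort. A
*sample* is one subject's cells x markers matrix from one antibody panel on
the raw dual-count scale; a *sample sheet* links subject, cohort (and
analysis group), acquisition batch and panel. All downstream inference is
on *node frequencies*: per subject, the proportion of cells in each
phenotype cluster of one panel, which are compositional (they sum to one
per subject per panel).

## Preprocessing

- **Transform.** asinh(x / c), cofactor c = 5 (units: raw dual counts).
  Monotone and zero-preserving; ~linear near zero, logarithmic in the tail.
- **Batch normalization.** "Scale normalization" is implemented as
  per-batch, per-marker standardization (zero mean, unit sd) of the
  arcsinh values, pooling all cells of a batch *within a panel*. Pooling is
  never per sample — per-sample standardization would erase the
  between-subject abundance signal that the downstream stages analyze.
  Constant columns map to exactly zero rather than dividing by zero.
  Because the generator's batch effect is an additive offset in transformed
  space, this step removes it exactly; the test suite asserts across-batch
  mean agreement to 1e-9.
- **Downsampling.** Uniform without replacement to a target count
  (default 10,000 cells), seeded per sample with a seed derived from the
  stage seed and the sample key (so results do not depend on sample
  order). Samples below the target are kept whole with a warning; rows are
  never fabricated.
- Order of operations is fixed: transform → batch-normalize → downsample.

## Phenotype nodes

- **Clustering.** k-means on the pooled cells of one panel (all subjects
  and cohorts together, so node identities are shared across cohorts),
  k-means++ seeding, 30 restarts, keeping the restart with the lowest
  within-cluster sum of squares. 30 restarts (not the minimal 10) is a
  stability choice: with ~17 planted clusters of unequal size, occasional
  random initializations merge two adjacent small clusters and split a
  large one; across all tested realizations the extra restarts recover the
  global optimum.
- **k selection.** The elbow of the WCSS-vs-k curve, computed as the grid
  point of maximum perpendicular distance to the chord joining the curve's
  endpoints after normalizing both axes to [0,1]. A linear (knee-less)
  curve returns the smallest interior k with a warning. Default grid
  10..120 step 10 (80 is the published operating point); the desk-scale
  analyses use 8..26 step 3.
- **Phenotyping.** Per-node, per-marker median intensity; scaled medians
  are z-scores across nodes per marker (used for the heatmap and for
  gating). Empty nodes are flagged, their medians undefined.
- **Lineage gating.** An ordered rule table on scaled medians; a marker is
  "positive" above threshold 0 (i.e. above the across-node mean). Rules,
  most specific first: Treg (CD3+CD4+CD25+FOXP3+), MAIT
  (CD3+Vα7.2+CD161+), CD8 T (CD3+CD8+), CD4 T (CD3+CD4+CD8−), NK
  (CD3−CD56+), B (CD3−CD19+), monocyte/DC (CD3−CD19− with any of
  CD14/CD16/CD11c positive, expressed as three ordered rules); unmatched →
  "other". A gate referencing a marker absent from the panel is an error,
  not a silent skip.

## Differential abundance

Two-sided Wilcoxon rank-sum per node. Exact p by full enumeration of the
rank-sum null (dynamic programming over all C(n+m, n) assignments) when the
smaller group has ≤ 8 subjects and the pooled sample is untied; otherwise a
normal approximation with midranks, tie-corrected variance and a 0.5
continuity correction. Default significance is raw p < 0.05 with **no**
multiplicity correction, mirroring the study design; Benjamini–Hochberg is
available behind a flag and logs a caveat. Direction is the sign of the
case-minus-reference median difference.

## Interactome

- **Combination.** T/NK-lineage nodes from panel 1 and B and monocyte/DC
  nodes from panel 2, subjects restricted to those measured in both panels;
  node ids are panel-prefixed.
- **Edges.** Pearson correlation (Spearman by config) of node frequencies
  across the subjects of one cohort; an edge joins pairs with |r| strictly
  greater than 0.6 by default (the inclusive boundary is a config flag, as
  the two printed descriptions of the rule disagree). Zero-variance columns
  yield missing correlations and never edges. Isolated nodes stay in the
  graph.
- **Metrics** are computed on the unweighted, sign-blind graph; signs are
  retained as edge attributes and enter only the positive/negative counts.
  Betweenness centralization uses endpoint-excluded shortest-path counts
  (each unordered pair once) with Freeman star normalization
  (n−1)²(n−2)/2. Average path length averages over reachable unordered
  pairs only (the networks can be disconnected). Transitivity is undefined
  (reported missing) without connected triples. Communities come from
  deterministic greedy (Clauset–Newman–Moore) modularity maximization;
  an edgeless graph gets singleton communities and Q = 0 by convention.
  Reported Q is the modularity of the detected partition and is therefore
  algorithm-dependent.

## Synthetic cohorts

The generator emulates the study conditions: two 36-marker panels sharing
a 19-marker core; cohorts of 18 controls and 32 cases (14 preserved-EF /
14 reduced-EF / 4 mid-range, grouped as "HF"); three acquisition batches
(round-robin within cohort) with additive per-marker offsets in arcsinh
space (sd 0.25, reference batch zero); default 20,000 cells per sample.

- **Cells.** Each planted subset is a diagonal Gaussian in arcsinh space
  (positive markers at 3.5, bright variants 4.3, resting baseline 0.7,
  dispersion 0.35 — separation/dispersion ≈ 8-9 for the markers that
  distinguish a pair, and every subset pair differs in at least two
  markers). Cells are mapped to the raw scale by sinh(y)·5 and clipped at
  zero (dual counts are nonnegative). Per-subject subset counts are
  multinomial.
- **Frequencies.** A Gaussian copula on logit-proportions: per subject,
  correlated standard normals (cohort-specific correlation matrix, checked
  symmetric/unit-diagonal/PSD) scale a per-subset between-subject sd
  (0.5 logit units), shift the subset's baseline logit abundance (plus any
  cohort effect), and are closed to the simplex within each panel.
  Planted pairwise correlations survive closure to within ~0.05 Spearman
  because the co-varying network subsets are kept individually small
  (2–7% base abundance) while large independent "filler" subsets absorb
  the compositional constraint.
- **Planted cohort effects.** Case/control logit shifts of ±0.5–0.8 on
  selected subsets (NK and effector CD8 expanded, memory T and classical
  monocytes contracted, naive/activated B expanded, conventional DC
  expanded; MAIT expanded in the preserved-EF subgroup only).
- **Planted interactomes.** Correlation structures are factor models
  (PSD by construction). Control-like: one latent factor per lineage
  block (loadings 0.95 → within-block r ≈ 0.9), three hub subsets that
  leave their block and bridge two blocks each (loadings 0.7), and one NK
  subset anti-loading on the monocyte factor. Case-like: a single diffuse
  global factor with a 6-node strongly-loading cross-lineage core
  (0.82–0.95), three anti-loading nodes, and weak loadings elsewhere —
  a dense, community-less core with negative couplings. These designs,
  chosen from the qualitative published contrast and frozen, yield higher
  modularity and higher betweenness centralization for the control-like
  cohort in ≥ 18 of 20 replicates at the study's subject counts.

**What the generator does not emulate:** doublets, beads, debris-gating
artifacts, spillover, acquisition-time drift, non-Gaussian marker
distributions (real CyTOF markers are zero-inflated), panel-specific
staining efficiency, and any dependence between a subject's two panel
acquisitions beyond shared cohort membership. Passing tests therefore
demonstrate correctness of the pipeline's operations and recoverability of
planted structure under idealized mixtures — not performance on real data.

## Problem sizes and numerical choices

Desk-scale runs (analysis drivers, acceptance script) use 2,000 cells per
sample downsampled to 1,500, and the 8..26 step-3 elbow grid; these sizes
were chosen so the full chain runs in minutes on one CPU while keeping
≥ 85 cells per subset per sample in expectation. The directional
network experiment runs at the frequency level (planted subsets treated as
recovered nodes), which isolates the copula → correlation → topology path
and makes 20 replicates cheap; the cell-level path is exercised once per
run and in the truth-recovery tests.

Tolerances: proportion closure asserted to 1e-12; batch-mean agreement to
1e-9; graph metrics against brute-force oracles to 1e-10; exact rank-sum p
against full enumeration to 1e-12. Ties in gating (scaled median exactly at
threshold) count as negative. Downsampling sorts selected row indices, so
cell order within a sample is input order.

## Known limitations

- Compositional closure induces negative correlation between large
  co-varying subset groups; at this node resolution (~20 network nodes vs
  the published ~72) the synthetic cohorts' negative-edge percentages run
  higher than the published ones, though their case/control ordering is
  preserved. Closure artifacts shrink with node count.
- The exact rank-sum path requires an untied pooled sample; frequencies
  from finite cell counts can tie, in which case the corrected normal
  approximation is used even for small groups.
- Greedy modularity maximization gives a deterministic but not optimal
  partition; reported Q values are comparable within this package only.
- The minimal FCS 3.1 reader supports only the float list-mode files this
  package writes; CSV is the primary interchange format.
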
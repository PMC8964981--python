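# immunome-net

Circulating immune cells, profiled per subject by mass cytometry (CyTOF),
can be read at two levels: which phenotype subsets expand or contract in
disease, and how the *frequencies* of those subsets co-vary across subjects
— a correlation network (the "immuno-interactome") whose topology changes
when immune regulation is perturbed. This package implements that full
analysis for a two-panel case/control cohort design (healthy controls
versus heart-failure patients, with preserved/reduced ejection-fraction
subgroups), together with a synthetic cohort generator with known ground
truth, so every stage is testable without access to patient data.

The pipeline stages and their models:

1. **Preprocessing.** Raw dual-count intensities x are transformed as
   asinh(x / c) with cofactor c = 5; each marker is standardized to zero
   mean and unit variance within each acquisition batch (pooled over that
   batch's cells), which removes additive batch offsets exactly; each
   sample is then downsampled without replacement to a fixed cell count
   (default 10,000), seeded.
2. **Phenotype nodes.** Cells from all subjects of one panel are pooled and
   partitioned by k-means (careful seeding, 30 restarts, lowest
   within-cluster sum of squares wins); k is chosen by the elbow of the
   WCSS-vs-k curve, operationalized as the point of maximum perpendicular
   distance to the chord joining the curve's endpoints. Each node is
   summarized by per-marker medians, scaled across nodes (z-scores) for
   display, and gated into a lineage (NK, CD4 T, CD8 T, MAIT, Treg, B,
   monocyte/DC) by an ordered marker-gate table.
3. **Differential abundance.** Node frequencies per subject (proportions of
   that subject's cells) are compared between groups with a two-sided
   Wilcoxon rank-sum test — exact by enumeration for small untied groups,
   otherwise a tie- and continuity-corrected normal approximation — at raw
   p < 0.05 (Benjamini–Hochberg available behind a flag).
4. **Interactome.** T/NK nodes from panel 1 and B / monocyte-DC nodes from
   panel 2 are combined into one subjects x nodes matrix; within each
   cohort, node pairs with |Pearson r| > 0.6 (strict) become edges carrying
   the correlation sign. The comparative property suite on the unweighted
   graph: edge density m / C(n,2); Freeman betweenness centralization
   Σ(b_max − b_i) normalized by the star graph's maximum (n−1)²(n−2)/2;
   transitivity 3·triangles / connected triples; Newman–Girvan modularity
   Q = Σ_c [m_c/m − (d_c/2m)²] of greedily detected communities; mean
   shortest-path length over reachable pairs; signed edge counts; lineage
   mean degree; intra- vs inter-lineage edge classification.
5. **Synthetic cohorts.** Subsets are Gaussian mixtures in arcsinh space,
   inverse-mapped to the raw scale; subject-level subset frequencies follow
   a Gaussian copula on logit-proportions (closure to the simplex per
   panel) so that a chosen between-subject correlation structure — the
   planted interactome — can be imposed per cohort, along with logit-scale
   case/control abundance shifts and additive batch offsets.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic study-condition cohort (18 HC vs 32 HF, two 36-marker panels
sharing a 19-marker core, 3 batches; 2,000 cells per sample downsampled to
1,500):

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess.py
python analysis/03_cluster_nodes.py
python analysis/04_differential_abundance.py
python analysis/05_interactome.py
```

Output of the chain (abridged):

```
Preprocessed 100 samples (2000 -> 1500 cells each)
  max across-batch marker-mean deviation after normalization: 6.20e-16
P1: 17 nodes; lineage counts: {'MonoDC': 3, 'CD4T': 3, 'NK': 3, 'CD8T': 3, ...}
differential_P1_HF_vs_HC: 5/17 nodes significant
  n07 (NK): expanded, p=0.0000
  n12 (CD8T): reduced, p=0.0000
  ...
Contrast (control vs case):
  edge density   0.142 vs 0.105
  modularity     0.741 vs 0.000
  centralization 0.031 vs 0.001
  % negative     14.8 vs 55.0
```

Reading: batch normalization removes the planted batch effect to machine
precision; the elbow finds the planted subset resolution; the planted NK
expansion and CD8 contraction are recovered with the correct direction; and
the control cohort's network is denser, more modular and more centralized
than the case cohort's, which instead carries a higher share of negative
edges — the qualitative signature of a dysregulated immunome. Tables land
in `results/`, heavy intermediates in `scratch/` (not tracked).

The same pipeline is scriptable via the `immunome-net` CLI
(`simulate | preprocess | cluster | abundance | network | report |
run-all`) driven by a YAML config, or as a library (see
`immunome_net.pipeline.PipelineConfig`).

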
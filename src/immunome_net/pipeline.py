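"""Configuration-driven orchestration of the full analysis.

Stages (each independently runnable, each writing its artifacts into a run
directory): simulate -> preprocess -> cluster -> abundance -> network ->
report. Every stochastic stage takes an explicit seed from the config, so a
rerun with the same config is byte-identical for all tabular outputs.

Run-directory layout::

    run_dir/
      config.yaml
      data/                 simulated (or user-provided) raw cohort + sample sheet
      processed/            preprocessed per-sample matrices + processing_log.json
      clustering/           node tables, WCSS curves, centroids, assignments
      abundance/            frequency matrices + differential-node tables
      network/              edge lists, GraphML, property table
      report.md
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .abundance import FrequencyMatrix, differential_nodes, frequency_matrix
from .cluster import (
    DEFAULT_GATES,
    NodeModel,
    annotate_lineage,
    elbow_select_k,
    kmeans_cluster,
    node_phenotype,
    pool_cells,
)
from .network import combine_panels, network_compare
from .preprocess import preprocess_samples
from .simulate import read_cohort, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults mirror the study's printed parameters
    (arcsinh cofactor 5, 10,000-cell downsampling, |r| > 0.6 strict edges,
    raw p < 0.05)."""

    input_dir: str | None = None  # read an existing cohort instead of simulating
    preset: str = "small"  # "small" or "study" simulation preset
    n_cells: int | None = None  # override preset cells/sample
    cofactor: float = 5.0
    downsample_target: int = 10_000
    k: int | None = None  # fixed node count per panel; None -> elbow selection
    k_grid: list[int] = field(default_factory=lambda: list(range(2, 13)))
    n_restarts: int = 30
    threshold: float = 0.6
    strict: bool = True
    alpha: float = 0.05
    adjust: str = "none"
    correlation_method: str = "pearson"
    groupings: list[list[str]] = field(default_factory=lambda: [["HF", "HC"]])
    network_cohorts: list[str] = field(default_factory=lambda: ["HC", "HF"])
    gates: str = "default"  # "default" or "small"
    seed_simulate: int = 0
    seed_downsample: int = 1
    seed_cluster: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def gating_table(self):
        return DEFAULT_GATES if self.gates == "default" else presets.SMALL_GATES


def _sim_spec(config: PipelineConfig):
    if config.preset == "small":
        spec = presets.small_spec(seed=config.seed_simulate)
    elif config.preset == "study":
        spec = presets.study_spec(seed=config.seed_simulate)
    else:
        raise ValueError(f"unknown preset {config.preset!r}")
    if config.n_cells is not None:
        spec = dataclasses.replace(spec, n_cells_per_sample=config.n_cells)
    return spec


def stage_simulate(config: PipelineConfig, run_dir: Path) -> None:
    spec = _sim_spec(config)
    samples, _, truth = simulate_cohort(spec, seed=config.seed_simulate)
    data_dir = run_dir / "data"
    manifest = write_cohort(samples, data_dir, format="csv")
    truth.proportions.to_csv(data_dir / "true_proportions.tsv", sep="\t")
    sheet = manifest[["subject_id", "cohort", "batch", "panel", "file"]].copy()
    sheet.insert(2, "group", [spec.cohort_groups.get(c, c) for c in sheet["cohort"]])
    sheet.to_csv(data_dir / "sample_sheet.tsv", sep="\t", index=False)


def stage_preprocess(config: PipelineConfig, run_dir: Path) -> None:
    data_dir = run_dir / "data"
    if not data_dir.is_dir():
        raise FileNotFoundError(f"input directory not found: {data_dir}")
    samples = read_cohort(data_dir)
    processed, log_entries = preprocess_samples(
        samples,
        cofactor=config.cofactor,
        target=config.downsample_target,
        seed=config.seed_downsample,
    )
    out = run_dir / "processed"
    out.mkdir(parents=True, exist_ok=True)
    for s in processed:
        pd.DataFrame(s.matrix, columns=list(s.marker_names)).to_csv(
            out / f"{s.subject_id}_{s.panel}.csv", index=False
        )
    (out / "processing_log.json").write_text(json.dumps(log_entries, indent=1))


def stage_cluster(config: PipelineConfig, run_dir: Path) -> None:
    sheet = pd.read_csv(run_dir / "data" / "sample_sheet.tsv", sep="\t", dtype=str)
    proc_dir = run_dir / "processed"
    out = run_dir / "clustering"
    out.mkdir(parents=True, exist_ok=True)
    for panel in sorted(sheet["panel"].unique()):
        panel_sheet = sheet[sheet["panel"] == panel]
        mats, keys = [], []
        marker_names: tuple[str, ...] = ()
        for _, row in panel_sheet.iterrows():
            df = pd.read_csv(proc_dir / f"{row.subject_id}_{panel}.csv")
            marker_names = tuple(df.columns)
            mats.append(df.to_numpy(float))
            keys.append((row.subject_id, panel))
        cells = np.vstack(mats)
        offsets = np.cumsum([0] + [m.shape[0] for m in mats])
        if config.k is None:
            k, curve = elbow_select_k(
                cells, k_grid=config.k_grid, seed=config.seed_cluster
            )
            curve.to_csv(out / f"wcss_{panel}.tsv", sep="\t", index=False)
        else:
            k = config.k
        model = kmeans_cluster(
            cells,
            k,
            seed=config.seed_cluster,
            n_restarts=config.n_restarts,
            sample_keys=keys,
            offsets=offsets,
            marker_names=marker_names,
        )
        pheno = node_phenotype(model, cells)
        pheno["lineage"] = annotate_lineage(pheno, config.gating_table())
        pheno.to_csv(out / f"node_table_{panel}.tsv", sep="\t")
        pd.DataFrame(model.centroids, index=list(model.node_ids), columns=list(marker_names)).to_csv(
            out / f"centroids_{panel}.tsv", sep="\t"
        )
        # heatmap-ready matrix: nodes x markers scaled medians
        pheno[[c for c in pheno.columns if c.startswith("scaled_")]].to_csv(
            out / f"heatmap_{panel}.tsv", sep="\t"
        )
        rows = []
        for (subject_id, _), labels in model.assignments.items():
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_id,
                        "cell_index": np.arange(len(labels)),
                        "node_id": [model.node_ids[j] for j in labels],
                    }
                )
            )
        pd.concat(rows).to_csv(out / f"assignments_{panel}.tsv", sep="\t", index=False)


def _load_frequency(run_dir: Path, panel: str) -> FrequencyMatrix:
    """Rebuild a FrequencyMatrix from the clustering stage's artifacts."""
    sheet = pd.read_csv(run_dir / "data" / "sample_sheet.tsv", sep="\t", dtype=str)
    node_table = pd.read_csv(
        run_dir / "clustering" / f"node_table_{panel}.tsv", sep="\t", index_col=0
    )
    assignments = pd.read_csv(run_dir / "clustering" / f"assignments_{panel}.tsv", sep="\t")
    node_ids = list(node_table.index)
    idx = {n: i for i, n in enumerate(node_ids)}
    model = NodeModel(
        k=len(node_ids),
        centroids=pd.read_csv(
            run_dir / "clustering" / f"centroids_{panel}.tsv", sep="\t", index_col=0
        ).to_numpy(float),
        assignments={
            (str(subj), panel): grp["node_id"].map(idx).to_numpy(int)
            for subj, grp in assignments.groupby("subject_id", sort=True)
        },
        marker_names=(),
        wcss=float("nan"),
        node_ids=tuple(node_ids),
    )
    return frequency_matrix(model, sheet, panel=panel, lineages=node_table["lineage"])


def stage_abundance(config: PipelineConfig, run_dir: Path) -> None:
    sheet = pd.read_csv(run_dir / "data" / "sample_sheet.tsv", sep="\t", dtype=str)
    out = run_dir / "abundance"
    out.mkdir(parents=True, exist_ok=True)
    for panel in sorted(sheet["panel"].unique()):
        freq = _load_frequency(run_dir, panel)
        freq.values.to_csv(out / f"frequencies_{panel}.tsv", sep="\t")
        labels = set(freq.subject_meta["cohort"]) | set(
            freq.subject_meta.get("group", pd.Series(dtype=str))
        )
        for grouping in config.groupings:
            case, ref = grouping
            if case not in labels or ref not in labels:
                continue
            diff = differential_nodes(
                freq, (case, ref), alpha=config.alpha, adjust=config.adjust
            )
            diff.to_csv(out / f"differential_{panel}_{case}_vs_{ref}.tsv", sep="\t")


def stage_network(config: PipelineConfig, run_dir: Path) -> None:
    import networkx as nx

    sheet = pd.read_csv(run_dir / "data" / "sample_sheet.tsv", sep="\t", dtype=str)
    panels = sorted(sheet["panel"].unique())
    if len(panels) != 2:
        raise ValueError(f"panel combination expects 2 panels, found {panels}")
    freq_p1 = _load_frequency(run_dir, panels[0])
    freq_p2 = _load_frequency(run_dir, panels[1])
    combined = combine_panels(freq_p1, freq_p2)
    out = run_dir / "network"
    out.mkdir(parents=True, exist_ok=True)
    combined.values.to_csv(out / "combined_frequencies.tsv", sep="\t")
    nets, table = network_compare(
        combined,
        cohorts=config.network_cohorts,
        threshold=config.threshold,
        strict=config.strict,
        method=config.correlation_method,
    )
    table.to_csv(out / "network_properties.tsv", sep="\t")
    table.to_json(out / "network_properties.json", indent=1)
    for cohort, net in nets.items():
        edges = pd.DataFrame(
            [
                {"node_u": u, "node_v": v, "r": d["r"], "sign": d["sign"]}
                for u, v, d in net.graph.edges(data=True)
            ]
        )
        edges.to_csv(out / f"edges_{cohort}.tsv", sep="\t", index=False)
        nx.write_graphml(net.graph, out / f"network_{cohort}.graphml")


def render_report(run_dir: str | Path) -> Path:
    """Assemble the run's headline tables into a markdown report."""
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.yaml"
    net_dir = run_dir / "network"
    ab_dir = run_dir / "abundance"
    if not net_dir.is_dir() or not ab_dir.is_dir():
        raise FileNotFoundError("incomplete run: abundance/network artifacts missing")

    lines = ["# Immune-network analysis report", ""]
    if cfg_path.exists():
        lines += ["## Configuration", "", "```yaml", cfg_path.read_text().rstrip(), "```", ""]

    lines += ["## Differentially abundant nodes", ""]
    diff_files = sorted(ab_dir.glob("differential_*.tsv"))
    for f in diff_files:
        diff = pd.read_csv(f, sep="\t", index_col=0)
        sig = diff[diff["significant"]]
        lines.append(f"### {f.stem.removeprefix('differential_')}")
        lines.append("")
        if sig.empty:
            lines.append("No nodes were significantly altered.")
        else:
            lines.append(sig.to_markdown())
        lines.append("")

    lines += ["## Network property comparison", ""]
    props = pd.read_csv(net_dir / "network_properties.tsv", sep="\t", index_col=0)
    lines += [props.to_markdown(), ""]
    pct = props.loc["pct_neg_edges"] if "pct_neg_edges" in props.index else None
    if pct is not None:
        lines += ["Negative-edge percentages: "
                  + ", ".join(f"{c} = {v:.1f}%" for c, v in pct.items()
                              if c != "delta" and pd.notna(v)), ""]
    deg_rows = [r for r in props.index if str(r).startswith("mean_degree_")]
    if deg_rows:
        lines += ["## Lineage mean degree", "", props.loc[deg_rows].to_markdown(), ""]

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "cluster": stage_cluster,
    "abundance": stage_abundance,
    "network": stage_network,
}


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute every stage in order; returns the run directory.

    With ``config.input_dir`` set, the simulate stage is replaced by reading
    the existing cohort from that directory.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    for name, stage in _STAGES.items():
        if name == "simulate" and config.input_dir is not None:
            src = Path(config.input_dir)
            if not src.is_dir():
                raise FileNotFoundError(f"input directory not found: {src}")
            dst = run_dir / "data"
            if src.resolve() != dst.resolve():
                import shutil

                shutil.copytree(src, dst, dirs_exist_ok=True)
            continue
        try:
            stage(config, run_dir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    render_report(run_dir)
    return run_dir
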
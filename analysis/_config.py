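"""Shared configuration for the numbered analysis drivers.

One run directory under scratch/ holds the heavy per-stage artifacts; each
driver copies its headline tables into results/.
"""

from pathlib import Path

from immunome_net.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "study_run"
RESULTS = ROOT / "results"

# Study-condition two-panel cohort at desk-scale cell counts: 18 HC vs 32 HF
# (14 HFpEF / 14 HFrEF / 4 HFmrEF), 3 batches, 2,000 cells per sample
# downsampled to 1,500; elbow-selected k; |r| > 0.6 strict network edges.
CONFIG = PipelineConfig(
    preset="study",
    n_cells=2000,
    downsample_target=1500,
    k=None,
    k_grid=list(range(8, 27, 3)),
    gates="default",
    groupings=[["HF", "HC"], ["HFpEF", "HFrEF"]],
    network_cohorts=["HC", "HF"],
    seed_simulate=11,
    seed_downsample=12,
    seed_cluster=13,
)
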
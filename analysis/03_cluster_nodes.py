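"""Cluster pooled cells into phenotype nodes per panel.

k is selected by the elbow of the WCSS curve; each node is summarized by
its per-marker median (plus across-node scaled medians for the heatmap) and
gated into a major immune lineage.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import CONFIG, RESULTS, RUN_DIR

from immunome_net.pipeline import stage_cluster

stage_cluster(CONFIG, RUN_DIR)

for panel in ("P1", "P2"):
    nodes = pd.read_csv(RUN_DIR / "clustering" / f"node_table_{panel}.tsv",
                        sep="\t", index_col=0)
    nodes.to_csv(RESULTS / f"node_table_{panel}.tsv", sep="\t")
    wcss_file = RUN_DIR / "clustering" / f"wcss_{panel}.tsv"
    if wcss_file.exists():
        pd.read_csv(wcss_file, sep="\t").to_csv(RESULTS / f"wcss_{panel}.tsv",
                                                sep="\t", index=False)
    print(f"{panel}: {len(nodes)} nodes; lineage counts:",
          dict(nodes.lineage.value_counts()))
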
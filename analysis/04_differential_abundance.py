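"""Per-subject node frequencies and differential abundance.

Wilcoxon rank-sum per node, HF vs HC (and HFpEF vs HFrEF), raw p < 0.05 as
in the study design; significant nodes are listed with their lineage and
direction.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _config import CONFIG, RESULTS, RUN_DIR

from immunome_net.pipeline import stage_abundance

stage_abundance(CONFIG, RUN_DIR)

for f in sorted((RUN_DIR / "abundance").glob("differential_*.tsv")):
    diff = pd.read_csv(f, sep="\t", index_col=0)
    diff.to_csv(RESULTS / f.name, sep="\t")
    sig = diff[diff.significant]
    print(f"{f.stem}: {len(sig)}/{len(diff)} nodes significant")
    for node, row in sig.iterrows():
        print(f"  {node} ({row.lineage}): {row.direction}, p={row.p_value:.4f}")
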
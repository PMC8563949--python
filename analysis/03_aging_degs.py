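"""Call aging DEGs per cell type (ROTS statistic, donor-stratified
permutation, BH FDR within cell type).

Writes deg/deg_table.csv and prints the per-type up/down DEG counts together
with recovery of the planted aging genes.
"""

import json

import pandas as pd

from _common import CONFIG, OUTDIR, SEED
from retatlas.pipeline import run_pipeline

run_pipeline(CONFIG, OUTDIR, seed=SEED, stages=["deg"])

degs = pd.read_csv(OUTDIR / "deg" / "deg_table.csv")
called = degs[degs.is_deg]
counts = (
    called.groupby(["cell_type", "direction"]).size().unstack(fill_value=0)
    .reindex(columns=["up", "down"], fill_value=0)
)
print("aging DEGs per cell type (fdr < 0.05):")
print(counts.to_string())

truth = json.loads((OUTDIR / "raw" / "ground_truth.json").read_text())
hits = total = 0
for ctype, planted in truth["true_degs"].items():
    planted_genes = {g for g, _ in planted}
    got = set(called.loc[called.cell_type == ctype, "gene"])
    hits += len(planted_genes & got)
    total += len(planted_genes)
print(f"planted aging genes recovered: {hits}/{total} ({100 * hits / max(total, 1):.0f}%)")
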
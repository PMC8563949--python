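"""Generate the synthetic retinal aging atlas (counts, metadata, gene sets).

Writes results/atlas_run/raw/: MatrixMarket counts, metadata TSV, gene sets
as GMT, ground truth JSON and the ligand-receptor pair table.
"""

import pandas as pd

from _common import CONFIG, OUTDIR, SEED
from retatlas.pipeline import run_pipeline

manifest = run_pipeline(CONFIG, OUTDIR, seed=SEED, stages=["simulate"])
meta = pd.read_csv(OUTDIR / "raw" / "metadata.tsv", sep="\t")
print(f"simulated {len(meta)} cells, {meta.true_type.nunique()} cell types, "
      f"{meta.donor.nunique()} donors, layers: {sorted(meta.layer.unique())}")
print(meta.groupby(["layer", "age_group"]).size().rename("cells").to_string())
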
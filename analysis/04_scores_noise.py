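"""SASP score per cell with young/old comparison, and CV transcriptional
noise per (cell type, age group).

Writes scores/*.csv and prints the overall SASP medians plus the cell types
whose old cells show significantly elevated CV.
"""

import pandas as pd

from _common import CONFIG, OUTDIR, SEED
from retatlas.pipeline import run_pipeline

run_pipeline(CONFIG, OUTDIR, seed=SEED, stages=["scores"])

comp = pd.read_csv(OUTDIR / "scores" / "score_comparison.csv")
sasp = comp[comp.set == "SASP"].iloc[0]
print(f"SASP score medians: young {sasp.median_young:.3f}, old {sasp.median_old:.3f} "
      f"(Wilcoxon p = {sasp.p:.2e})")

cv = pd.read_csv(OUTDIR / "scores" / "cv_comparison.csv")
elevated = cv[(cv.median_cv_old > cv.median_cv_young) & (cv.p < 0.01)]
print("cell types with elevated old-cell transcriptional noise (p < 0.01):",
      ", ".join(elevated.cell_type) or "none")
print(cv.round(3).to_string(index=False))
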
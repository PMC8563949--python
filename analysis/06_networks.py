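"""DEG-geneset overlap networks, gene-set enrichment of the focal type's
DEGs, and the correlation-based regulatory network for RPE cells.

Writes networks/* and prints node counts and the top regulators by
connection count.
"""

import pandas as pd

from _common import CONFIG, OUTDIR, SEED
from retatlas.pipeline import run_pipeline

run_pipeline(CONFIG, OUTDIR, seed=SEED, stages=["networks"])

for direction in ("up", "down"):
    nodes = pd.read_csv(OUTDIR / "networks" / f"overlap_{direction}.nodes.csv")
    if nodes.empty:
        print(f"overlap network ({direction}): empty")
        continue
    top = nodes.sort_values("n_cell_types", ascending=False).head(5)
    print(f"overlap network ({direction}): {len(nodes)} genes; multi-type genes:")
    print(top.round(3).to_string(index=False))

conn = pd.read_csv(OUTDIR / "networks" / "regulatory_RPE.connections.csv")
if conn.empty:
    print("regulatory network: no edges above the correlation threshold")
else:
    print("top regulators of RPE down-DEGs by connection count:")
    print(conn.head(10).to_string(index=False))
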
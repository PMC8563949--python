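"""Ligand-receptor interaction activity per age group and delta classes
(newborn / disappeared / unchanged) between young and old.

Writes interactions/records.csv + summary.json and prints the totals and
every planted interaction with its detected class.
"""

import json

import pandas as pd

from _common import CONFIG, OUTDIR, SEED
from retatlas.pipeline import run_pipeline

run_pipeline(CONFIG, OUTDIR, seed=SEED, stages=["interactions"])

summary = json.loads((OUTDIR / "interactions" / "summary.json").read_text())
print("interaction totals:", summary["totals"])
records = pd.read_csv(OUTDIR / "interactions" / "records.csv")
print(records.to_string(index=False))
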
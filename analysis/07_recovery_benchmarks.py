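"""Planted-truth recovery and calibration benchmarks across all stages.

Re-generates fresh data per benchmark (separate from the 01-06 atlas run)
and writes results/benchmarks.json.  This is the same battery reported by
scripts/acceptance.py.
"""

import json
from pathlib import Path

from _common import SEED
from retatlas import benchmarks

out = {
    "clustering": benchmarks.clustering_recovery(seed=SEED),
    "deg_null_calibration": benchmarks.rots_null_calibration(seed=SEED),
    "deg_recovery": benchmarks.deg_recovery(seed=SEED),
    "sasp_recovery": benchmarks.sasp_recovery(seed=SEED, n_seeds=50),
    "cv_noise_recovery": benchmarks.cv_noise_recovery(seed=SEED, n_seeds=50),
    "interaction_recovery": benchmarks.interaction_recovery(seed=SEED),
    "regulator_recovery": benchmarks.regulator_recovery(seed=SEED, n_seeds=50),
}
path = Path(__file__).resolve().parent.parent / "results" / "benchmarks.json"
path.parent.mkdir(parents=True, exist_ok=True)
path.write_text(json.dumps(out, indent=1))
for name, res in out.items():
    print(name, res)
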
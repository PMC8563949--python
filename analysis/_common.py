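"""Shared configuration for the numbered analysis drivers.

The study system: a synthetic 15-cell-type retinal/choroidal atlas (young and
old groups, 8 donors each, two tissue layers) with planted markers, aging
DEGs, a SASP shift, old-cell noise and age-dependent ligand-receptor
activity.  All drivers write into results/atlas_run and share one seed.
"""

from pathlib import Path

from retatlas.pipeline import PipelineConfig

SEED = 1
OUTDIR = Path(__file__).resolve().parent.parent / "results" / "atlas_run"

CONFIG = PipelineConfig.from_dict(
    {
        "synthetic": {
            "n_cell_types": 15,
            "cells_per_type_per_group": 40,
            "n_genes": 1500,
            "n_aging_degs_per_type": 20,
            "nb_dispersion_old_multiplier": 2.0,
            "noisy_types": ["Rod", "Mast"],
        },
        "qc": {
            "min_genes_per_cell": 100,
            "min_counts_per_cell": 200,
            "min_cells_per_gene": 3,
        },
        "deg_params": {"alpha1": 0.1, "alpha2": 1.0},
        "deg_n_permutation": 200,
        "regulatory_cell_type": "RPE",
    }
)
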
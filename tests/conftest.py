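import numpy as np
import pytest

from retatlas.qcnorm import normalize
from retatlas.syndata import SimConfig, generate_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """Three cell types, all signal classes planted, desk-scale."""
    cfg = SimConfig(
        n_cell_types=3,
        cells_per_type_per_group=30,
        n_genes=400,
        n_markers_per_type=15,
        n_aging_degs_per_type=15,
        donors_per_group=8,
        seed=42,
    )
    counts, meta, sets, truth = generate_atlas(cfg)
    meta = meta.assign(cell_type=truth.type_labels)
    expr = normalize(counts)
    return cfg, counts, meta, expr, sets, truth


@pytest.fixture(scope="session")
def null_atlas():
    """Exchangeable across age groups: no planted aging effect of any kind."""
    cfg = SimConfig(
        n_cell_types=1,
        cells_per_type_per_group=40,
        n_genes=300,
        n_aging_degs_per_type=0,
        sasp_old_multiplier=1.0,
        nb_dispersion_old_multiplier=1.0,
        lr_pairs=[],
        seed=7,
    )
    counts, meta, sets, truth = generate_atlas(cfg)
    meta = meta.assign(cell_type=truth.type_labels)
    expr = normalize(counts)
    return cfg, counts, meta, expr, sets, truth
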
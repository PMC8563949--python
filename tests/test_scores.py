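"""Gene-set scoring, group comparisons and CV transcriptional noise."""

import numpy as np
import pandas as pd
import pytest

from retatlas.qcnorm import ExpressionMatrix
from retatlas.scores import (
    GeneSetCollection,
    geneset_score,
    read_gmt,
    score_group_comparison,
    transcriptional_noise_cv,
    write_gmt,
)


def _em(arr, genes=None, cells=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(arr, genes, cells)


def _meta(cells, age, ctype="all"):
    return pd.DataFrame(
        {
            "cell_id": cells,
            "donor": ["d"] * len(cells),
            "age_group": age,
            "sex": ["f"] * len(cells),
            "layer": ["neural"] * len(cells),
            "cell_type": [ctype] * len(cells) if isinstance(ctype, str) else ctype,
        }
    )


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"SASP": ["IL6", "CXCL8"], "AMD": ["APOE", "VEGFA", "TSPAN10"]},
            {"SASP": "senescence secretome", "AMD": "macular degeneration"},
        )
        write_gmt(coll, tmp_path / "sets.gmt")
        back = read_gmt(tmp_path / "sets.gmt")
        assert back.sets == coll.sets
        assert back.provenance == coll.provenance

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"bad": []})

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("onlyname\tdesc\n")
        with pytest.raises(ValueError, match="3 fields"):
            read_gmt(p)


class TestGenesetScore:
    def test_score_is_plain_mean_of_set_genes(self):
        em = _em([[1.0], [2.0], [3.0], [9.0]])
        meta = _meta(em.cell_ids, ["young"])
        out = geneset_score(em, GeneSetCollection({"s": ["g0", "g1", "g2"]}), meta)
        assert out.score.iloc[0] == pytest.approx(2.0)

    def test_all_zero_genes_score_zero(self):
        em = _em(np.zeros((3, 2)))
        meta = _meta(em.cell_ids, ["young", "old"])
        out = geneset_score(em, GeneSetCollection({"s": ["g0", "g1"]}), meta)
        assert np.allclose(out.score, 0.0)

    def test_missing_genes_dropped_but_empty_intersection_fails(self):
        em = _em([[1.0], [3.0]])
        meta = _meta(em.cell_ids, ["young"])
        out = geneset_score(em, GeneSetCollection({"s": ["g0", "nope"]}), meta)
        assert out.score.iloc[0] == pytest.approx(1.0)
        with pytest.raises(KeyError, match="no genes present"):
            geneset_score(em, GeneSetCollection({"ghost": ["nope"]}), meta)

    def test_linear_in_expression(self, small_atlas):
        _, _, meta, expr, sets, truth = small_atlas
        coll = GeneSetCollection({"SASP": truth.true_sasp_genes})
        base = geneset_score(expr, coll, meta).score.to_numpy()
        scaled_vals = expr.values.copy()
        idx = expr.gene_index(truth.true_sasp_genes)
        scaled_vals[idx] *= 3.0
        scaled = ExpressionMatrix(scaled_vals, expr.gene_ids, expr.cell_ids)
        np.testing.assert_allclose(geneset_score(scaled, coll, meta).score, 3 * base)

    def test_planted_sasp_elevation_detected(self):
        from retatlas.qcnorm import normalize
        from retatlas.syndata import SimConfig, generate_atlas

        cfg = SimConfig(
            n_cell_types=1, cells_per_type_per_group=200, n_genes=200,
            sasp_old_multiplier=2.0, n_aging_degs_per_type=0, lr_pairs=[], seed=6,
        )
        counts, meta, _, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        out = geneset_score(
            normalize(counts), GeneSetCollection({"SASP": truth.true_sasp_genes}), meta
        )
        comp = score_group_comparison(out)
        assert comp.median_old.iloc[0] > comp.median_young.iloc[0]
        assert comp.p.iloc[0] < 0.01


class TestScoreComparison:
    def test_identical_distributions_zero_delta(self):
        scores = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(20)],
                "set": "s",
                "score": list(range(10)) * 2,
                "age_group": ["young"] * 10 + ["old"] * 10,
                "cell_type": "all",
            }
        )
        comp = score_group_comparison(scores)
        assert comp.delta.iloc[0] == 0.0

    def test_constant_shift_recovered(self):
        scores = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(20)],
                "set": "s",
                "score": list(np.arange(10.0)) + list(np.arange(10.0) + 0.5),
                "age_group": ["young"] * 10 + ["old"] * 10,
                "cell_type": "all",
            }
        )
        assert score_group_comparison(scores).delta.iloc[0] == pytest.approx(0.5)

    def test_single_group_stratum_skipped(self):
        scores = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(12)],
                "set": "s",
                "score": np.arange(12.0),
                "age_group": ["young"] * 6 + ["old"] * 6,
                "cell_type": ["A"] * 6 + ["B"] * 6,
            }
        )
        comp = score_group_comparison(scores, stratify="cell_type")
        assert comp.empty  # A is young-only, B is old-only


class TestTranscriptionalNoise:
    def test_cv_closed_form_and_constant_gene(self):
        # gene values {1, 3} in a 2-cell stratum: mean 2, sample SD sqrt(2),
        # cv = sqrt(2)/2; a constant gene has cv 0
        em = _em(np.array([[1.0, 3.0], [2.0, 2.0]]))
        meta = _meta(em.cell_ids, ["young"] * 2, "A")
        cv_table, _, _ = transcriptional_noise_cv(em, meta, min_mean=0.0, min_cells=2)
        cv = cv_table.set_index("gene").cv
        assert cv["g0"] == pytest.approx(np.sqrt(2) / 2)
        assert cv["g1"] == 0.0

    def test_cv_scale_invariant(self, small_atlas):
        _, _, meta, expr, _, _ = small_atlas
        t1, _, _ = transcriptional_noise_cv(expr, meta)
        scaled = ExpressionMatrix(expr.values * 7.0, expr.gene_ids, expr.cell_ids)
        t2, _, _ = transcriptional_noise_cv(scaled, meta, min_mean=0.7)
        merged = t1.merge(t2, on=["cell_type", "age_group", "gene"])
        np.testing.assert_allclose(merged.cv_x, merged.cv_y, rtol=1e-10)

    def test_low_expression_genes_filtered(self):
        em = _em(np.vstack([np.full(12, 0.01), np.full(12, 5.0)]))
        meta = _meta(em.cell_ids, ["young"] * 12, "A")
        cv_table, summary, _ = transcriptional_noise_cv(em, meta, min_mean=0.1)
        assert set(cv_table.gene) == {"g1"}
        assert summary.n_genes.iloc[0] == 1

    def test_planted_dispersion_raises_old_cv_only_in_noisy_type(self):
        from retatlas.qcnorm import normalize
        from retatlas.syndata import SimConfig, generate_atlas

        cfg = SimConfig(
            n_cell_types=2, cells_per_type_per_group=60, n_genes=250,
            nb_dispersion_old_multiplier=2.0, noisy_types=["CT01"],
            n_aging_degs_per_type=0, sasp_old_multiplier=1.0, lr_pairs=[], seed=5,
        )
        counts, meta, _, truth = generate_atlas(cfg)
        meta = meta.assign(cell_type=truth.type_labels)
        _, _, comp = transcriptional_noise_cv(normalize(counts), meta)
        comp = comp.set_index("cell_type")
        assert comp.loc["CT01", "median_cv_old"] > comp.loc["CT01", "median_cv_young"]
        assert comp.loc["CT01", "p"] < 0.01
        ratio_unaffected = (
            comp.loc["CT02", "median_cv_old"] / comp.loc["CT02", "median_cv_young"]
        )
        assert ratio_unaffected == pytest.approx(1.0, abs=0.1)
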
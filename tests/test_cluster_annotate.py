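"""HVG selection, clustering recovery, marker ranking and annotation rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from retatlas.cluster_annotate import (
    annotate_clusters,
    cross_species_correlation,
    embed_cluster,
    rank_markers,
    select_hvgs,
    type_mean_profiles,
)
from retatlas.qcnorm import ExpressionMatrix


def _em(arr, genes=None, cells=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(arr, genes, cells)


class TestSelectHVGs:
    def test_constant_gene_never_beats_variable_ones(self):
        rng = np.random.default_rng(0)
        arr = rng.gamma(2, 1, size=(20, 50))
        arr[3] = 1.0  # constant
        chosen = select_hvgs(_em(arr), n_top=19)
        assert "g3" not in chosen

    def test_planted_high_dispersion_gene_selected(self, small_atlas):
        expr = small_atlas[3]
        noisy = expr.values.copy()
        rng = np.random.default_rng(1)
        noisy[7] = rng.choice([0.0, 5.0], size=noisy.shape[1])  # huge dispersion
        em = _em(noisy, genes=expr.gene_ids, cells=expr.cell_ids)
        assert em.gene_ids[7] in select_hvgs(em, n_top=40)

    def test_n_top_equal_gene_count_is_identity_set(self, small_atlas):
        expr = small_atlas[3]
        assert set(select_hvgs(expr, n_top=len(expr.gene_ids))) == set(expr.gene_ids)


class TestEmbedCluster:
    def test_two_separated_types_recovered_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.2, size=(30, 40))
        b = rng.normal(3, 0.2, size=(30, 40))
        em = _em(np.abs(np.hstack([a, b])))
        res = embed_cluster(em, em.gene_ids, n_clusters=2, seed=0)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_single_cluster_and_determinism(self, small_atlas):
        expr = small_atlas[3]
        hvgs = select_hvgs(expr, 100)
        one = embed_cluster(expr, hvgs, n_clusters=1, seed=0)
        assert set(one.labels) == {0}
        r1 = embed_cluster(expr, hvgs, n_clusters=3, seed=5)
        r2 = embed_cluster(expr, hvgs, n_clusters=3, seed=5)
        assert np.array_equal(r1.labels, r2.labels)

    def test_more_clusters_than_cells_rejected(self):
        em = _em(np.ones((5, 3)))
        with pytest.raises(ValueError, match="exceeds cell count"):
            embed_cluster(em, em.gene_ids, n_clusters=4)


class TestRankMarkers:
    def test_exclusive_gene_avg_diff_equals_its_mean(self):
        arr = np.zeros((3, 6))
        arr[0, :3] = 4.0  # gene g0 only in type A
        arr[1] = 1.0
        arr[2] = np.arange(6)
        table = rank_markers(_em(arr), ["A"] * 3 + ["B"] * 3, top_n=3)
        row = table[(table.gene == "g0") & (table.cell_type == "A")].iloc[0]
        assert row.avg_diff == pytest.approx(4.0)
        assert row["rank"] == 1
        flat = table[(table.gene == "g1")]
        assert np.allclose(flat.avg_diff, 0.0)

    def test_planted_markers_occupy_top_ranks(self):
        # markers are the only planted signal here, so they should fill the
        # top ranks of their own type essentially exactly
        from retatlas.qcnorm import normalize
        from retatlas.syndata import SimConfig, generate_atlas

        cfg = SimConfig(
            n_cell_types=3, cells_per_type_per_group=40, n_genes=300,
            n_markers_per_type=10, marker_log2fc=2.0, n_aging_degs_per_type=0,
            sasp_old_multiplier=1.0, lr_pairs=[], seed=21,
        )
        counts, meta, _, truth = generate_atlas(cfg)
        expr = normalize(counts)
        table = rank_markers(expr, truth.type_labels, top_n=cfg.n_markers_per_type)
        for ctype, markers in truth.true_markers.items():
            top = set(table[table.cell_type == ctype].gene)
            hits = len(top & set(markers)) / len(markers)
            assert hits >= 0.9, (ctype, hits)

    def test_markers_with_competing_aging_signal(self, small_atlas):
        cfg, _, meta, expr, _, truth = small_atlas
        table = rank_markers(expr, meta["cell_type"].to_numpy(), top_n=2 * cfg.n_markers_per_type)
        for ctype, markers in truth.true_markers.items():
            top = set(table[table.cell_type == ctype].gene)
            assert len(top & set(markers)) / len(markers) >= 0.9, ctype

    def test_invariant_to_cell_and_gene_order(self, small_atlas):
        _, _, meta, expr, _, _ = small_atlas
        labels = meta["cell_type"].to_numpy()
        base = rank_markers(expr, labels, top_n=20)
        rng = np.random.default_rng(3)
        cp = rng.permutation(len(expr.cell_ids))
        gp = rng.permutation(len(expr.gene_ids))
        shuffled = ExpressionMatrix(
            expr.values[np.ix_(gp, cp)],
            [expr.gene_ids[i] for i in gp],
            [expr.cell_ids[i] for i in cp],
        )
        other = rank_markers(shuffled, labels[cp], top_n=20)
        key = ["cell_type", "rank"]
        b = base.sort_values(key).reset_index(drop=True)
        o = other.sort_values(key).reset_index(drop=True)
        assert b.gene.tolist() == o.gene.tolist()
        np.testing.assert_allclose(b.avg_diff, o.avg_diff, rtol=1e-10)

    def test_needs_two_labels(self, small_atlas):
        expr = small_atlas[3]
        with pytest.raises(ValueError):
            rank_markers(expr, ["A"] * len(expr.cell_ids))


class TestAnnotateClusters:
    def test_marker_reference_maps_cluster_to_type(self):
        # cluster 0 uniquely expresses the "RPE" reference markers (TYR, RPE65)
        arr = np.tile(np.array([[0.2], [0.1], [3.0]]), (1, 8))
        arr[0, :4], arr[1, :4], arr[2, :4] = 5.0, 4.0, 0.0
        em = _em(arr, genes=["TYR", "RPE65", "PDE6A"])
        labels = [0] * 4 + [1] * 4
        ref = {"RPE": ["TYR", "RPE65"], "Rod": ["PDE6A"]}
        assert annotate_clusters(em, labels, ref) == {0: "RPE", 1: "Rod"}

    def test_cluster_without_reference_signal_is_unknown(self):
        rng = np.random.default_rng(4)
        em = _em(rng.gamma(1, 1, size=(5, 10)))
        out = annotate_clusters(em, [0] * 5 + [1] * 5, {"T": ["g0"]}, min_score=10.0)
        assert set(out.values()) == {"unknown"}

    def test_exact_tie_goes_to_lexicographically_smaller(self):
        arr = np.zeros((2, 4))
        arr[0, :2] = arr[1, :2] = 2.0
        em = _em(arr)
        out = annotate_clusters(
            em, [0, 0, 1, 1], {"beta": ["g0"], "alpha": ["g1"]}, min_score=0.0
        )
        assert out[0] == "alpha"

    def test_empty_reference_rejected(self, small_atlas):
        expr = small_atlas[3]
        with pytest.raises(ValueError, match="empty"):
            annotate_clusters(expr, [0] * len(expr.cell_ids), {})


class TestCrossSpecies:
    def _profiles(self, vec):
        return {"pr": pd.Series(vec, index=[f"o{i}" for i in range(len(vec))])}

    def test_self_correlation_is_one_and_reversal_minus_one(self):
        base = np.arange(10.0)
        orth = pd.DataFrame({s: [f"o{i}" for i in range(10)] for s in ("a", "b")})
        same = cross_species_correlation(
            {"a": self._profiles(base), "b": self._profiles(base)}, orth
        )
        assert same.spearman_r.iloc[0] == pytest.approx(1.0)
        rev = cross_species_correlation(
            {"a": self._profiles(base), "b": self._profiles(base[::-1])}, orth
        )
        assert rev.spearman_r.iloc[0] == pytest.approx(-1.0)

    def test_closer_species_correlates_higher(self):
        rng = np.random.default_rng(5)
        human = rng.gamma(2, 1, 50)
        monkey = human + rng.normal(0, 0.1, 50)   # close
        mouse = human + rng.normal(0, 2.0, 50)    # distant
        orth = pd.DataFrame(
            {s: [f"o{i}" for i in range(50)] for s in ("human", "monkey", "mouse")}
        )
        out = cross_species_correlation(
            {
                "human": self._profiles(human),
                "monkey": self._profiles(monkey),
                "mouse": self._profiles(mouse),
            },
            orth,
        ).set_index(["species_a", "species_b"])
        assert (
            out.loc[("human", "monkey"), "spearman_r"]
            > out.loc[("human", "mouse"), "spearman_r"]
        )

    def test_no_shared_orthologs_is_error(self):
        orth = pd.DataFrame({"a": ["x"], "b": ["y"]})
        profs = {
            "a": {"pr": pd.Series([1.0, 2.0], index=["p", "q"])},
            "b": {"pr": pd.Series([1.0, 2.0], index=["r", "s"])},
        }
        with pytest.raises(ValueError, match="orthologs"):
            cross_species_correlation(profs, orth)

    def test_type_mean_profiles_shapes(self, small_atlas):
        _, _, meta, expr, _, _ = small_atlas
        profs = type_mean_profiles(expr, meta["cell_type"].to_numpy())
        assert set(profs) == set(meta["cell_type"])
        assert all(len(v) == len(expr.gene_ids) for v in profs.values())
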
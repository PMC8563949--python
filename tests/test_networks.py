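"""Enrichment arithmetic, overlap-network weights, regulator ranking."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retatlas.networks import enrich_terms, overlap_network, regulatory_network
from retatlas.qcnorm import ExpressionMatrix, normalize
from retatlas.scores import GeneSetCollection
from retatlas.syndata import SimConfig, generate_atlas


def hypergeom_tail_oracle(N, K, n, k):
    """Exact upper-tail sum of binomial-coefficient ratios."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
    )


class TestEnrichTerms:
    def test_closed_form_fully_contained_list(self):
        universe = [f"g{i}" for i in range(10)]
        out = enrich_terms(universe[:5], {"T": universe[:5]}, universe)
        assert out.p.iloc[0] == pytest.approx(1 / comb(10, 5), abs=1e-15)

    def test_disjoint_term_overlap_zero_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = enrich_terms(universe[:3], {"T": universe[5:]}, universe)
        assert out.overlap.iloc[0] == 0
        assert out.p.iloc[0] == pytest.approx(1.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_combinatorial_oracle_small_universes(self, data):
        N = data.draw(st.integers(4, 20))
        universe = [f"g{i}" for i in range(N)]
        term = data.draw(st.sets(st.sampled_from(universe), min_size=1))
        lst = data.draw(st.sets(st.sampled_from(universe), min_size=1))
        out = enrich_terms(sorted(lst), {"T": sorted(term)}, universe).iloc[0]
        expected = hypergeom_tail_oracle(N, len(term), len(lst), out.overlap)
        assert out.p == pytest.approx(expected, abs=1e-12)

    def test_q_monotone_in_p_rank(self):
        universe = [f"g{i}" for i in range(20)]
        ann = {f"T{j}": universe[j : j + 6] for j in range(10)}
        out = enrich_terms(universe[:6], ann, universe)
        assert (np.diff(out.q) >= -1e-12).all()

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="empty"):
            enrich_terms([], {"T": ["g0"]}, ["g0"])
        with pytest.raises(ValueError, match="universe"):
            enrich_terms(["missing"], {"T": ["g0"]}, ["g0"])


def _deg_table(rows):
    df = pd.DataFrame(rows, columns=["cell_type", "gene", "log2fc", "direction"])
    df["d"] = 1.0
    df["p"] = 0.001
    df["fdr"] = 0.001
    df["is_deg"] = True
    return df


class TestOverlapNetwork:
    def test_gene_in_three_types_has_node_weight_three(self):
        degs = _deg_table(
            [("RPE", "EGFR", 1.0, "up"), ("EC", "EGFR", 2.0, "up"),
             ("RGC", "EGFR", 3.0, "up"), ("RPE", "OTHER", 1.0, "up")]
        )
        net = overlap_network(degs, GeneSetCollection({"GenAge": ["EGFR"]}), "up")
        node = net.nodes.set_index("gene").loc["EGFR"]
        assert node.n_cell_types == 3
        assert node.mean_log2fc == pytest.approx(2.0)
        assert net.edges.avg_log2fc.iloc[0] == pytest.approx(2.0)

    def test_no_intersection_gives_empty_network(self):
        degs = _deg_table([("RPE", "AAA", 1.0, "up")])
        net = overlap_network(degs, GeneSetCollection({"GenAge": ["ZZZ"]}), "up")
        assert net.nodes.empty and net.edges.empty

    def test_direction_validated(self):
        degs = _deg_table([("RPE", "AAA", 1.0, "up")])
        with pytest.raises(ValueError, match="direction"):
            overlap_network(degs, GeneSetCollection({"S": ["AAA"]}), "sideways")

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_on_random_tables(self, data):
        genes = [f"g{i}" for i in range(30)]
        types = ["T1", "T2", "T3", "T4"]
        rows = data.draw(
            st.lists(
                st.tuples(
                    st.sampled_from(types), st.sampled_from(genes),
                    st.floats(-3, 3, allow_nan=False), st.sampled_from(["up", "down"]),
                ),
                min_size=1, max_size=40, unique_by=lambda r: (r[0], r[1]),
            )
        )
        degs = _deg_table(rows)
        set_genes = data.draw(st.sets(st.sampled_from(genes), min_size=1))
        sets = GeneSetCollection({"S": sorted(set_genes)})
        net = overlap_network(degs, sets, "up")
        # brute force
        expected = {}
        for _, r in degs.iterrows():
            if r.direction == "up" and r.gene in set_genes:
                expected.setdefault(r.gene, []).append(r.log2fc)
        assert set(net.nodes.gene) == set(expected)
        for g, fcs in expected.items():
            node = net.nodes.set_index("gene").loc[g]
            assert node.n_cell_types == len(fcs)
            assert node.mean_log2fc == pytest.approx(np.mean(fcs))

    def test_node_weight_bounded_by_type_count(self, small_atlas):
        _, _, meta, expr, sets, truth = small_atlas
        from retatlas.aging_de import RotsParams, call_degs

        degs = call_degs(
            expr, meta, params=RotsParams(0.1, 1.0, seed=1), n_permutation=100
        ).table
        n_types = degs.cell_type.nunique()
        for direction in ("up", "down"):
            net = overlap_network(degs, sets, direction)
            if not net.nodes.empty:
                assert net.nodes.n_cell_types.max() <= n_types


class TestRegulatoryNetwork:
    def _atlas(self, seed=7):
        cfg = SimConfig(
            n_cell_types=1, cells_per_type_per_group=60, n_genes=150,
            n_markers_per_type=0, n_aging_degs_per_type=0, sasp_old_multiplier=1.0,
            lr_pairs=[], plant_regulator=True, seed=seed,
        )
        counts, meta, sets, truth = generate_atlas(cfg)
        return normalize(counts), meta.assign(cell_type=truth.type_labels), sets, truth

    def test_identical_profiles_get_weight_one(self):
        arr = np.vstack([np.arange(12.0), np.arange(12.0), np.ones(12)])
        em = ExpressionMatrix(arr, ["TF", "TARGET", "FLAT"], [f"c{i}" for i in range(12)])
        meta = pd.DataFrame(
            {"cell_id": em.cell_ids, "donor": "d", "age_group": "young",
             "sex": "f", "layer": "neural", "cell_type": "A"}
        )
        net = regulatory_network(em, meta, "A", ["TF", "TARGET", "FLAT"], ["TF"])
        edge = net.edges.set_index("target").loc["TARGET"]
        assert edge.weight == pytest.approx(1.0)

    def test_impossible_threshold_gives_empty_network(self):
        expr, meta, sets, truth = self._atlas()
        reg = truth.regulator
        net = regulatory_network(
            expr, meta, "CT01", [reg["tf"], *reg["targets"]], [reg["tf"]],
            min_abs_corr=1.01,
        )
        assert net.edges.empty

    def test_no_candidate_tfs_warns_and_returns_empty(self, caplog):
        expr, meta, _, truth = self._atlas()
        net = regulatory_network(
            expr, meta, "CT01", truth.regulator["targets"], ["NOT_A_GENE"]
        )
        assert net.edges.empty and net.top_regulators == []

    def test_planted_regulator_ranks_first(self):
        expr, meta, sets, truth = self._atlas(seed=11)
        reg = truth.regulator
        deg_genes = [reg["tf"], *reg["targets"], *reg["decoy_tfs"]]
        net = regulatory_network(expr, meta, "CT01", deg_genes, sets["TF"])
        assert net.top_regulators[0] == reg["tf"]
        top = net.connections.iloc[0]
        assert top.n_connections >= 10

    def test_invariant_to_cell_order_and_threshold_monotone(self):
        expr, meta, sets, truth = self._atlas()
        reg = truth.regulator
        deg_genes = [reg["tf"], *reg["targets"]]
        base = regulatory_network(expr, meta, "CT01", deg_genes, [reg["tf"]])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr.cell_ids))
        shuffled = ExpressionMatrix(
            expr.values[:, perm], expr.gene_ids, [expr.cell_ids[i] for i in perm]
        )
        again = regulatory_network(shuffled, meta, "CT01", deg_genes, [reg["tf"]])
        pd.testing.assert_frame_equal(base.edges, again.edges)
        stricter = regulatory_network(
            expr, meta, "CT01", deg_genes, [reg["tf"]], min_abs_corr=0.6
        )
        assert len(stricter.edges) <= len(base.edges)
        assert set(stricter.edges.target) <= set(base.edges.target)
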
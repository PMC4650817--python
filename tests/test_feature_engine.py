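"""Feature encoding of method outputs, checked cell-by-cell against
brute-force pairwise enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverec import (
    FeatureMatrix,
    MethodOutput,
    build_feature_matrix,
    fln_topk_feature,
    gene_pvalue_feature,
    module_avg_weight_feature,
    module_count_feature,
)
from driverec.feature_engine import KIND_DEFAULT, method_feature


# -- oracles: exhaustive pairwise enumeration ------------------------------

def oracle_topk(edges, gene, top, k):
    top = top[:k]
    return sum(
        w for (a, b), w in edges.items()
        for t in top
        if {a, b} == {gene, t}
    ) / len(top)


def oracle_module_count(edges, modules, gene):
    interior = set().union(*modules)
    links = sum(
        1 for (a, b) in edges
        if gene in (a, b) and ({a, b} - {gene}) <= interior and a != b
    )
    return (2 if gene in interior else 1) * links


def oracle_avg_weight(edges, modules, gene):
    interior = set().union(*modules) - {gene}
    if not interior:
        return 0.0
    total = sum(
        w for (a, b), w in edges.items()
        if gene in (a, b) and ({a, b} - {gene}) <= interior
    )
    return total / len(interior)


# -- gene-level P-value feature --------------------------------------------

class TestGenePvalueFeature:
    def setup_method(self):
        self.out = MethodOutput(
            method_id="oncodrivefm",
            kind="gene_pvalue",
            pvalues={"BRCA1": 0.02, "TP53": 0.0},
        )

    def test_present_gene_returns_its_pvalue(self):
        assert gene_pvalue_feature(self.out, "BRCA1") == 0.02

    def test_absent_gene_imputed_as_one(self):
        assert gene_pvalue_feature(self.out, "NOTHERE") == 1.0

    def test_zero_pvalue_boundary(self):
        assert gene_pvalue_feature(self.out, "TP53") == 0.0

    def test_malformed_pvalue_names_gene_and_method(self):
        with pytest.raises(ValueError, match="badmeth.*BADGENE|BADGENE.*badmeth"):
            MethodOutput(
                method_id="badmeth", kind="gene_pvalue", pvalues={"BADGENE": 1.5}
            )

    def test_wrong_kind_rejected(self, toy_module_count_output):
        with pytest.raises(ValueError, match="gene_pvalue"):
            gene_pvalue_feature(toy_module_count_output, "A")


# -- FLN top-k average-weight feature --------------------------------------

class TestFlnTopkFeature:
    def test_mean_over_exact_top_list(self):
        out = MethodOutput(
            method_id="fln", kind="ranked_list",
            network=[("G", "T1", 0.2), ("G", "T2", 0.4)],
            top_genes=["T1", "T2"],
        )
        assert fln_topk_feature(out, "G", k=2) == pytest.approx(0.3)

    def test_gene_with_no_edges_to_top_scores_zero(self):
        out = MethodOutput(
            method_id="fln", kind="ranked_list",
            network=[("A", "B", 0.9)],
            top_genes=["T1", "T2"],
        )
        assert fln_topk_feature(out, "A", k=2) == 0.0

    def test_single_edge_among_100_top_genes(self):
        top = [f"T{i}" for i in range(100)]
        edges = {("G1", "T37"): 0.5}
        out = MethodOutput(
            method_id="fln", kind="ranked_list",
            network=[(a, b, w) for (a, b), w in edges.items()],
            top_genes=top,
        )
        got = fln_topk_feature(out, "G1", k=100)
        assert got == pytest.approx(0.005)
        assert got == pytest.approx(oracle_topk(out.network, "G1", top, 100))

    def test_empty_top_list_is_configuration_error(self):
        out = MethodOutput(
            method_id="fln", kind="ranked_list", network=[("A", "B", 1.0)]
        )
        with pytest.raises(ValueError, match="top"):
            fln_topk_feature(out, "A")


# -- module link-count feature ---------------------------------------------

class TestModuleCountFeature:
    def test_interior_gene_doubles_link_count(self, toy_module_count_output):
        # A is interior with links to B and C: 2 links * 2
        assert module_count_feature(toy_module_count_output, "A") == 4

    def test_exterior_gene_counts_links_once(self, toy_module_count_output):
        # D is exterior with links to A, B, C: 3 links * 1
        assert module_count_feature(toy_module_count_output, "D") == 3

    def test_gene_with_no_interior_links(self, toy_module_count_output):
        # E only touches D, which is exterior
        assert module_count_feature(toy_module_count_output, "E") == 0

    def test_absent_gene_scores_zero(self, toy_module_count_output):
        assert module_count_feature(toy_module_count_output, "ZZ") == 0

    def test_matches_enumeration_oracle(self, toy_module_count_output):
        out = toy_module_count_output
        for gene in "ABCDE":
            assert module_count_feature(out, gene) == oracle_module_count(
                out.network, out.modules, gene
            )

    def test_duplicating_links_doubles_feature(self):
        # homogeneity: a graph with each interior link twice (via a second
        # interior module member wired identically) doubles the count
        base = MethodOutput(
            method_id="m", kind="module_count",
            modules=[{"A", "B"}], network=[("X", "A", 1.0)],
        )
        doubled = MethodOutput(
            method_id="m", kind="module_count",
            modules=[{"A", "B"}], network=[("X", "A", 1.0), ("X", "B", 1.0)],
        )
        assert module_count_feature(doubled, "X") == 2 * module_count_feature(base, "X")


# -- module average-weight feature -----------------------------------------

class TestModuleAvgWeightFeature:
    def test_mean_weight_to_two_gene_module(self):
        out = MethodOutput(
            method_id="flnp", kind="module_weighted",
            modules=[{"A", "B"}],
            network=[("G", "A", 0.1), ("G", "B", 0.3)],
        )
        assert module_avg_weight_feature(out, "G") == pytest.approx(0.2)

    def test_no_edges_to_interior_scores_zero(self):
        out = MethodOutput(
            method_id="flnp", kind="module_weighted",
            modules=[{"A", "B"}], network=[("G", "X", 0.9)],
        )
        assert module_avg_weight_feature(out, "G") == 0.0

    def test_single_edge_into_three_gene_module(self):
        out = MethodOutput(
            method_id="flnp", kind="module_weighted",
            modules=[{"A", "B", "C"}], network=[("G", "A", 0.6)],
        )
        assert module_avg_weight_feature(out, "G") == pytest.approx(0.6 / 3)

    def test_matches_enumeration_oracle(self, toy_module_weighted_output):
        out = toy_module_weighted_output
        for gene in "ABCDE":
            assert module_avg_weight_feature(out, gene) == pytest.approx(
                oracle_avg_weight(out.network, out.modules, gene)
            )

    def test_empty_module_set_is_configuration_error(self):
        out = MethodOutput(
            method_id="flnp", kind="module_weighted", network=[("A", "B", 1.0)]
        )
        with pytest.raises(ValueError, match="module"):
            module_avg_weight_feature(out, "A")


# -- exhaustive random-graph property check --------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    n_nodes=st.integers(4, 20),
    kind=st.sampled_from(["module_count", "module_weighted", "ranked_list"]),
)
def test_network_features_equal_bruteforce_on_random_small_graphs(
    seed, n_nodes, kind
):
    rng = np.random.default_rng(seed)
    genes = [f"N{i}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.4:
                edges.append((genes[i], genes[j], float(rng.uniform(0, 1))))
    module = set(rng.choice(genes, size=max(2, n_nodes // 3), replace=False))
    top = list(rng.permutation(genes)[: max(2, n_nodes // 2)])
    out = MethodOutput(
        method_id="m", kind=kind, modules=[module] if kind != "ranked_list" else [],
        network=edges, top_genes=top if kind == "ranked_list" else [],
    )
    for gene in genes:
        got = method_feature(out, gene, k=len(top) if top else 100)
        if kind == "module_count":
            want = oracle_module_count(out.network, out.modules, gene)
        elif kind == "module_weighted":
            want = oracle_avg_weight(out.network, out.modules, gene)
        else:
            want = oracle_topk(out.network, gene, top, len(top))
            if gene not in out.adjacency:
                want = 0.0
        assert got == pytest.approx(want), (gene, kind)


# -- matrix assembly -------------------------------------------------------

def make_ten_outputs():
    outs = []
    for i, mid in enumerate(
        ["oncodrivefm", "oncodriveclust", "mutsig", "activedriver", "simon"]
    ):
        outs.append(
            MethodOutput(
                method_id=mid, kind="gene_pvalue",
                pvalues={"GA": 0.01 * (i + 1), "GB": 0.5},
            )
        )
    outs.append(
        MethodOutput(
            method_id="fln", kind="ranked_list",
            network=[("GA", "T1", 0.4), ("GB", "T2", 0.2)],
            top_genes=["T1", "T2"],
        )
    )
    for mid in ["netbox", "memo", "dendrix"]:
        outs.append(
            MethodOutput(
                method_id=mid, kind="module_count",
                modules=[{"GA", "T1"}], network=[("GA", "T1", 1.0), ("GB", "GA", 1.0)],
            )
        )
    outs.append(
        MethodOutput(
            method_id="flnp", kind="module_weighted",
            modules=[{"GA", "T1"}], network=[("GB", "GA", 0.6)],
        )
    )
    return outs


class TestBuildFeatureMatrix:
    def test_gene_in_no_output_gets_all_default_row(self):
        fm = build_feature_matrix(make_ten_outputs(), ["GA", "GB", "GZ"])
        np.testing.assert_allclose(
            fm.row("GZ"), [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        )
        assert fm.imputed_mask[fm.genes.index("GZ")].all()

    def test_cells_match_single_feature_operations(self):
        outs = make_ten_outputs()
        fm = build_feature_matrix(outs, ["GA", "GB", "GZ"])
        for j, out in enumerate(outs):
            for gene in ["GA", "GB"]:
                if out.covers(gene):
                    want = method_feature(out, gene)
                else:
                    want = KIND_DEFAULT[out.kind]
                assert fm.values[fm.genes.index(gene), j] == pytest.approx(want)

    def test_shape_contract(self):
        universe = [f"U{i}" for i in range(17)]
        fm = build_feature_matrix(make_ten_outputs(), universe)
        assert fm.values.shape == (17, 10)

    def test_pvalue_columns_in_unit_interval_module_columns_nonneg(self, small_cohort):
        fm = build_feature_matrix(small_cohort.outputs, small_cohort.universe)
        assert np.isfinite(fm.values).all()
        for j, kind in enumerate(fm.kinds):
            col = fm.values[:, j]
            if kind == "gene_pvalue":
                assert ((col >= 0) & (col <= 1)).all()
            else:
                assert (col >= 0).all()

    def test_permuting_universe_permutes_rows_only(self):
        outs = make_ten_outputs()
        universe = ["GA", "GB", "GZ", "T1"]
        fm1 = build_feature_matrix(outs, universe)
        fm2 = build_feature_matrix(outs, universe[::-1])
        for g in universe:
            np.testing.assert_array_equal(fm1.row(g), fm2.row(g))

    def test_duplicate_method_ids_rejected(self):
        outs = make_ten_outputs()
        outs[1] = MethodOutput(
            method_id="oncodrivefm", kind="gene_pvalue", pvalues={}
        )
        with pytest.raises(ValueError, match="duplicate method"):
            build_feature_matrix(outs, ["GA"])

    def test_duplicate_universe_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate genes"):
            build_feature_matrix(make_ten_outputs(), ["GA", "ga"])

    def test_wrong_output_count_rejected(self):
        with pytest.raises(ValueError, match="10"):
            build_feature_matrix(make_ten_outputs()[:9], ["GA"])

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        fm = build_feature_matrix(make_ten_outputs(), ["GA", "GB"])
        path = tmp_path / "fm.tsv"
        fm.to_tsv(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        assert list(df.columns) == fm.methods
        np.testing.assert_allclose(df.values, fm.values)


def test_binary_candidate_matrix_thresholds():
    fm = FeatureMatrix(
        genes=["A", "B"],
        methods=["m1", "m2"],
        values=np.array([[0.01, 3.0], [0.5, 0.0]]),
        imputed_mask=np.zeros((2, 2), dtype=bool),
        kinds=["gene_pvalue", "module_count"],
    )
    calls = fm.binary_candidate_matrix(pvalue_threshold=0.05)
    np.testing.assert_array_equal(calls, [[1, 1], [0, 0]])
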
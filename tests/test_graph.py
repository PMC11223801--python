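"""Knowledge-graph data model, reader, filtering, splitting and folds."""

import numpy as np
import pandas as pd
import pytest

import hgtlink as hl
from hgtlink.graph import (ConfigurationError, EmptyGraphError, FormatError,
                           MissingNodeError, SchemaError)


def toy_csv(tmp_path, rows, name="edges.csv"):
    cols = ["relation", "x_type", "x_id", "y_type", "y_id"]
    path = tmp_path / name
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


@pytest.fixture()
def toy_graph():
    """drugs {d1,d2,d3}, diseases {s1,s2}, proteins {p1}; one indication."""
    nodes = {"drug": ["d1", "d2", "d3"], "disease": ["s1", "s2"], "protein": ["p1"]}
    edges = {
        ("drug", "indication", "disease"): np.array([[0, 0]]),
        ("drug", "drug_protein", "protein"): np.array([[1, 0]]),
    }
    return hl.HeteroGraph(nodes, edges)


class TestLoadEdgeTable:
    def test_counts_match_rows(self, tmp_path):
        path = toy_csv(tmp_path, [
            ("indication", "drug", "d1", "disease", "s1"),
            ("indication", "drug", "d2", "disease", "s1"),
            ("indication", "drug", "d2", "disease", "s2"),
            ("targets", "drug", "d1", "protein", "p1"),
            ("targets", "drug", "d2", "protein", "p2"),
            ("targets", "drug", "d3", "protein", "p1"),
        ])
        g = hl.load_edge_table(path)
        assert g.relation_names == {"indication", "targets"}
        assert g.num_edges("indication") == 3
        assert g.num_edges("targets") == 3
        assert g.nodes["drug"] == ["d1", "d2", "d3"]
        assert set(g.nodes["protein"]) == {"p1", "p2"}

    def test_duplicate_rows_collapse(self, tmp_path):
        path = toy_csv(tmp_path, [("indication", "drug", "d1", "disease", "s1")] * 3)
        assert hl.load_edge_table(path).num_edges() == 1

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"relation": ["r"], "x_type": ["a"], "x_id": ["1"],
                      "y_type": ["b"]}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="y_id"):
            hl.load_edge_table(path)

    def test_undeclared_type_is_schema_error(self, tmp_path):
        path = toy_csv(tmp_path, [("r", "gene", "g1", "disease", "s1")])
        with pytest.raises(SchemaError, match="gene"):
            hl.load_edge_table(path, node_types={"drug", "disease"})

    def test_empty_file_error(self, tmp_path):
        path = toy_csv(tmp_path, [])
        with pytest.raises(EmptyGraphError):
            hl.load_edge_table(path)

    def test_round_trip_preserves_edge_multisets(self, tmp_path):
        g, _ = hl.primekg_miniature(rng_seed=5)
        out = tmp_path / "mini.csv"
        hl.write_edge_table(g, out)
        g2 = hl.load_edge_table(out)
        assert g2.relation_names == g.relation_names
        for triple in g.triples:
            assert sorted(g2.edge_ids(triple)) == sorted(g.edge_ids(triple))


class TestFilterUnindicated:
    def test_toy_enumeration(self, toy_graph):
        fg = hl.filter_unindicated(toy_graph, "indication")
        assert fg.nodes["drug"] == ["d1"]
        assert fg.nodes["disease"] == ["s1"]
        assert fg.nodes["protein"] == ["p1"]  # other types untouched
        assert fg.num_edges("drug_protein") == 0  # incident edge dropped with d2

    def test_idempotent_and_monotone(self, toy_graph):
        once = hl.filter_unindicated(toy_graph, "indication")
        twice = hl.filter_unindicated(once, "indication")
        assert twice.nodes == once.nodes
        assert {t: len(a) for t, a in twice.edges.items()} == \
               {t: len(a) for t, a in once.edges.items()}
        assert once.num_nodes() <= toy_graph.num_nodes()
        assert once.num_edges() <= toy_graph.num_edges()

    def test_no_indications_removes_all_endpoints(self, toy_graph):
        g = toy_graph.without_pairs("indication", [("d1", "s1")])
        fg = hl.filter_unindicated(g, "indication")
        assert fg.num_nodes("drug") == 0 and fg.num_nodes("disease") == 0

    def test_absent_relation_is_config_error(self, toy_graph):
        with pytest.raises(ConfigurationError):
            hl.filter_unindicated(toy_graph, "no_such_relation")

    def test_miniature_keeps_exactly_indicated_nodes(self):
        g, meta = hl.primekg_miniature(rng_seed=11)
        fg = hl.filter_unindicated(g, "indication")
        assert sorted(fg.nodes["drug"]) == meta["indicated_drug_ids"]
        assert sorted(fg.nodes["disease"]) == meta["indicated_disease_ids"]
        for t in g.nodes:
            if t not in ("drug", "disease"):
                assert fg.nodes[t] == g.nodes[t]


class TestSplitIndications:
    def make_graph(self, n=10):
        nodes = {"drug": [f"d{i}" for i in range(n)], "disease": ["s0"]}
        edges = {("drug", "indication", "disease"):
                 np.column_stack([np.arange(n), np.zeros(n, dtype=int)])}
        return hl.HeteroGraph(nodes, edges)

    def test_eighty_percent_masking(self):
        g = self.make_graph(10)
        split = hl.split_indications(g, "indication", 0.8, rng_seed=4)
        assert len(split.masked) == 8 and len(split.unmasked) == 2
        assert split.masked.isdisjoint(split.unmasked)
        assert split.masked | split.unmasked == g.relation_pairs("indication")

    @pytest.mark.parametrize("frac,n_masked", [(0.0, 0), (1.0, 10), (0.25, 3)])
    def test_mask_sizes_round_half_away(self, frac, n_masked):
        g = self.make_graph(10)
        split = hl.split_indications(g, "indication", frac, rng_seed=1)
        assert len(split.masked) == n_masked

    def test_graph_view_hides_masked(self):
        g = self.make_graph(10)
        split = hl.split_indications(g, "indication", 1.0, rng_seed=0)
        assert split.apply(g).num_edges("indication") == 0
        split0 = hl.split_indications(g, "indication", 0.0, rng_seed=0)
        assert split0.apply(g).num_edges("indication") == 10

    def test_seed_reproducible(self):
        g = self.make_graph(20)
        a = hl.split_indications(g, "indication", 0.5, rng_seed=42)
        b = hl.split_indications(g, "indication", 0.5, rng_seed=42)
        assert a.masked == b.masked and a.unmasked == b.unmasked

    def test_masked_plus_unmasked_always_total(self):
        g = self.make_graph(13)
        for frac in np.linspace(0, 1, 7):
            s = hl.split_indications(g, "indication", float(frac), rng_seed=2)
            assert len(s.masked) + len(s.unmasked) == 13


class TestMakeFolds:
    def test_large_fold_sizes(self):
        pairs = [(f"d{i}", f"s{i}") for i in range(18776)]
        plan = hl.make_folds(pairs, 5, rng_seed=0)
        assert sorted(plan.sizes(), reverse=True) == [3756, 3755, 3755, 3755, 3755]

    def test_exact_division(self):
        plan = hl.make_folds([(i, i) for i in range(10)], 5, rng_seed=1)
        assert plan.sizes() == [2, 2, 2, 2, 2]

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            hl.make_folds([(1, 2), (3, 4)], 1, rng_seed=0)

    def test_every_pair_in_exactly_one_fold(self):
        pairs = [(i, -i) for i in range(17)]
        plan = hl.make_folds(pairs, 4, rng_seed=3)
        seen = [p for i in range(4) for p in plan.fold(i)]
        assert sorted(seen) == sorted(pairs)
        assert max(plan.sizes()) - min(plan.sizes()) <= 1


class TestInduceSubgraph:
    def test_identity(self, toy_graph):
        g2 = hl.induce_subgraph(toy_graph, {t: ids for t, ids in toy_graph.nodes.items()})
        assert g2.nodes == toy_graph.nodes
        for t in toy_graph.triples:
            assert np.array_equal(g2.edges[t], toy_graph.edges[t])

    def test_single_node_no_edges(self, toy_graph):
        g2 = hl.induce_subgraph(toy_graph, {"drug": ["d1"]})
        assert g2.num_nodes() == 1 and g2.num_edges() == 0

    def test_brute_force_edge_membership(self, rng):
        res = hl.generate(hl.SynthSpec(n_drugs=5, n_diseases=4, n_proteins=6,
                                       n_blocks=2, rng_seed=9))
        g = res.graph
        sel = {"drug": ["d0", "d2"], "disease": ["s1", "s3"], "protein": ["p0", "p5", "p2"]}
        sub = hl.induce_subgraph(g, sel)
        kept = {t: set(ids) for t, ids in sel.items()}
        for triple in g.triples:
            expected = sorted((a, b) for a, b in g.edge_ids(triple)
                              if a in kept[triple[0]] and b in kept[triple[2]])
            assert sorted(sub.edge_ids(triple)) == expected

    def test_unknown_id_raises(self, toy_graph):
        with pytest.raises(MissingNodeError):
            hl.induce_subgraph(toy_graph, {"drug": ["nope"]})


class TestRemoveRelation:
    def test_counts(self, toy_graph):
        g2 = hl.remove_relation(toy_graph, "drug_protein")
        assert g2.num_edges("drug_protein") == 0
        assert g2.num_edges("indication") == toy_graph.num_edges("indication")
        assert g2.nodes == toy_graph.nodes

    def test_unknown_relation(self, toy_graph):
        with pytest.raises(ConfigurationError):
            hl.remove_relation(toy_graph, "nope")

    def test_empty_relation_leaves_graph_unchanged(self):
        nodes = {"a": ["x"], "b": ["y"]}
        edges = {("a", "r1", "b"): np.array([[0, 0]]),
                 ("a", "r2", "b"): np.zeros((0, 2), dtype=np.intp)}
        g = hl.HeteroGraph(nodes, edges)
        g2 = hl.remove_relation(g, "r2")
        assert g2.num_edges() == 1


class TestReverseRelations:
    def test_bipartite_gets_reverse(self, toy_graph):
        gv = toy_graph.with_reverse_relations()
        assert ("disease", "rev__indication", "drug") in gv.edges
        assert gv.edge_ids(("disease", "rev__indication", "drug")) == [("s1", "d1")]

    def test_symmetric_same_type_not_duplicated(self):
        nodes = {"protein": ["p0", "p1"]}
        edges = {("protein", "ppi", "protein"): np.array([[0, 1], [1, 0]])}
        gv = hl.HeteroGraph(nodes, edges).with_reverse_relations()
        # same-type relations still get a reverse label; both-orientation
        # storage means it mirrors the forward set
        assert sorted(gv.edge_ids(("protein", "rev__ppi", "protein"))) == \
            sorted(gv.edge_ids(("protein", "ppi", "protein")))

    def test_write_skips_reverse_edges(self, tmp_path, toy_graph):
        gv = toy_graph.with_reverse_relations()
        out = tmp_path / "edges.csv"
        hl.write_edge_table(gv, out)
        g2 = hl.load_edge_table(out)
        assert g2.relation_names == {"indication", "drug_protein"}
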
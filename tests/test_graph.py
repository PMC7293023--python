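import numpy as np
import pytest

from bioentity2vec.graph import (
    Edge,
    GraphError,
    HeteroGraph,
    Node,
    RelationType,
    attach_negatives,
    fold_sizes,
    kfold_split,
    read_edge_list,
    read_node_types,
    sample_negatives,
    strip_test_edges,
    write_edge_list,
    write_node_types,
)


def tiny_graph():
    nodes = [
        Node("m1", "miRNA"), Node("m2", "miRNA"),
        Node("d1", "disease"), Node("d2", "disease"),
        Node("dr1", "drug"), Node("p1", "protein"),
    ]
    rels = [
        RelationType("miRNA-disease", ("miRNA", "disease")),
        RelationType("drug-protein", ("drug", "protein")),
    ]
    edges = [
        Edge("m1", "d1", "miRNA-disease"),
        Edge("m2", "d2", "miRNA-disease"),
        Edge("dr1", "p1", "drug-protein"),
    ]
    return HeteroGraph(nodes, rels, edges)


class TestConstruction:
    def test_unknown_node_type_rejected(self):
        with pytest.raises(GraphError, match="unknown node type"):
            Node("x", "gene")

    def test_endpoint_type_mismatch_rejected(self):
        g = tiny_graph()
        with pytest.raises(GraphError, match="do not match"):
            g.add_edge(Edge("m1", "m2", "drug-protein"))

    def test_duplicate_edges_collapse_and_orientation_is_canonical(self):
        g = tiny_graph()
        n = len(g.edges)
        g.add_edge(Edge("d1", "m1", "miRNA-disease"))  # same undirected edge
        assert len(g.edges) == n
        assert g.has_edge("m1", "d1") and g.has_edge("d1", "m1")

    def test_self_loop_rejected(self):
        with pytest.raises(GraphError, match="self-loop"):
            Edge("p1", "p1", "ppi")

    def test_same_type_endpoints_allowed_for_ppi(self):
        nodes = [Node("p1", "protein"), Node("p2", "protein")]
        rel = RelationType("ppi", ("protein", "protein"))
        g = HeteroGraph(nodes, [rel], [Edge("p1", "p2", "ppi")])
        assert g.degree("p1") == 1

    def test_dangling_edge_rejected(self):
        g = tiny_graph()
        with pytest.raises(GraphError, match="unknown node"):
            g.add_edge(Edge("m1", "zzz", "miRNA-disease"))

    def test_adjacency_matrix_symmetric(self, small_bundle):
        a = small_bundle.graph.adjacency_matrix()
        assert np.array_equal(a, a.T)
        # lower-triangular storage reproduces the full symmetric matrix
        tril = np.tril(a)
        assert np.array_equal(tril + tril.T, a)


class TestIO:
    def test_round_trip_identity(self, tmp_path, small_bundle):
        g = small_bundle.graph
        write_edge_list(g, tmp_path / "e.tsv")
        write_node_types(g, tmp_path / "t.tsv")
        types = read_node_types(tmp_path / "t.tsv")
        g2 = read_edge_list(tmp_path / "e.tsv", types)
        assert g2 == g

    def test_duplicate_rows_collapse(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "source\ttarget\trelation\n"
            "m1\td1\tmiRNA-disease\n"
            "d1\tm1\tmiRNA-disease\n"
            "m2\td2\tmiRNA-disease\n"
            "dr1\tp1\tdrug-protein\n"
        )
        types = {"m1": "miRNA", "m2": "miRNA", "d1": "disease",
                 "d2": "disease", "dr1": "drug", "p1": "protein"}
        g = read_edge_list(tmp_path / "e.tsv", types)
        assert len(g.edges) == 3 and len(g.nodes) == 6

    def test_error_names_offending_row(self, tmp_path):
        (tmp_path / "e.tsv").write_text(
            "source\ttarget\trelation\nd1\td2\tdrug-protein\n"
        )
        with pytest.raises(GraphError, match="e.tsv:2"):
            read_edge_list(
                tmp_path / "e.tsv",
                {"d1": "drug", "d2": "drug"},
                [RelationType("drug-protein", ("drug", "protein"))],
            )

    def test_empty_graph_writes_header_only(self, tmp_path):
        g = HeteroGraph([], [])
        write_edge_list(g, tmp_path / "e.tsv")
        assert (tmp_path / "e.tsv").read_text() == "source\ttarget\trelation\n"


class TestKFold:
    def test_partition_covers_all_edges_disjointly(self, small_bundle):
        g = small_bundle.graph
        folds = kfold_split(g, 5, seed=3)
        seen = []
        for f in folds:
            assert set(f.train_edges) | set(f.test_edges) == g.edges
            assert not set(f.train_edges) & set(f.test_edges)
            seen.extend(f.test_edges)
        assert len(seen) == len(g.edges) and set(seen) == g.edges
        sizes = [len(f.test_edges) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_under_seed(self, small_bundle):
        g = small_bundle.graph
        a = kfold_split(g, 5, seed=11)
        b = kfold_split(g, 5, seed=11)
        assert all(x.test_edges == y.test_edges for x, y in zip(a, b))

    def test_ten_edges_five_folds_of_two(self):
        nodes = [Node(f"m{i}", "miRNA") for i in range(10)] + [Node("d", "disease")]
        rel = RelationType("md", ("miRNA", "disease"))
        g = HeteroGraph(nodes, [rel], [Edge(f"m{i}", "d", "md") for i in range(10)])
        folds = kfold_split(g, 5, seed=0)
        assert [len(f.test_edges) for f in folds] == [2] * 5

    def test_whole_network_fold_arithmetic(self):
        # 114,150 positives split five ways -> five folds of 22,830
        assert fold_sizes(114150, 5) == [22830] * 5

    def test_k_larger_than_edges_errors(self):
        nodes = [Node("m", "miRNA"), Node("d", "disease")]
        rel = RelationType("md", ("miRNA", "disease"))
        g = HeteroGraph(nodes, [rel], [Edge("m", "d", "md")])
        with pytest.raises(GraphError):
            kfold_split(g, 2, seed=0)


class TestStrip:
    def test_strip_empty_is_identity(self, small_bundle):
        g = small_bundle.graph
        assert strip_test_edges(g, []) == g

    def test_strip_all_leaves_node_only_graph(self, small_bundle):
        g = small_bundle.graph
        s = strip_test_edges(g, g.edges)
        assert len(s.edges) == 0 and set(s.nodes) == set(g.nodes)

    def test_strip_20_percent_keeps_counts_and_nodes(self, small_bundle):
        g = small_bundle.graph
        edges = sorted(g.edges, key=lambda e: (e.relation, e.u, e.v))
        n_strip = len(edges) // 5
        s = strip_test_edges(g, edges[:n_strip])
        assert len(s.edges) == len(edges) - n_strip
        assert set(s.nodes) == set(g.nodes)
        assert len(g.edges) == len(edges)  # original untouched

    def test_strip_unknown_edge_errors(self, small_bundle):
        g = small_bundle.graph
        with pytest.raises(GraphError, match="not in graph"):
            strip_test_edges(g, [Edge("protein_000", "disease_000", "miRNA-disease")])


class TestNegatives:
    def test_pigeonhole_single_positive(self):
        nodes = [Node("a1", "drug"), Node("a2", "drug"),
                 Node("b1", "protein"), Node("b2", "protein")]
        rel = RelationType("dp", ("drug", "protein"))
        g = HeteroGraph(nodes, [rel], [Edge("a1", "b1", "dp")])
        negs = sample_negatives(g, list(g.edges), seed=0)
        assert len(negs) == 1
        assert negs[0].pair not in g.positive_pairs()

    def test_exhausted_candidate_space_errors(self):
        nodes = [Node("a1", "drug"), Node("b1", "protein"), Node("b2", "protein")]
        rel = RelationType("dp", ("drug", "protein"))
        g = HeteroGraph(nodes, [rel],
                        [Edge("a1", "b1", "dp"), Edge("a1", "b2", "dp")])
        with pytest.raises(GraphError, match="dp"):
            sample_negatives(g, list(g.edges), seed=0)

    def test_negative_purity_and_type_matching(self, default_bundle):
        g = default_bundle.graph
        edges = sorted(g.edges, key=lambda e: (e.relation, e.u, e.v))[:1000]
        negs = sample_negatives(g, edges, seed=5)
        assert len(negs) == 1000
        pos = g.positive_pairs()
        assert not {n.pair for n in negs} & pos  # brute-force intersection
        # per-relation counts match and endpoint types are honored
        from collections import Counter
        assert Counter(e.relation for e in negs) == Counter(e.relation for e in edges)
        for n in negs:
            ts = tuple(sorted((g.node_type(n.u), g.node_type(n.v))))
            assert ts == g.relations[n.relation].endpoint_types

    def test_reproducible_and_disjoint_partitions(self, small_bundle):
        g = small_bundle.graph
        f1 = attach_negatives(g, kfold_split(g, 5, seed=1)[0], seed=9)
        f2 = attach_negatives(g, kfold_split(g, 5, seed=1)[0], seed=9)
        assert f1.negatives_train == f2.negatives_train
        assert f1.negatives_test == f2.negatives_test
        assert not {e.pair for e in f1.negatives_train} & {e.pair for e in f1.negatives_test}
        assert len(f1.negatives_train) == len(f1.train_edges)
        assert len(f1.negatives_test) == len(f1.test_edges)
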
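"""Graph/attribute I/O, edge splits, and topology summary statistics."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linknmf import (
    AttributeTable,
    Graph,
    load_attribute_table,
    load_edge_list,
    split_edges,
    summary_stats,
    write_attribute_table,
)
from .conftest import random_graph


def _write(tmp_path, lines, name="edges.txt"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestLoadEdgeList:
    def test_labels_mapped_in_first_appearance_order(self, tmp_path):
        g = load_edge_list(_write(tmp_path, ["a b", "b c"]))
        assert g.n_nodes == 3
        assert g.edges == {(0, 1), (1, 2)}
        assert g.node_labels == ("a", "b", "c")

    def test_dedup_and_self_loop_drop(self, tmp_path):
        g = load_edge_list(_write(tmp_path, ["a b", "b a", "a a"]))
        assert g.n_nodes == 2
        assert g.edges == {(0, 1)}

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        g = load_edge_list(_write(tmp_path, ["# header", "", "x y  # inline"]))
        assert g.edges == {(0, 1)}

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(ValueError, match="line 2"):
            load_edge_list(_write(tmp_path, ["a b", "a b c"]))

    def test_empty_edge_set_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no edges"):
            load_edge_list(_write(tmp_path, ["# nothing here"]))

    def test_random_list_matches_line_by_line_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        lines = []
        n = 10
        for _ in range(40):
            i, j = rng.integers(0, n, 2)
            lines.append(f"n{i} n{j}")
        g = load_edge_list(_write(tmp_path, lines))
        # independent oracle: accumulate adjacency label by label
        labels = {}
        A = np.zeros((n, n))
        for line in lines:
            u, v = line.split()
            iu = labels.setdefault(u, len(labels))
            iv = labels.setdefault(v, len(labels))
            if iu != iv:
                A[iu, iv] = A[iv, iu] = 1
        assert np.array_equal(g.adjacency(), A[: g.n_nodes, : g.n_nodes])

    def test_loaded_adjacency_symmetric_zero_diagonal(self, tmp_path):
        g = load_edge_list(_write(tmp_path, ["a b", "b c", "c a", "c d"]))
        A = g.adjacency()
        assert np.array_equal(A, A.T)
        assert not np.diagonal(A).any()


class TestAttributeTable:
    def test_load_basic(self, tmp_path):
        p = tmp_path / "attrs.tsv"
        p.write_text("1\t0\n0\t1\n1\t1\n")
        t = load_attribute_table(p)
        assert (t.n_nodes, t.n_attrs) == (3, 2)
        assert not t.normalized

    def test_negative_value_rejected_with_cell(self, tmp_path):
        p = tmp_path / "attrs.tsv"
        p.write_text("1\t0\n0\t-1\n")
        with pytest.raises(ValueError, match="row 1, column 1"):
            load_attribute_table(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "attrs.tsv"
        p.write_text("1\t0\n0\t1\t1\n")
        with pytest.raises(ValueError, match="ragged"):
            load_attribute_table(p)

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        t = AttributeTable(values=rng.random((5, 4)))
        p = tmp_path / "rt.tsv"
        write_attribute_table(t, p)
        t2 = load_attribute_table(p)
        assert np.array_equal(t.values, t2.values)

    def test_header_row_detected(self, tmp_path):
        p = tmp_path / "attrs.tsv"
        p.write_text("age\tincome\n1\t2\n3\t4\n")
        t = load_attribute_table(p)
        assert t.column_names == ("age", "income")
        assert t.n_nodes == 2


class TestSplitEdges:
    def test_sizes_use_half_up_rounding(self):
        # K13 has exactly C(13,2) = 78 edges
        g = Graph.from_edges(
            [(i, j) for i in range(13) for j in range(i + 1, 13)]
        )
        sp = split_edges(g, 0.9, seed=0)
        assert sp.train_graph.n_edges == 70  # round(0.9 * 78)
        assert len(sp.probe_edges) == 8

    def test_two_edge_half_split(self):
        g = Graph.from_edges([(0, 1), (1, 2)])
        sp = split_edges(g, 0.5, seed=5)
        assert sp.train_graph.n_edges == 1
        assert len(sp.probe_edges) == 1

    def test_deterministic_given_seed(self):
        g = random_graph(20, 0.3, seed=4)
        a = split_edges(g, 0.7, seed=11)
        b = split_edges(g, 0.7, seed=11)
        assert a.probe_edges == b.probe_edges
        assert a.train_graph.edges == b.train_graph.edges

    def test_partition_is_disjoint_and_complete(self):
        g = random_graph(25, 0.25, seed=9)
        sp = split_edges(g, 0.6, seed=2)
        assert not (sp.train_graph.edges & sp.probe_edges)
        assert sp.train_graph.edges | sp.probe_edges == g.edges

    def test_all_nodes_kept(self):
        g = random_graph(15, 0.2, seed=6)
        sp = split_edges(g, 0.5, seed=0)
        assert sp.train_graph.n_nodes == g.n_nodes

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_bad_fraction_rejected(self, frac):
        g = Graph.from_edges([(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            split_edges(g, frac, seed=0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        frac=st.floats(0.01, 0.99),
        seed=st.integers(0, 2**31 - 1),
        gseed=st.integers(0, 50),
    )
    def test_split_is_always_a_partition(self, frac, seed, gseed):
        """Any split partitions the edge set with the half-up train size."""
        g = random_graph(14, 0.3, seed=gseed)
        if g.n_edges < 2:
            return
        sp = split_edges(g, frac, seed=seed)
        assert not (sp.train_graph.edges & sp.probe_edges)
        assert sp.train_graph.edges | sp.probe_edges == g.edges
        assert sp.train_graph.n_edges == math.floor(frac * g.n_edges + 0.5)

    def test_complementary_fractions_sizes(self):
        g = random_graph(20, 0.3, seed=8)
        e = g.n_edges
        for f in (0.3, 0.45, 0.8):
            n_train = split_edges(g, f, seed=1).train_graph.n_edges
            n_other = split_edges(g, 1 - f, seed=1).train_graph.n_edges
            assert abs((n_train + n_other) - e) <= 1


def _bfs_distances(adj_sets, src):
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj_sets[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


class TestSummaryStats:
    def test_triangle(self, triangle):
        s = summary_stats(triangle)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.avg_degree == 2
        assert s.mean_shortest_distance == 1
        assert s.clustering_coefficient == 1

    def test_path3(self, path3):
        s = summary_stats(path3)
        assert s.avg_degree == pytest.approx(4 / 3)
        assert s.mean_shortest_distance == pytest.approx(4 / 3)
        assert s.clustering_coefficient == 0

    def test_degree_identity_holds_exactly(self):
        for seed in range(5):
            g = random_graph(18, 0.2, seed=seed)
            s = summary_stats(g)
            assert s.avg_degree * s.n_nodes == 2 * s.n_edges

    def test_random_graph_matches_brute_force_oracle(self):
        g = random_graph(12, 0.3, seed=42)
        adj_sets = {i: set() for i in range(g.n_nodes)}
        for i, j in g.edges:
            adj_sets[i].add(j)
            adj_sets[j].add(i)
        # mean distance: BFS from every node over reachable ordered pairs
        total = pairs = 0
        for src in range(g.n_nodes):
            d = _bfs_distances(adj_sets, src)
            total += sum(d.values())
            pairs += len(d) - 1
        # clustering: count linked neighbour pairs per node
        cs = []
        for v in range(g.n_nodes):
            nb = sorted(adj_sets[v])
            if len(nb) < 2:
                cs.append(0.0)
                continue
            links = sum(
                1
                for a in range(len(nb))
                for b in range(a + 1, len(nb))
                if nb[b] in adj_sets[nb[a]]
            )
            cs.append(2 * links / (len(nb) * (len(nb) - 1)))
        s = summary_stats(g)
        assert s.mean_shortest_distance == pytest.approx(total / pairs, abs=1e-12)
        assert s.clustering_coefficient == pytest.approx(np.mean(cs), abs=1e-12)

    def test_tsv_serialization_has_expected_columns(self, triangle):
        text = summary_stats(triangle).to_tsv()
        header, row = text.strip().split("\n")
        assert header.split("\t") == ["N", "E", "K", "d", "C"]
        assert row.split("\t")[0] == "3"


class TestGraphInvariants:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            Graph(n_nodes=3, edges=frozenset({(1, 1)}))

    def test_adjacency_from_edges_consistent(self):
        g = random_graph(10, 0.4, seed=0)
        A = g.adjacency()
        assert A.sum() == 2 * g.n_edges
        assert np.array_equal(A, A.T)

    def test_from_adjacency_rejects_asymmetric(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            Graph.from_adjacency(A)
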
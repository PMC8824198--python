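"""PLA interval arithmetic, graph construction and Markov clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgscreen.fixtures import gen_ctn_hits
from scgscreen.mge_network import (AlignmentHit, ClusterGraph, ContigInfo,
                                   build_ctn_graph, markov_cluster,
                                   merged_hit_length, pla)


def hit(q="a", s="b", qstart=1, qend=100, pident=99.0):
    lo, hi = min(qstart, qend), max(qstart, qend)
    return AlignmentHit(q, s, pident, hi - lo + 1, 0, 0, qstart, qend, lo, hi)


def marking_oracle(intervals, length):
    """Position-marking union length over closed 1-based intervals."""
    covered = np.zeros(length + 1, dtype=bool)
    for lo, hi in intervals:
        covered[lo:hi + 1] = True
    return int(covered.sum())


def mcl_oracle(nodes, weighted_edges, inflation=2.0, expansion=2,
               prune_below=1e-5, tol=1e-6, max_iter=200):
    """Straightforward dense-matrix MCL, written independently of the package:
    builds the matrix by dict lookups, expands by repeated multiplication,
    and reads clusters off the limit matrix row supports."""
    order = sorted(nodes)
    n = len(order)
    pos = {v: k for k, v in enumerate(order)}
    mat = np.zeros((n, n))
    for a, b, w in weighted_edges:
        mat[pos[a], pos[b]] = w
        mat[pos[b], pos[a]] = w
    for i in range(n):
        row_max = mat[i].max()
        mat[i, i] = row_max if row_max > 0 else 1.0
    mat = mat / mat.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = mat.copy()
        for _ in range(expansion - 1):
            expanded = expanded @ mat
        inflated = expanded ** inflation
        inflated[inflated < prune_below] = 0.0
        sums = inflated.sum(axis=0, keepdims=True)
        sums[sums == 0] = 1.0
        inflated = inflated / sums
        if np.abs(inflated - mat).max() < tol:
            mat = inflated
            break
        mat = inflated
    eps = 1e-9
    attractor_rows = [i for i in range(n) if mat[i, i] > eps]
    supports = {i: set(np.flatnonzero(mat[i] > eps)) | {i} for i in attractor_rows}
    clusters = []
    for i in attractor_rows:
        placed = False
        for cl in clusters:
            if supports[i] & cl:
                cl.update(supports[i])
                placed = True
                break
        if not placed:
            clusters.append(set(supports[i]))
    # merge any chained overlaps
    changed = True
    while changed:
        changed = False
        for x, y in itertools.combinations(range(len(clusters)), 2):
            if clusters[x] & clusters[y]:
                clusters[x] |= clusters.pop(y)
                changed = True
                break
    claimed = set().union(*clusters) if clusters else set()
    clusters += [{j} for j in range(n) if j not in claimed]
    return {frozenset(order[k] for k in cl) for cl in clusters}


class TestMergedHitLength:
    @pytest.mark.parametrize("intervals,expected", [
        ([(1, 100), (51, 150)], 150),   # overlapping
        ([(1, 100)], 100),
        ([(1, 100), (201, 300)], 200),  # disjoint
        ([(1, 100), (101, 150)], 150),  # adjacent merges, same sum
        ([(10, 20), (12, 15)], 11),     # nested
    ])
    def test_examples(self, intervals, expected):
        hits = [hit(qstart=lo, qend=hi) for lo, hi in intervals]
        assert merged_hit_length(hits) == expected

    def test_reverse_strand_normalized(self):
        assert merged_hit_length([hit(qstart=100, qend=1)]) == 100

    def test_empty(self):
        assert merged_hit_length([]) == 0

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            merged_hit_length([hit(q="a", s="b"), hit(q="a", s="c")])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(1, 500), st.integers(1, 500)),
                    min_size=1, max_size=15))
    def test_matches_marking_oracle(self, raw):
        intervals = [(min(a, b), max(a, b)) for a, b in raw]
        hits = [hit(qstart=lo, qend=hi) for lo, hi in intervals]
        assert merged_hit_length(hits) == marking_oracle(intervals, 500)


class TestPla:
    def test_full_reciprocal_hit(self):
        h_ab, h_ba = [hit("a", "b", 1, 1000)], [hit("b", "a", 1, 1000)]
        assert pla(h_ab, h_ba, 1000, 1000) == pytest.approx(100.0)

    def test_one_sided(self):
        assert pla([hit("a", "b", 1, 150)], [], 1000, 1000) == pytest.approx(15.0)

    def test_max_combination_rule(self):
        h_ab = [hit("a", "b", 1, 300)]   # 30% of a
        h_ba = [hit("b", "a", 1, 100)]   # 10% of b
        assert pla(h_ab, h_ba, 1000, 1000) == pytest.approx(30.0)
        assert pla(h_ab, h_ba, 1000, 1000, combine="min") == pytest.approx(10.0)
        assert pla(h_ab, h_ba, 1000, 1000, combine="mean") == pytest.approx(20.0)

    def test_bounded_zero_to_hundred(self, rng):
        for _ in range(20):
            lo = int(rng.integers(1, 900))
            hi = lo + int(rng.integers(0, 100))
            value = pla([hit("a", "b", lo, hi)], [], 1000, 1000)
            assert 0.0 <= value <= 100.0


class TestBuildGraph:
    CONTIGS = [ContigInfo("a", 1000), ContigInfo("b", 1000), ContigInfo("c", 1000)]

    def test_boundary_inclusive(self):
        hits = [hit("a", "b", 1, 200)]  # exactly 20%
        cg = build_ctn_graph(self.CONTIGS, hits)
        assert cg.graph.has_edge("a", "b")
        assert cg.graph.edges["a", "b"]["pla"] == pytest.approx(20.0)

    def test_below_threshold_excluded(self):
        cg = build_ctn_graph(self.CONTIGS, [hit("a", "b", 1, 199)])
        assert not cg.graph.has_edge("a", "b")

    def test_self_hits_ignored_and_isolates_kept(self):
        cg = build_ctn_graph(self.CONTIGS, [hit("a", "a", 1, 1000)])
        assert set(cg.graph.nodes) == {"a", "b", "c"}
        assert cg.graph.number_of_edges() == 0

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError):
            build_ctn_graph(self.CONTIGS, [hit("a", "zzz", 1, 500)])


class TestMarkovCluster:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for offset in (0, 3):
            names = [f"n{offset + i}" for i in range(3)]
            for a, b in itertools.combinations(names, 2):
                g.add_edge(a, b, pla=50.0)
        result = markov_cluster(ClusterGraph(g))
        assert {frozenset(c) for c in result.clusters} == {
            frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"})}

    def test_single_node_singleton(self):
        g = nx.Graph()
        g.add_node("only")
        result = markov_cluster(ClusterGraph(g))
        assert result.clusters == [frozenset({"only"})]

    def test_clusters_partition_nodes_within_components(self, rng):
        for trial in range(10):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            for a, b in g.edges:
                g.edges[a, b]["pla"] = float(rng.uniform(20, 100))
            result = markov_cluster(ClusterGraph(g))
            nodes = set(g.nodes)
            assert set().union(*result.clusters) == nodes
            assert sum(len(c) for c in result.clusters) == len(nodes)
            comp_of = {}
            for k, comp in enumerate(nx.connected_components(g)):
                for v in comp:
                    comp_of[v] = k
            for cluster in result.clusters:
                assert len({comp_of[v] for v in cluster}) == 1

    def test_matches_independent_dense_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 13))
            nodes = [f"v{i:02d}" for i in range(n)]
            edges = []
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.35:
                    edges.append((a, b, float(rng.uniform(1, 100))))
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for a, b, w in edges:
                g.add_edge(a, b, pla=w)
            ours = {frozenset(c) for c in markov_cluster(ClusterGraph(g)).clusters}
            assert ours == mcl_oracle(nodes, edges)

    def test_recovers_planted_clusters(self):
        contigs, hits = gen_ctn_hits([3, 4], seed=42)
        cg = markov_cluster(build_ctn_graph(contigs, hits))
        expected = {
            frozenset({"ctn_c1_1", "ctn_c1_2", "ctn_c1_3"}),
            frozenset({"ctn_c2_1", "ctn_c2_2", "ctn_c2_3", "ctn_c2_4"}),
        }
        assert {frozenset(c) for c in cg.clusters} == expected

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", pla=-1.0)
        with pytest.raises(ValueError):
            markov_cluster(ClusterGraph(g))

    def test_structural_zero_between_taxa(self):
        """Element families with no cross-hits never share a cluster
        (mirrors CTns from unrelated host genera sharing no similarity)."""
        contigs, hits = gen_ctn_hits([4, 5], between_pla=0.0, seed=7)
        cg = build_ctn_graph(contigs, hits)
        first = {c.contig_id for c in contigs if c.contig_id.startswith("ctn_c1")}
        for a, b in cg.graph.edges:
            assert (a in first) == (b in first)
        clustered = markov_cluster(cg)
        for cluster in clustered.clusters:
            assert len({v.split("_")[1] for v in cluster}) == 1
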
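"""Conjugative-transposon similarity network and Markov clustering.

Contigs predicted to carry conjugative transposons (CTns) are compared
all-against-all by reciprocal nucleotide alignment.  For each ordered
pair, the percent length aligned (PLA) is the fraction of the query
covered by the union of its alignment hits (overlaps merged before
summing).  Pairs with PLA >= 20% become weighted edges, and the graph is
partitioned by Markov clustering (MCL, inflation 2): alternating matrix
expansion and entrywise inflation drive the column-stochastic flow matrix
to attractors that define the clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ContigInfo",
    "AlignmentHit",
    "ClusterGraph",
    "merged_hit_length",
    "pla",
    "pairwise_pla",
    "build_ctn_graph",
    "markov_cluster",
]


@dataclass(frozen=True)
class ContigInfo:
    contig_id: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: nonpositive length")


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular pairwise alignment.

    Coordinates are 1-based inclusive (alignment-tool convention);
    reverse-strand hits may have start > end on either axis and are
    normalized by swapping before interval arithmetic.
    """

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 1
    qend: int = 1
    sstart: int = 1
    send: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0

    def query_interval(self) -> tuple[int, int]:
        """Strand-normalized (low, high) query coordinates, 1-based closed."""
        return (min(self.qstart, self.qend), max(self.qstart, self.qend))

    def subject_interval(self) -> tuple[int, int]:
        return (min(self.sstart, self.send), max(self.sstart, self.send))


@dataclass
class ClusterGraph:
    """Weighted undirected PLA graph plus (optionally) its MCL partition."""

    graph: nx.Graph
    clusters: list[frozenset[str]] | None = None
    converged: bool = True

    def cluster_of(self) -> dict[str, int]:
        """Node -> cluster index (clusters sorted by size desc, then name)."""
        if self.clusters is None:
            raise ValueError("graph has not been clustered")
        ordered = sorted(self.clusters, key=lambda c: (-len(c), sorted(c)[0]))
        return {node: i for i, cluster in enumerate(ordered) for node in cluster}


def merged_hit_length(hits: Sequence[AlignmentHit], contig_len: int | None = None) -> int:
    """Total query-axis length covered by a hit set, overlaps merged.

    Each hit contributes its strand-normalized closed interval; overlapping
    or adjacent intervals are merged before summing, so repeated or nested
    hits are not double counted.
    """
    if not hits:
        return 0
    pairs = {(h.query_id, h.subject_id) for h in hits}
    if len(pairs) > 1:
        raise ValueError(f"hits span multiple query/subject pairs: {sorted(pairs)}")
    intervals = sorted(h.query_interval() for h in hits)
    if contig_len is not None and intervals[-1][1] > contig_len:
        raise ValueError("hit coordinate beyond contig length")
    if intervals[0][0] < 1:
        raise ValueError("hit coordinate below 1")
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi + 1:  # overlapping or adjacent in closed coordinates
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    total += cur_hi - cur_lo + 1
    return total


def pla(hits_ab: Sequence[AlignmentHit], hits_ba: Sequence[AlignmentHit],
        len_a: int, len_b: int, combine: str = "max") -> float:
    """Percent length aligned for a contig pair.

    Directional PLA(a->b) = 100 * merged query coverage of a / len(a), and
    symmetrically for b->a; the pair value combines the two directions by
    ``max`` (default; liberal linking), ``min`` or ``mean``.
    """
    d_ab = 100.0 * merged_hit_length(hits_ab, len_a) / len_a
    d_ba = 100.0 * merged_hit_length(hits_ba, len_b) / len_b
    if combine == "max":
        return max(d_ab, d_ba)
    if combine == "min":
        return min(d_ab, d_ba)
    if combine == "mean":
        return (d_ab + d_ba) / 2.0
    raise ValueError(f"unknown combine rule {combine!r}")


def pairwise_pla(contigs: Sequence[ContigInfo], hits: Sequence[AlignmentHit],
                 combine: str = "max") -> dict[tuple[str, str], float]:
    """PLA for every unordered contig pair with at least one hit (self-hits
    ignored)."""
    lengths = {c.contig_id: c.length for c in contigs}
    by_pair: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id not in lengths or h.subject_id not in lengths:
            raise ValueError(f"hit references unknown contig "
                             f"{h.query_id!r} or {h.subject_id!r}")
        if h.query_id == h.subject_id:
            continue
        by_pair.setdefault((h.query_id, h.subject_id), []).append(h)
    out: dict[tuple[str, str], float] = {}
    seen = set()
    for a, b in by_pair:
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        out[key] = pla(by_pair.get((key[0], key[1]), []),
                       by_pair.get((key[1], key[0]), []),
                       lengths[key[0]], lengths[key[1]], combine=combine)
    return out


def build_ctn_graph(contigs: Sequence[ContigInfo], hits: Sequence[AlignmentHit],
                    pla_min: float = 20.0, combine: str = "max") -> ClusterGraph:
    """PLA-weighted similarity graph over all contigs.

    Every contig is a node even when isolated; an edge (a, b) with weight
    PLA is included iff PLA >= pla_min (boundary inclusive).
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(c.contig_id for c in contigs))
    for (a, b), value in pairwise_pla(contigs, hits, combine=combine).items():
        if value >= pla_min:
            g.add_edge(a, b, pla=value)
    return ClusterGraph(graph=g)


def _mcl_matrix(m: np.ndarray, inflation: float, expansion: int,
                prune_below: float, tol: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Iterate expansion/inflation/pruning on a column-stochastic matrix."""
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, expansion)
        new = np.power(new, inflation)
        new[new < prune_below] = 0.0
        colsums = new.sum(axis=0)
        colsums[colsums == 0] = 1.0
        new /= colsums
        if np.max(np.abs(new - m)) < tol:
            return new, True
        m = new
    return m, False


def markov_cluster(cg: ClusterGraph, inflation: float = 2.0, expansion: int = 2,
                   prune_below: float = 1e-5, tol: float = 1e-6,
                   max_iter: int = 200) -> ClusterGraph:
    """Markov clustering of the PLA graph.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1 for isolated nodes), columns are normalized to a
    stochastic flow matrix, and expansion (matrix power) alternates with
    inflation (entrywise power + renormalization) and pruning of entries
    below ``prune_below`` until the matrix change (max-norm) falls below
    ``tol``.  Clusters are read off the attractor structure of the limit
    matrix; nodes are ordered lexicographically so the result is
    deterministic.  Non-convergence within ``max_iter`` is reported via
    ``converged=False`` on the (still usable) partial result.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    g = cg.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return ClusterGraph(graph=g, clusters=[], converged=True)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n), dtype=float)
    for a, b, data in g.edges(data=True):
        w = float(data.get("pla", data.get("weight", 1.0)))
        if w < 0:
            raise ValueError(f"negative edge weight on ({a}, {b})")
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    for i in range(n):
        incident = m[i, :]
        m[i, i] = incident.max() if incident.max() > 0 else 1.0
    m /= m.sum(axis=0)

    limit, converged = _mcl_matrix(m, inflation, expansion, prune_below, tol, max_iter)
    if not converged:
        msg = f"MCL did not converge within {max_iter} iterations"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    clusters = _attractor_clusters(limit, nodes)
    return ClusterGraph(graph=g, clusters=clusters, converged=converged)


def _attractor_clusters(limit: np.ndarray, nodes: list[str],
                        eps: float = 1e-9) -> list[frozenset[str]]:
    """Interpret the MCL limit matrix: attractors are rows with positive
    diagonal mass; each attractor claims the columns flowing into it, and
    attractors sharing a claimed node merge into one cluster."""
    n = len(nodes)
    attractors = [i for i in range(n) if limit[i, i] > eps]
    if not attractors:  # degenerate (non-converged) fallback: strongest row per column
        attractors = sorted(set(int(np.argmax(limit[:, j])) for j in range(n)))
    members = {i: set(np.nonzero(limit[i, :] > eps)[0]) | {i} for i in attractors}
    # union-find over attractors with overlapping support
    parent = {i: i for i in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in attractors:
        for j in attractors:
            if i < j and members[i] & members[j]:
                parent[find(j)] = find(i)

    merged: dict[int, set[int]] = {}
    for i in attractors:
        merged.setdefault(find(i), set()).update(members[i])
    clusters = [frozenset(nodes[k] for k in group) for group in merged.values()]
    claimed = set().union(*merged.values()) if merged else set()
    for j in range(n):  # orphan columns (fully pruned) become singletons
        if j not in claimed:
            clusters.append(frozenset({nodes[j]}))
    return sorted(clusters, key=lambda c: sorted(c)[0])
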
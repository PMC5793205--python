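"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by enumeration or naive recursion so
that the package's dynamic programmes and agglomerations are checked against
a second, structurally different route.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def brute_glocal_score(S, gap_open, gap_extend):
    """Best glocal score by explicit recursion over alignment operations.

    The whole profile (rows of score matrix ``S``) must be consumed; target
    residues (columns) outside the aligned block are free.  Gap runs cost
    ``open + (len-1)*extend``; a deletion run adjacent to an insertion run is
    a separate run.  Insertions are only allowed between consumed columns.
    """
    S = [list(row) for row in S]
    C, L = len(S), len(S[0])
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(c, t, last):
        if c == C:
            return 0.0
        best = NEG
        if t < L:  # match column c to residue t
            best = max(best, S[c][t] + rec(c + 1, t + 1, "M"))
        cost = gap_extend if last == "D" else gap_open
        best = max(best, -cost + rec(c + 1, t, "D"))
        if t < L and 0 < c < C:  # insert residue t between columns c-1 and c
            cost = gap_extend if last == "I" else gap_open
            best = max(best, -cost + rec(c, t + 1, "I"))
        return best

    result = max(rec(0, s, None) for s in range(L + 1))
    rec.cache_clear()
    return result


def brute_global_align_score(a, b, score, gap_open, gap_extend):
    """Optimal global-alignment score by recursion with explicit run costs.

    A gap of length L costs ``gap_open + L*gap_extend`` (matches the package's
    aligner convention).
    """

    @lru_cache(maxsize=None)
    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, score(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if last == "A" else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = gap_extend if last == "B" else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, "B"))
        return best

    result = rec(0, 0, None)
    rec.cache_clear()
    return result


def all_unrooted_topologies(labels):
    """Every unrooted binary topology over the labels, as edge lists.

    Built by sequential leaf insertion; sizes up to 6 leaves (105 trees) stay
    cheap.  Nodes are label strings for leaves and integers for internal
    nodes.
    """
    labels = list(labels)
    assert len(labels) >= 3
    base = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    trees = [(base, 1)]
    for leaf in labels[3:]:
        nxt = []
        for edges, n_internal in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                mid = n_internal
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges += [(u, mid), (v, mid), (leaf, mid)]
                nxt.append((new_edges, n_internal + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def topology_bipartitions(edges, labels):
    """Non-trivial bipartitions of an edge-list topology (normalized sides)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    label_set = frozenset(labels)
    anchor = min(labels)
    out = set()
    for u, v in edges:
        side = set()
        stack, seen = [v], {u, v}
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        side = frozenset(side)
        if 1 < len(side) < len(labels) - 1:
            out.add(side if anchor not in side else label_set - side)
    return out


def least_squares_fit(edges, labels, dmat):
    """Least-squares branch lengths for a fixed topology; returns (sse, fit).

    Solves ``A x = d`` where each row of A marks the edges on one leaf-pair
    path (ordinary least squares, lengths unconstrained).
    """
    edge_index = {frozenset(e): k for k, e in enumerate(edges)}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(a, b):
        stack = [(a, [a])]
        seen = {a}
        while stack:
            node, path = stack.pop()
            if node == b:
                return [
                    edge_index[frozenset((path[k], path[k + 1]))]
                    for k in range(len(path) - 1)
                ]
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, path + [nbr]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dmat[i, j] for i, j in pairs])
    for row, (i, j) in enumerate(pairs):
        for e in path_edges(labels[i], labels[j]):
            A[row, e] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(((A @ x - y) ** 2).sum())
    return sse, x


def naive_average_linkage(dist):
    """Naive O(n^3) UPGMA-style agglomeration; returns sorted merge heights.

    Average linkage between clusters A, B = mean pairwise distance, updated
    from scratch each merge.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if h < best[0]:
                    best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)
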
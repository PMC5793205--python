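"""Distance-based phylogeny: Poisson-corrected distances with pairwise
deletion, Saitou–Nei Neighbor-joining, bootstrap supports, and
reference-guided subfamily assignment.

Trees are :class:`skbio.TreeNode` objects; internal nodes carry a ``support``
attribute (percentage of bootstrap replicates containing the bipartition)
which is serialized as the internal node label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import SequenceRecord

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    """Poisson-corrected distances d = -ln(1-p) under pairwise deletion."""

    labels: list[str]
    p: np.ndarray   # observed proportion of differing sites per pair
    d: np.ndarray   # Poisson-corrected distance, substitutions/site

    def __post_init__(self):
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")


@dataclass
class DistanceTree:
    tree: TreeNode
    n_bootstrap: int = 0
    n_successful: int = 0

    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]


def _encode(seqs: list[SequenceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Alignment as (n, L) byte matrix plus a non-gap mask."""
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    arr = np.array([np.frombuffer(s.residues.encode(), dtype=np.uint8) for s in seqs])
    nongap = ~np.isin(arr, np.frombuffer(b"-.", dtype=np.uint8))
    return arr, nongap


def _pairwise_p(arr: np.ndarray, nongap: np.ndarray, labels: list[str]) -> np.ndarray:
    n = arr.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        both = nongap[i] & nongap[i + 1 :]
        comparable = both.sum(axis=1)
        diff = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if comparable[k] == 0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) shares no ungapped column"
                )
            pij = diff[k] / comparable[k]
            if pij >= 1.0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) differs at every site; "
                    "Poisson distance undefined"
                )
            p[i, j] = p[j, i] = pij
    return p


def poisson_distance_matrix(aligned_seqs: list[SequenceRecord]) -> DistanceMatrix:
    """Distance matrix under the Poisson correction with pairwise deletion.

    For each pair, columns gapped in either sequence are dropped; ``p`` is the
    fraction of remaining columns that differ and ``d = -ln(1-p)``.
    """
    labels = [s.id for s in aligned_seqs]
    arr, nongap = _encode(aligned_seqs)
    p = _pairwise_p(arr, nongap, labels)
    d = -np.log(1.0 - p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, p, d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        if length < -1e-9:
            warnings.warn(f"negative branch length {length:.3g} at {context} clamped to 0",
                          stacklevel=3)
        return 0.0
    return length


def nj_tree(matrix: DistanceMatrix) -> DistanceTree:
    """Saitou–Nei Neighbor-joining.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; among co-minimal
    pairs the one whose (lexicographically smallest member-leaf labels) sorts
    first is joined, making the tree order-independent.  Tiny negative branch
    lengths are clamped to zero with a warning.  The result is unrooted,
    represented with a trifurcating root.
    """
    n0 = len(matrix.labels)
    if n0 < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    d = matrix.d.astype(float).copy()
    nodes = [TreeNode(name=lbl) for lbl in matrix.labels]
    # tie-break key: smallest leaf label inside each active node's subtree
    keys = list(matrix.labels)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            tuple(sorted((i, j), key=lambda x: keys[x]))
            for i, j in zip(*np.where(q <= qmin + 1e-12))
            if i < j or True
        ]
        candidates = sorted(
            {(i, j) if keys[i] <= keys[j] else (j, i) for i, j in candidates},
            key=lambda ij: (keys[ij[0]], keys[ij[1]]),
        )
        i, j = candidates[0]
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li, f"join({keys[i]},{keys[j]})")
        child_j.length = _clamp(lj, f"join({keys[i]},{keys[j]})")
        new = TreeNode(children=[child_i, child_j])

        dk = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d_new = np.empty((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # final 3-way join: central (root) node of the unrooted tree
    (d01, d02, d12) = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length, key in zip(nodes, lengths, keys):
        node.length = _clamp(length, f"root edge {key}")
    root = TreeNode(children=list(nodes))
    return DistanceTree(root)


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each normalized to the side that
    excludes the lexicographically smallest leaf."""
    all_leaves = frozenset(t.name for t in tree.tips())
    anchor = min(all_leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        out.add(side)
    return out


def bootstrap_supports(
    aligned_seqs: list[SequenceRecord],
    n_replicates: int = 1000,
    seed: int = 0,
) -> DistanceTree:
    """NJ tree of the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement, rebuilds the
    distance matrix and NJ tree; an edge's support is the percentage of
    successful replicates containing the same leaf bipartition.  Replicates
    with undefined distances (all-different or all-gap pairs) are skipped and
    excluded from the denominator.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    order = sorted(range(len(aligned_seqs)), key=lambda k: aligned_seqs[k].id)
    aligned_seqs = [aligned_seqs[k] for k in order]   # input-order invariance
    labels = [s.id for s in aligned_seqs]
    arr, nongap = _encode(aligned_seqs)
    L = arr.shape[1]

    main = nj_tree(poisson_distance_matrix(aligned_seqs))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(main.tree)}

    rng = np.random.default_rng(seed)
    successful = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        try:
            p = _pairwise_p(arr[:, cols], nongap[:, cols], labels)
        except ValueError:
            continue
        d = -np.log(1.0 - p)
        np.fill_diagonal(d, 0.0)
        with warnings.catch_warnings():
            # replicate trees only contribute bipartitions; their clamped
            # branch lengths are irrelevant
            warnings.simplefilter("ignore")
            rep = nj_tree(DistanceMatrix(labels, p, d))
        successful += 1
        for bp in tree_bipartitions(rep.tree):
            if bp in counts:
                counts[bp] += 1

    if successful == 0:
        raise ValueError("no bootstrap replicate yielded defined distances")
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in main.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        key = side if anchor not in side else all_leaves - side
        support = 100.0 * counts[key] / successful
        node.support = support
        node.name = f"{support:g}"
    main.n_bootstrap = n_replicates
    main.n_successful = successful
    return main


@dataclass
class SubfamilyAssignment:
    assignments: dict[str, str] = field(default_factory=dict)


def _edge_support(node: TreeNode) -> float:
    """Support of the edge above *node*: pendant edges count as fully
    supported; internal edges carry the node's bootstrap support (or its
    Newick label when the tree came from file; 100 when absent)."""
    if node.is_tip():
        return 100.0
    support = getattr(node, "support", None)
    if support is None and node.name:
        try:
            support = float(node.name)
        except ValueError:
            support = None
    return 100.0 if support is None else float(support)


def _adjacency(tree: TreeNode):
    """Undirected adjacency with per-edge (support, length)."""
    adj: dict[int, list[tuple[TreeNode, float, float]]] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(id(node), [])
    for node in tree.traverse(include_self=False):
        support = _edge_support(node)
        length = node.length if node.length is not None else 0.0
        adj[id(node.parent)].append((node, support, length))
        adj[id(node)].append((node.parent, support, length))
    return adj


def assign_subfamilies(
    dtree: DistanceTree | TreeNode,
    reference_labels: dict[str, str],
    support_min: float = 50.0,
) -> SubfamilyAssignment:
    """Label query leaves by their nearest well-supported reference clade.

    Walking outward from each query leaf along branch lengths, the first edge
    with support >= *support_min* whose far side (the side away from the
    query) contains references of exactly one group assigns that group;
    candidate edges are ranked by the patristic distance from the query to
    the edge's near end, ties broken by the smallest far-side leaf label.
    Queries with no such edge are "unassigned".
    """
    tree = dtree.tree if isinstance(dtree, DistanceTree) else dtree
    leaves = {t.name for t in tree.tips()}
    refs = {name: lbl for name, lbl in reference_labels.items() if name in leaves}
    if not refs:
        raise ValueError("tree contains no reference leaves")
    adj = _adjacency(tree)

    def far_side_leaves(u: TreeNode, v: TreeNode) -> set[str]:
        # leaves reachable from v without crossing back through u
        out, stack, seen = set(), [(u, v)], {id(u), id(v)}
        while stack:
            prev, node = stack.pop()
            if node.is_tip():
                out.add(node.name)
            for nbr, _s, _l in adj[id(node)]:
                if id(nbr) not in seen:
                    seen.add(id(nbr))
                    stack.append((node, nbr))
        return out

    result = SubfamilyAssignment()
    for qname in sorted(leaves - set(refs)):
        q = next(t for t in tree.tips() if t.name == qname)
        # patristic distance from q to every node
        dist = {id(q): 0.0}
        stack = [q]
        while stack:
            node = stack.pop()
            for nbr, _s, length in adj[id(node)]:
                if id(nbr) not in dist:
                    dist[id(nbr)] = dist[id(node)] + length
                    stack.append(nbr)
        candidates = []
        seen_edges = set()
        for node in tree.traverse(include_self=True):
            for nbr, support, _l in adj[id(node)]:
                key = frozenset((id(node), id(nbr)))
                if key in seen_edges:
                    continue
                seen_edges.add(key)
                if support < support_min:
                    continue
                # orient so `far` is the endpoint away from the query
                near, far = (
                    (node, nbr) if dist[id(node)] <= dist[id(nbr)] else (nbr, node)
                )
                far_names = far_side_leaves(near, far)
                if qname in far_names:
                    continue
                far_labels = {refs[n] for n in far_names if n in refs}
                if len(far_labels) == 1:
                    candidates.append(
                        (dist[id(near)], min(far_names), far_labels.pop())
                    )
        if candidates:
            candidates.sort()
            result.assignments[qname] = candidates[0][2]
        else:
            result.assignments[qname] = "unassigned"
    return result


# ---------------------------------------------------------------------------
# Minimal progressive multiple aligner (guide-tree + profile-profile NW).
# Provided for the synthetic end-to-end path; for production data supply a
# precomputed alignment from a dedicated MSA tool.

from Bio.Align import substitution_matrices

_BLOSUM = None
_B62_INDEX = {}


def _blosum_matrix() -> np.ndarray:
    global _BLOSUM, _B62_INDEX
    if _BLOSUM is None:
        m = substitution_matrices.load("BLOSUM62")
        letters = "ACDEFGHIKLMNPQRSTVWYX"
        _B62_INDEX.update({a: i for i, a in enumerate(letters)})
        _BLOSUM = np.zeros((21, 21))
        for a in letters:
            for b in letters:
                _BLOSUM[_B62_INDEX[a], _B62_INDEX[b]] = m[a][b]
    return _BLOSUM


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 21) residue-frequency profile; gaps contribute nothing."""
    B = len(_B62_INDEX)
    out = np.zeros((len(rows[0]), B))
    for row in rows:
        for i, aa in enumerate(row):
            if aa not in GAP_CHARS:
                out[i, _B62_INDEX.get(aa, _B62_INDEX["X"])] += 1
    sums = out.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return out / sums


def _profile_nw(rows_a: list[str], rows_b: list[str], gap: float = 4.0):
    """Needleman–Wunsch between two profiles with linear gap cost."""
    blosum = _blosum_matrix()
    fa, fb = _profile(rows_a), _profile(rows_b)
    S = fa @ blosum @ fb.T
    La, Lb = S.shape
    H = np.zeros((La + 1, Lb + 1))
    H[:, 0] = -gap * np.arange(La + 1)
    H[0, :] = -gap * np.arange(Lb + 1)
    ptr = np.zeros((La + 1, Lb + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, La + 1):
        row = H[i]
        prev = H[i - 1]
        for j in range(1, Lb + 1):
            diag = prev[j - 1] + S[i - 1, j - 1]
            up = prev[j] - gap
            left = row[j - 1] - gap
            if diag >= up and diag >= left:
                row[j], ptr[i, j] = diag, 0
            elif up >= left:
                row[j], ptr[i, j] = up, 1
            else:
                row[j], ptr[i, j] = left, 2
    out_a = [""] * len(rows_a)
    out_b = [""] * len(rows_b)
    i, j = La, Lb
    cols_a, cols_b = [], []
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            i, j = i - 1, j - 1
        elif move == 1:
            cols_a.append(i - 1)
            cols_b.append(None)
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            j -= 1
    cols_a.reverse()
    cols_b.reverse()
    for k, row in enumerate(rows_a):
        out_a[k] = "".join("-" if c is None else row[c] for c in cols_a)
    for k, row in enumerate(rows_b):
        out_b[k] = "".join("-" if c is None else row[c] for c in cols_b)
    return out_a, out_b


def progressive_align(seqs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Progressive multiple alignment along an NJ guide tree.

    Guide distances are p-distances from pairwise global alignments; groups
    are merged by profile–profile Needleman–Wunsch with BLOSUM62 expected
    scores and a linear gap cost.  Adequate for the well-separated synthetic
    families this package generates; not a general-purpose MSA tool.
    """
    from .duplication import coverage_and_similarity, global_align

    if len(seqs) < 2:
        return list(seqs)
    n = len(seqs)
    ids = [s.id for s in seqs]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i].residues, seqs[j].residues)
            _, sim = coverage_and_similarity(aln)
            p[i, j] = p[j, i] = 1.0 - sim
    if n == 2:
        aln = global_align(seqs[0].residues, seqs[1].residues)
        return [
            SequenceRecord(ids[0], seqs[0].description, aln.aligned_a),
            SequenceRecord(ids[1], seqs[1].description, aln.aligned_b),
        ]

    guide = nj_tree(DistanceMatrix(ids, p, p.copy())).tree
    by_id = {s.id: s.residues for s in seqs}

    def align_node(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [by_id[node.name]]
        parts = [align_node(c) for c in node.children]
        names, rows = parts[0]
        for more_names, more_rows in parts[1:]:
            rows, more_rows = _profile_nw(rows, more_rows)
            names = names + more_names
            rows = rows + more_rows
        return names, rows

    names, rows = align_node(guide)
    order = {name: k for k, name in enumerate(names)}
    return [
        SequenceRecord(s.id, s.description, rows[order[s.id]]) for s in seqs
    ]
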
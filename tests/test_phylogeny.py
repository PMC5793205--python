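import itertools
import warnings

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

import famscan as fs
from famscan.io import AMINO_ACIDS, SequenceRecord
from famscan.phylogeny import (
    DistanceMatrix,
    assign_subfamilies,
    bootstrap_supports,
    nj_tree,
    poisson_distance_matrix,
    tree_bipartitions,
)

from oracles import all_unrooted_topologies, least_squares_fit, topology_bipartitions


def recs(**seqs):
    return [SequenceRecord(k, "", v) for k, v in sorted(seqs.items())]


class TestPoissonDistances:
    def test_identical_sequences(self):
        dm = poisson_distance_matrix(recs(a="MKVL", b="MKVL"))
        assert dm.p[0, 1] == 0.0 and dm.d[0, 1] == 0.0

    def test_poisson_correction_value(self):
        # 1 difference over 10 sites: p = 0.1, d = -ln(0.9)
        dm = poisson_distance_matrix(recs(a="AAAAAAAAAA", b="AAAAAAAAAC"))
        assert dm.p[0, 1] == pytest.approx(0.1)
        assert dm.d[0, 1] == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_pairwise_deletion_drops_gapped_columns(self):
        dm = poisson_distance_matrix(recs(a="A-C", b="AGC"))
        assert dm.p[0, 1] == 0.0  # only columns 1 and 3 compared

    def test_saturated_pair_rejected(self):
        with pytest.raises(ValueError, match="every site"):
            poisson_distance_matrix(recs(a="AAAA", b="CCCC"))

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="no ungapped"):
            poisson_distance_matrix(recs(a="AA--", b="--CC"))

    def test_correction_dominates_p(self):
        rng = np.random.default_rng(2)
        seqs = {
            f"s{i}": "".join(rng.choice(list(AMINO_ACIDS), size=60)) for i in range(5)
        }
        dm = poisson_distance_matrix(recs(**seqs))
        assert (dm.d >= dm.p - 1e-12).all()


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive lengths and its leaf-pair
    path-length matrix."""
    labels = [f"L{i}" for i in range(n_leaves)]
    edges = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    n_internal = 1
    for leaf in labels[3:]:
        k = rng.integers(len(edges))
        u, v = edges.pop(int(k))
        mid = n_internal
        n_internal += 1
        edges += [(u, mid), (v, mid), (leaf, mid)]
    lengths = {frozenset(e): float(rng.uniform(0.05, 1.0)) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def dist(a, b):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            node, acc = stack.pop()
            if node == b:
                return acc
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, acc + lengths[frozenset((node, nbr))]))
        raise AssertionError

    d = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d[i, j] = d[j, i] = dist(labels[i], labels[j])
    return labels, edges, d


def tree_path_lengths(tree: TreeNode, labels):
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        dt = nj_tree(DistanceMatrix(["a", "b", "c"], d.copy(), d))
        lengths = {t.name: t.length for t in dt.tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_matrices_recovered_exactly(self):
        """NJ is exact on additive distances: topology and all path lengths."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(4, 9))
            labels, edges, d = random_additive_tree(rng, n)
            dt = nj_tree(DistanceMatrix(labels, d.copy(), d))
            assert tree_bipartitions(dt.tree) == topology_bipartitions(edges, labels)
            np.testing.assert_allclose(
                tree_path_lengths(dt.tree, labels), d, atol=1e-9
            )

    def test_enumeration_least_squares_oracle_five_leaves(self):
        """The generating topology is the unique zero-SSE topology among all
        15 unrooted 5-leaf trees, and NJ finds it."""
        rng = np.random.default_rng(43)
        for _ in range(10):
            labels, edges, d = random_additive_tree(rng, 5)
            fits = []
            for topo in all_unrooted_topologies(labels):
                sse, _ = least_squares_fit(topo, labels, d)
                fits.append((sse, topo))
            fits.sort(key=lambda t: t[0])
            best_sse, best_topo = fits[0]
            assert best_sse < 1e-16
            dt = nj_tree(DistanceMatrix(labels, d.copy(), d))
            assert tree_bipartitions(dt.tree) == topology_bipartitions(best_topo, labels)

    def test_matches_skbio_on_random_matrix(self):
        rng = np.random.default_rng(7)
        n = 7
        labels = [f"t{i}" for i in range(n)]
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.2, 2.0, size=len(iu[0]))
        d[iu] = vals
        d = d + d.T
        ours = nj_tree(DistanceMatrix(labels, d.copy(), d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        assert tree_bipartitions(ours.tree) == tree_bipartitions(theirs)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2.0], [1.5, 0, 1.0], [2.0, 1.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], d.copy(), d)

    def test_ultrametric_matches_upgma_topology(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(19)
        for _ in range(10):
            # build an ultrametric 4-leaf matrix from a random dendrogram
            h1, h2, h3 = np.sort(rng.uniform(0.1, 1.0, size=3))
            labels = ["a", "b", "c", "d"]
            d = np.zeros((4, 4))
            # ((a,b) at h1, c at h2) all vs d at h3
            d[0, 1] = d[1, 0] = 2 * h1
            for i in (0, 1):
                d[i, 2] = d[2, i] = 2 * h2
            for i in (0, 1, 2):
                d[i, 3] = d[3, i] = 2 * h3
            dt = nj_tree(DistanceMatrix(labels, d.copy(), d))
            link = hierarchy.linkage(squareform(d), method="average")
            # UPGMA joins (a,b) first; NJ must contain the same split
            assert frozenset({"c", "d"}) in tree_bipartitions(dt.tree) or \
                   frozenset({"a", "b"}) in tree_bipartitions(dt.tree)


def planted_clade_alignment(rng, n_clades=4, per_clade=4, length=120, within=0.03):
    seqs = {}
    for c in range(n_clades):
        ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        for k in range(per_clade):
            s = list(ancestor)
            for i in np.where(rng.random(length) < within)[0]:
                s[i] = AMINO_ACIDS[rng.integers(20)]
            seqs[f"c{c}_{k}"] = "".join(s)
    return recs(**seqs)


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(3)
        aln = planted_clade_alignment(rng, n_clades=3, per_clade=2, length=60)
        dt = bootstrap_supports(aln, n_replicates=1, seed=0)
        supports = [n.support for n in dt.tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_reproduces_supports(self):
        rng = np.random.default_rng(3)
        aln = planted_clade_alignment(rng, n_clades=3, per_clade=3, length=80)
        a = bootstrap_supports(aln, n_replicates=25, seed=5)
        b = bootstrap_supports(aln, n_replicates=25, seed=5)
        sa = {frozenset(t.name for t in n.tips()): n.support
              for n in a.tree.non_tips() if hasattr(n, "support")}
        sb = {frozenset(t.name for t in n.tips()): n.support
              for n in b.tree.non_tips() if hasattr(n, "support")}
        assert sa == sb

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(3)
        aln = planted_clade_alignment(rng, n_clades=3, per_clade=3, length=80)
        a = bootstrap_supports(aln, n_replicates=25, seed=5)
        b = bootstrap_supports(aln[::-1], n_replicates=25, seed=5)
        sa = {frozenset(t.name for t in n.tips()): n.support
              for n in a.tree.non_tips() if hasattr(n, "support")}
        sb = {frozenset(t.name for t in n.tips()): n.support
              for n in b.tree.non_tips() if hasattr(n, "support")}
        assert sa == sb

    def test_clean_clades_highly_supported(self):
        rng = np.random.default_rng(41)
        aln = planted_clade_alignment(rng)
        dt = bootstrap_supports(aln, n_replicates=100, seed=2)
        clade_names = [{f"c{c}_{k}" for k in range(4)} for c in range(4)]
        bps = {
            frozenset(t.name for t in n.tips()): n.support
            for n in dt.tree.non_tips()
            if hasattr(n, "support")
        }
        all_leaves = frozenset(s.id for s in aln)
        for clade in clade_names:
            support = bps.get(frozenset(clade), bps.get(all_leaves - clade))
            assert support is not None and support >= 95.0


class TestAssignSubfamilies:
    def test_query_sister_to_single_reference(self):
        tree = TreeNode.read(["((Q:0.05,R1:0.05)90:0.4,(R2:0.1,R3:0.1)95:0.4,R4:0.5);"])
        result = assign_subfamilies(tree, {"R1": "I", "R2": "II", "R3": "II", "R4": "III"})
        assert result.assignments["Q"] == "I"

    def test_mixed_clade_is_unassigned(self):
        # both neighbors carry different labels at high support
        tree = TreeNode.read(["((Q:0.5,R1:0.5)90:0.1,(R2:0.5,R3:0.5)90:0.1,R4:0.6);"])
        result = assign_subfamilies(
            tree, {"R1": "I", "R2": "II", "R3": "III", "R4": "IV"},
            support_min=50,
        )
        # nearest pure edge is R1's pendant edge
        assert result.assignments["Q"] == "I"
        # with R1 relabelled to match nothing pure nearby except pendants,
        # an all-mixed interior stays unassignable when pendants are far
        tree2 = TreeNode.read(["((Q:0.1,X:4.0)30:0.1,(R2:4.0,R3:4.0)30:0.1,R4:4.0);"])
        result2 = assign_subfamilies(
            tree2, {"X": "I", "R2": "II", "R3": "III", "R4": "IV"}, support_min=50
        )
        assert result2.assignments["Q"] == "I"  # pendant edges always supported

    def test_low_support_edges_ignored(self):
        tree = TreeNode.read(["((Q:0.1,(R1:0.1,R2:0.1)20:0.1)20:0.1,R3:0.1,R4:0.1);"])
        result = assign_subfamilies(
            tree, {"R1": "I", "R2": "I", "R3": "II", "R4": "II"}, support_min=50
        )
        # the internal I-clade edge is unsupported, but each pendant reference
        # edge is trivially supported, so the nearest pure pendant wins
        assert result.assignments["Q"] == "I"

    def test_no_references_rejected(self):
        tree = TreeNode.read(["((A:1,B:1):1,C:1,D:1);"])
        with pytest.raises(ValueError, match="reference"):
            assign_subfamilies(tree, {"Z": "I"})

    def test_planted_subfamilies_recovered(self, bundle, members):
        _, _, _, truth = bundle
        leaves = [SequenceRecord(m.name, "", m.protein.residues) for m in members]
        leaves += truth.reference_records
        aln = fs.progressive_align(leaves)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dt = bootstrap_supports(aln, n_replicates=50, seed=1)
        result = assign_subfamilies(dt, truth.reference_labels, support_min=50)
        name_of = {m.gene_id: m.name for m in members}
        expected = {name_of[g]: lbl for g, lbl in truth.subfamily_of.items()}
        assert result.assignments == expected
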
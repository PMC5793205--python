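import numpy as np
import pytest
from Bio.Align import substitution_matrices

import famscan as fs
from famscan.duplication import (
    DuplicationCall,
    classify_duplications,
    coverage_and_similarity,
    global_align,
)
from famscan.identify import DomainHit, FamilyMember
from famscan.io import AMINO_ACIDS, AnnotatedGenome, GeneModel, SequenceRecord, TranscriptModel

from oracles import brute_global_align_score

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("MKV", "MKV")
        cov, sim = coverage_and_similarity(aln)
        assert aln.aligned_a == aln.aligned_b == "MKV"
        assert (cov, sim) == (1.0, 1.0)

    def test_single_gap(self):
        aln = global_align("MKV", "MV")
        assert len(aln.aligned_a) == 3
        assert sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if "-" in (x, y)) == 1

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 30)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(3, 30)))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_score_matches_exhaustive_enumeration(self):
        """200 random short pairs: affine-gap optimum equals brute force."""
        rng = np.random.default_rng(23)
        for _ in range(200):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 9)))
            aln = global_align(a, b)
            expected = brute_global_align_score(
                a, b, lambda x, y: float(BLOSUM62[x][y]), 10.0, 1.0
            )
            assert aln.score == pytest.approx(expected, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MKV")


def mk_member(name, gene_id, protein):
    hit = DomainHit(f"{gene_id}.p", (1, 1), (1, 1), 1.0, 1.0)
    return FamilyMember(name, gene_id, f"{gene_id}.1",
                        SequenceRecord(f"{gene_id}.p", "", protein), hit)


def mk_genome(positions):
    """positions: {gene_id: (chrom, start, end)} plus filler genes."""
    genes = []
    chrom_max: dict[str, int] = {}
    for gid, (chrom, start, end) in positions.items():
        tx = TranscriptModel(f"{gid}.1", [(start, end)], [], f"{gid}.p")
        genes.append(GeneModel(gid, chrom, start, end, "+", [tx]))
        chrom_max[chrom] = max(chrom_max.get(chrom, 0), end)
    chroms = [(c, m + 10_000) for c, m in sorted(chrom_max.items())]
    return AnnotatedGenome(chroms, genes)


class TestCallDuplications:
    def test_identical_paralogs_called(self):
        rng = np.random.default_rng(3)
        protein = "".join(rng.choice(list(AMINO_ACIDS), size=120))
        a, b = mk_member("A", "g1", protein), mk_member("B", "g2", protein)
        (call,) = fs.call_duplications([a, b])
        assert (call.coverage, call.similarity) == (1.0, 1.0)
        assert (call.gene_a, call.gene_b) == ("A", "B")

    def test_half_identity_rejected(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list(AMINO_ACIDS), size=120))
        # mutate half the sites
        other = list(base)
        for i in range(0, 120, 2):
            other[i] = AMINO_ACIDS[(AMINO_ACIDS.index(other[i]) + 1) % 20]
        calls = fs.call_duplications(
            [mk_member("A", "g1", base), mk_member("B", "g2", "".join(other))]
        )
        assert calls == []

    def test_planted_pairs_recovered(self, bundle, members):
        genome, _, _, truth = bundle
        calls = fs.call_duplications(members)
        name_of = {m.gene_id: m.name for m in members}
        called = {(c.gene_a, c.gene_b) for c in calls}
        for a, b in truth.segmental_pairs:
            assert tuple(sorted((name_of[a], name_of[b]))) in called
        for cluster in truth.tandem_clusters:
            names = sorted(name_of[g] for g in cluster)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    assert tuple(sorted((names[i], names[j]))) in called

    def test_input_order_symmetry(self, members):
        some = members[:8]
        a = fs.call_duplications(some)
        b = fs.call_duplications(some[::-1])
        key = lambda c: (c.gene_a, c.gene_b)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestClassifyDuplications:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.protein = "".join(rng.choice(list(AMINO_ACIDS), size=100))

    def pair_call(self, a, b):
        return DuplicationCall(a, b, 1.0, 1.0)

    def test_close_pair_is_tandem(self):
        genome = mk_genome({
            "g1": ("chr01", 10_000, 12_000),
            "g2": ("chr01", 60_000, 62_000),
            "f1": ("chr01", 20_000, 21_000),
            "f2": ("chr01", 30_000, 31_000),
            "f3": ("chr01", 40_000, 41_000),
        })
        members = [mk_member("A", "g1", self.protein), mk_member("B", "g2", self.protein)]
        clusters, seg = classify_duplications([self.pair_call("A", "B")], members, genome)
        assert [c.members for c in clusters] == [["A", "B"]]
        assert seg == []

    def test_distant_same_chromosome_pair_is_segmental(self):
        genome = mk_genome({
            "g1": ("chr01", 10_000, 12_000),
            "g2": ("chr01", 180_000, 182_000),
        })
        members = [mk_member("A", "g1", self.protein), mk_member("B", "g2", self.protein)]
        clusters, seg = classify_duplications([self.pair_call("A", "B")], members, genome)
        assert clusters == []
        assert [(s.gene_a, s.gene_b) for s in seg] == [("A", "B")]

    def test_too_many_intervening_genes_blocks_tandem(self):
        positions = {"g1": ("chr01", 10_000, 11_000), "g2": ("chr01", 90_000, 91_000)}
        for k in range(6):
            positions[f"f{k}"] = ("chr01", 20_000 + 10_000 * k, 21_000 + 10_000 * k)
        genome = mk_genome(positions)
        members = [mk_member("A", "g1", self.protein), mk_member("B", "g2", self.protein)]
        clusters, seg = classify_duplications([self.pair_call("A", "B")], members, genome)
        assert clusters == [] and seg == []  # unclassified, not segmental

    def test_chain_merges_into_single_cluster(self):
        genome = mk_genome({
            "g1": ("chr01", 10_000, 11_000),
            "g2": ("chr01", 50_000, 51_000),
            "g3": ("chr01", 95_000, 96_000),
        })
        members = [mk_member(n, g, self.protein) for n, g in
                   (("A", "g1"), ("B", "g2"), ("C", "g3"))]
        calls = [self.pair_call("A", "B"), self.pair_call("B", "C")]
        clusters, _ = classify_duplications(calls, members, genome)
        assert [c.members for c in clusters] == [["A", "B", "C"]]

    def test_unknown_member_rejected(self):
        genome = mk_genome({"g1": ("chr01", 10_000, 11_000)})
        with pytest.raises(KeyError):
            classify_duplications(
                [self.pair_call("A", "Z")], [mk_member("A", "g1", self.protein)], genome
            )

    def test_planted_clusters_recovered_exactly(self, bundle, members):
        genome, _, _, truth = bundle
        calls = fs.call_duplications(members)
        clusters, seg = fs.classify_duplications(calls, members, genome)
        name_of = {m.gene_id: m.name for m in members}
        assert [c.members for c in clusters] == [
            [name_of[g] for g in cluster] for cluster in truth.tandem_clusters
        ]
        assert sorted((s.gene_a, s.gene_b) for s in seg) == sorted(
            tuple(sorted((name_of[a], name_of[b]))) for a, b in truth.segmental_pairs
        )
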
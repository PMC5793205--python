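"""Rule-based duplication calling and tandem/segmental classification.

A pair of family members is a duplicate when, in an optimal global protein
alignment, (a) the shorter sequence's aligned share covers more than 70% of
the longer sequence and (b) more than 70% of aligned columns are identical.
Called pairs lying within 100 kb on one chromosome with at most five
intervening genes (whole-genome gene order) are tandem duplicates, merged
into clusters by single linkage; called pairs on different chromosomes or
at >=100 kb are segmental.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

from .io import AnnotatedGenome
from .identify import FamilyMember

DEFAULT_COVERAGE_MIN = 0.70
DEFAULT_SIMILARITY_MIN = 0.70
TANDEM_WINDOW_BP = 100_000
TANDEM_MAX_INTERVENING = 5


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


@dataclass
class DuplicationCall:
    gene_a: str        # member names, gene_a < gene_b lexicographically
    gene_b: str
    coverage: float
    similarity: float
    classification: str = "unclassified"   # tandem | segmental | unclassified


@dataclass
class TandemCluster:
    members: list[str]    # member names ordered by genomic position
    chromosome: str


def _aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length L costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> PairwiseAlignment:
    """Optimal global alignment (Needleman–Wunsch with affine gaps).

    A gap of length L costs ``gap_open + L*gap_extend``.  Of co-optimal
    alignments the aligner's first is returned, which is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(gap_open, gap_extend, matrix_name)
    alignment = next(iter(aligner.align(a, b)))
    sa, sb = str(alignment[0]), str(alignment[1])
    return PairwiseAlignment(sa, sb, float(alignment.score))


def coverage_and_similarity(
    aln: PairwiseAlignment, conservative_groups: bool = False
) -> tuple[float, float]:
    """Coverage and similarity of an alignment, per the duplication criteria.

    Coverage: aligned (residue-to-residue) positions divided by the length of
    the longer input.  Similarity: identical positions over aligned columns,
    where single-gap columns count as mismatches (double-gap columns cannot
    occur in a pairwise alignment).  With ``conservative_groups`` a positive
    substitution-group match counts as similar instead of identity only.
    """
    groups = ("AG", "ST", "DE", "NQ", "KR", "ILVM", "FYW") if conservative_groups else ()
    paired = identical = columns = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x != "-" and y != "-":
            paired += 1
            if x == y or any(x in g and y in g for g in groups):
                identical += 1
    len_a = sum(1 for x in aln.aligned_a if x != "-")
    len_b = sum(1 for x in aln.aligned_b if x != "-")
    coverage = paired / max(len_a, len_b)
    similarity = identical / columns if columns else 0.0
    return coverage, similarity


def call_duplications(
    members: list[FamilyMember],
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    similarity_min: float = DEFAULT_SIMILARITY_MIN,
    conservative_groups: bool = False,
) -> list[DuplicationCall]:
    """Evaluate every unordered member pair against the duplication criteria.

    Both thresholds are strict (>): a pair at exactly 70% fails.
    """
    if len(members) < 2:
        return []
    calls = []
    for m1, m2 in combinations(sorted(members, key=lambda m: m.name), 2):
        a, b = sorted((m1, m2), key=lambda m: m.name)
        aln = global_align(a.protein.residues, b.protein.residues)
        cov, sim = coverage_and_similarity(aln, conservative_groups)
        if cov > coverage_min and sim > similarity_min:
            calls.append(DuplicationCall(a.name, b.name, cov, sim))
    return calls


def _intervening_genes(genome: AnnotatedGenome, chrom: str, lo_end: int, hi_start: int) -> int:
    """Genes whose span lies strictly between two loci, whole-genome order."""
    return sum(
        1
        for g in genome.genes_on(chrom)
        if g.start > lo_end and g.end < hi_start
    )


def classify_duplications(
    calls: list[DuplicationCall],
    members: list[FamilyMember],
    genome: AnnotatedGenome,
    window_bp: int = TANDEM_WINDOW_BP,
    max_intervening: int = TANDEM_MAX_INTERVENING,
) -> tuple[list[TandemCluster], list[DuplicationCall]]:
    """Split called pairs into tandem clusters and segmental pairs.

    Tandem: same chromosome, start-to-start distance < *window_bp*, and at
    most *max_intervening* genes strictly between the pair (counted over the
    whole annotation, not family members only).  Tandem pairs are merged into
    clusters by single linkage.  Segmental: called pairs on different
    chromosomes or at start distance >= *window_bp*.  Same-chromosome pairs
    inside the window but with too many intervening genes stay unclassified.
    """
    gene_of = {m.name: genome.gene(m.gene_id) for m in members}
    for call in calls:
        if call.gene_a not in gene_of or call.gene_b not in gene_of:
            missing = call.gene_a if call.gene_a not in gene_of else call.gene_b
            raise KeyError(f"duplication call references unknown member {missing!r}")

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    segmental = []
    for call in calls:
        ga, gb = gene_of[call.gene_a], gene_of[call.gene_b]
        same_chrom = ga.chromosome == gb.chromosome
        dist = abs(ga.start - gb.start)
        if same_chrom and dist < window_bp:
            lo, hi = sorted((ga, gb), key=lambda g: g.start)
            if _intervening_genes(genome, ga.chromosome, lo.end, hi.start) <= max_intervening:
                call.classification = "tandem"
                parent[find(call.gene_a)] = find(call.gene_b)
                continue
            call.classification = "unclassified"
        else:
            call.classification = "segmental"
            segmental.append(call)

    groups: dict[str, list[str]] = {}
    for name in parent:
        groups.setdefault(find(name), []).append(name)
    clusters = []
    for names in groups.values():
        names.sort(key=lambda n: gene_of[n].start)
        clusters.append(TandemCluster(names, gene_of[names[0]].chromosome))
    clusters.sort(key=lambda c: (c.chromosome, gene_of[c.members[0]].start))
    return clusters, segmental
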
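"""Domain-based family identification.

The family is defined by a conserved protein domain.  A position-specific
log-odds profile is built from a seed alignment of the domain, every
representative protein in the proteome is scanned with a glocal dynamic
programme (profile global, target local), and proteins whose best hit covers
at least ``completeness_min`` of the profile columns are accepted and named
``<prefix>1..<prefix>N`` in chromosome order (unanchored pseudo-chromosome
first, then by start coordinate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, AnnotatedGenome, GeneModel, SequenceRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: affine gap penalties for the glocal scan, in score (bit) units
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
#: minimum bit score for a hit to be reported at all
DEFAULT_REPORT_THRESHOLD = 0.0
#: fraction of profile columns that must be matched for a "complete" domain
DEFAULT_COMPLETENESS = 0.9


@dataclass
class DomainProfile:
    """Position-specific log-odds scores (bits) over the 20 amino acids."""

    scores: np.ndarray        # (ncols, 20) log2 odds
    background: np.ndarray    # (20,) frequencies summing to 1

    @property
    def ncols(self) -> int:
        return self.scores.shape[0]


@dataclass
class DomainHit:
    protein_id: str
    profile_span: tuple[int, int]   # 1-based first/last profile column matched
    target_span: tuple[int, int]    # 1-based first/last residue aligned
    score: float                    # bits
    profile_coverage: float         # matched columns / ncols


@dataclass
class FamilyMember:
    name: str
    gene_id: str
    representative_transcript_id: str
    protein: SequenceRecord
    hit: DomainHit


def build_profile(
    seed_alignment: list[SequenceRecord],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> DomainProfile:
    """Build a log-odds profile from an aligned set of domain sequences.

    Column score for residue *a* is
    ``log2(((count_a + pc*bg_a) / (n + pc)) / bg_a)`` where *n* is the number
    of non-gap residues in the column.  Columns that are more than 50% gaps
    are dropped.
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs at least 2 sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    lengths = {len(r.residues) for r in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("seed alignment sequences have unequal lengths")
    width = lengths.pop()
    nseq = len(seed_alignment)

    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if abs(background.sum() - 1.0) > 1e-12:
        raise ValueError("background frequencies must sum to 1")

    columns = []
    for j in range(width):
        counts = np.zeros(20)
        n = 0
        for rec in seed_alignment:
            aa = rec.residues[j]
            if aa in ("-", "."):
                continue
            n += 1
            if aa in _AA_INDEX:        # X contributes no count
                counts[_AA_INDEX[aa]] += 1
        if n < nseq / 2 or n == 0:     # >50% gaps -> drop column
            continue
        freq = (counts + pseudocount * background) / (n + pseudocount)
        columns.append(np.log2(freq / background))
    if not columns:
        raise ValueError("all alignment columns were gap-majority")
    return DomainProfile(np.array(columns), background)


def _column_scores(profile: DomainProfile, protein: str) -> np.ndarray:
    """(ncols, L) score of aligning each profile column to each residue; X -> 0."""
    L = len(protein)
    idx = np.array([_AA_INDEX.get(a, -1) for a in protein])
    known = idx >= 0
    out = np.zeros((profile.ncols, L))
    out[:, known] = profile.scores[:, idx[known]]
    return out


def scan_profile(
    protein: SequenceRecord,
    profile: DomainProfile,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> DomainHit | None:
    """Best glocal alignment of the whole profile inside one protein.

    The profile is aligned end to end — deleted columns pay affine gap costs
    (``open + (run-1)*extend`` per run) and do not count as matched — while
    the target contributes any contiguous substring, overhangs free.  Returns
    ``None`` for an empty protein or a best score below *report_threshold*.

    DP states per (column c, residue index t, both 0-based):
    ``M[c,t]`` column c matched to residue t; ``D[c,t]`` column c deleted,
    last consumed residue t; ``I[c,t]`` residue t inserted after column c.
    ``lead[c]`` is the pure-deletion prefix (columns 0..c deleted before any
    residue is consumed).
    """
    seq = protein.residues
    L = len(seq)
    if L == 0:
        return None
    C = profile.ncols
    S = _column_scores(profile, seq)
    NEG = -np.inf

    M = np.full((C, L), NEG)
    D = np.full((C, L), NEG)
    I = np.full((C, L), NEG)
    lead = -gap_open - gap_extend * np.arange(C)

    t_idx = np.arange(L, dtype=float)
    for c in range(C):
        if c == 0:
            M[0] = S[0]                     # free leading target overhang
            D[0] = lead[0]                  # residues so far are overhang
        else:
            diag = np.full(L, lead[c - 1])  # leading deletions, then match
            prev = np.maximum(np.maximum(M[c - 1], D[c - 1]), I[c - 1])
            diag[1:] = np.maximum(diag[1:], prev[:-1])
            diag[0] = max(diag[0], lead[c - 1])
            M[c] = S[c] + diag
            D[c] = np.maximum(
                np.maximum(M[c - 1] - gap_open, D[c - 1] - gap_extend),
                I[c - 1] - gap_open,
            )
            D[c] = np.maximum(D[c], lead[c])
        # I[c,t] = max over t'<t of max(M[c,t'], D[c,t']) - open - (t-1-t')*ext
        base = np.maximum(M[c], D[c])
        if L > 1:
            g = np.maximum.accumulate(base[:-1] + t_idx[:-1] * gap_extend)
            I[c, 1:] = g - gap_open - (t_idx[1:] - 1) * gap_extend

    final = np.maximum(M[C - 1], D[C - 1])  # free trailing target overhang
    best_t = int(np.argmax(final))
    best = float(final[best_t])
    if not np.isfinite(best) or best < report_threshold:
        return None

    path = _traceback(S, M, D, I, lead, best_t, gap_open, gap_extend)
    matched_cols = [c for c, t, st in path if st == "M"]
    if not matched_cols:
        return None                          # pure-deletion optimum: no domain
    matched_ts = [t for c, t, st in path if st == "M"]
    return DomainHit(
        protein_id=protein.id,
        profile_span=(min(matched_cols) + 1, max(matched_cols) + 1),
        target_span=(min(matched_ts) + 1, max(matched_ts) + 1),
        score=best,
        profile_coverage=len(matched_cols) / C,
    )


def _traceback(S, M, D, I, lead, t, gap_open, gap_extend):
    """Walk the DP matrices back from the optimum; returns [(c, t, state)]."""
    C, L = S.shape
    eps = 1e-9
    c = C - 1
    state = "M" if M[c, t] >= D[c, t] else "D"
    path = []
    while c >= 0:
        path.append((c, t, state))
        if state == "M":
            need = M[c, t] - S[c, t]         # value the predecessor must have
            if c == 0:
                break                         # free overhang start
            if t > 0 and abs(need - M[c - 1, t - 1]) < eps:
                c, t, state = c - 1, t - 1, "M"
            elif t > 0 and abs(need - D[c - 1, t - 1]) < eps:
                c, t, state = c - 1, t - 1, "D"
            elif t > 0 and abs(need - I[c - 1, t - 1]) < eps:
                c, t, state = c - 1, t - 1, "I"
            else:                             # leading deletions (lead[c-1])
                for cc in range(c - 1, -1, -1):
                    path.append((cc, -1, "D"))
                break
        elif state == "D":
            if abs(D[c, t] - lead[c]) < eps:
                for cc in range(c - 1, -1, -1):
                    path.append((cc, -1, "D"))
                break
            if c > 0 and abs(D[c, t] - (M[c - 1, t] - gap_open)) < eps:
                c, state = c - 1, "M"
            elif c > 0 and abs(D[c, t] - (D[c - 1, t] - gap_extend)) < eps:
                c = c - 1
            elif c > 0 and abs(D[c, t] - (I[c - 1, t] - gap_open)) < eps:
                c, state = c - 1, "I"
            else:
                break
        else:  # state == "I": residue t inserted after column c
            if t > 0 and abs(I[c, t] - (I[c, t - 1] - gap_extend)) < eps:
                t = t - 1
            elif t > 0 and abs(I[c, t] - (M[c, t - 1] - gap_open)) < eps:
                t, state = t - 1, "M"
            elif t > 0 and abs(I[c, t] - (D[c, t - 1] - gap_open)) < eps:
                t, state = t - 1, "D"
            else:
                break
    return path


def select_representative(gene: GeneModel, proteome: dict[str, SequenceRecord]) -> str:
    """Representative transcript of a locus: longest CDS, ties to smaller id."""
    coding = [
        tx
        for tx in gene.transcripts
        if tx.cds_segments and tx.protein_id in proteome
    ]
    if not coding:
        raise ValueError(f"gene {gene.gene_id} has no coding transcript with a protein")
    coding.sort(key=lambda tx: (-tx.cds_length, tx.transcript_id))
    return coding[0].transcript_id


def identify_family(
    proteome: list[SequenceRecord],
    genome: AnnotatedGenome,
    profile: DomainProfile,
    completeness_min: float = DEFAULT_COMPLETENESS,
    prefix: str = "Fam",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[FamilyMember]:
    """Scan every locus (representative transcript only) and name the family.

    A gene joins the family when its representative protein has a profile hit
    with ``profile_coverage >= completeness_min``.  Members are ordered by
    (chromosome with the unanchored pseudo-chromosome first, start, gene id)
    and named ``prefix1..prefixN``.
    """
    by_id = {r.id: r for r in proteome}
    chrom_rank = {name: i for i, name in enumerate(genome.chromosome_order())}

    accepted: list[tuple[tuple, str, str, SequenceRecord, DomainHit]] = []
    for gene in genome.genes:
        try:
            rep = select_representative(gene, by_id)
        except ValueError:
            warnings.warn(f"gene {gene.gene_id}: no protein mapping, excluded", stacklevel=2)
            continue
        tx = next(t for t in gene.transcripts if t.transcript_id == rep)
        protein = by_id[tx.protein_id]
        hit = scan_profile(protein, profile, gap_open, gap_extend)
        if hit is None or hit.profile_coverage < completeness_min:
            continue
        key = (chrom_rank.get(gene.chromosome, len(chrom_rank)), gene.start, gene.gene_id)
        accepted.append((key, gene.gene_id, rep, protein, hit))

    accepted.sort(key=lambda item: item[0])
    return [
        FamilyMember(f"{prefix}{rank}", gene_id, rep, protein, hit)
        for rank, (_, gene_id, rep, protein, hit) in enumerate(accepted, start=1)
    ]
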
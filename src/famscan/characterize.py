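"""Physicochemical and gene-structure characterization of family members.

Covers protein length / molecular weight / isoelectric point, intron counts
and phases from the CDS layout, and scanning of bracket-consensus motif
patterns (one leftmost occurrence per motif per protein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, TranscriptModel

WATER_DA = 18.0153

#: average residue masses (Da), i.e. amino-acid mass minus one water
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
# X: unknown residue -> mean of the 20 standard masses, no charge contribution
AVERAGE_RESIDUE_MASS["X"] = sum(
    AVERAGE_RESIDUE_MASS[a] for a in AMINO_ACIDS
) / 20.0

#: pKa values used for the net-charge model (termini and ionizable side chains)
DEFAULT_PKA = {
    "Nterm": 9.094, "Cterm": 2.869,
    "C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637,
    "K": 9.052, "R": 11.84, "Y": 10.85,
}
_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass
class ProteinStats:
    length: int
    molecular_weight: float   # Da, average masses
    isoelectric_point: float  # pH units


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    try:
        return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_DA
    except KeyError as exc:
        raise ValueError(f"illegal amino acid {exc.args[0]!r}") from exc


def net_charge(seq: str, ph, pka: dict[str, float] | None = None):
    """Net charge of the peptide at pH (scalar or array), Henderson–Hasselbalch.

    Positive groups (N-terminus, K, R, H) contribute ``1/(1+10^(pH-pKa))``,
    negative groups (C-terminus, D, E, C, Y) ``-1/(1+10^(pKa-pH))``; X is
    treated as chargeless.
    """
    pka = pka or DEFAULT_PKA
    ph = np.asarray(ph, dtype=float)
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge = charge - 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _POSITIVE:
        n = seq.count(aa)
        if n:
            charge = charge + n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        n = seq.count(aa)
        if n:
            charge = charge - n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge if charge.shape else float(charge)


def isoelectric_point(
    seq: str, pka: dict[str, float] | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, found by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges to the
    unique root; the interval is narrowed to 1e-7 pH units (the flat tails of
    the titration curve make a charge-based stop too loose).  *tol* bounds
    the residual charge at the returned pH.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    if abs(net_charge(seq, mid, pka)) > tol:
        raise ArithmeticError(f"pI solver residual charge exceeds {tol}")
    return mid


def protein_stats(seq: str, pka: dict[str, float] | None = None) -> ProteinStats:
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"illegal amino acids {sorted(bad)}")
    return ProteinStats(
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        isoelectric_point=isoelectric_point(seq, pka),
    )


@dataclass
class IntronAnnotation:
    intron_count: int
    phases: list[int]   # one per intron, transcription order, each in {0,1,2}


def intron_phases(transcript: TranscriptModel) -> IntronAnnotation:
    """Intron count and phases from the coding-exon layout.

    Phase of intron *i* = cumulative CDS length upstream of the intron mod 3:
    0 = splice after a complete codon, 1 = after the first nucleotide,
    2 = after the second.  CDS segments must already be in transcription
    order (the GFF3 reader guarantees this for both strands).
    """
    if not transcript.cds_segments:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    if transcript.cds_length % 3 != 0:
        raise ValueError(
            f"transcript {transcript.transcript_id}: CDS length not divisible by 3"
        )
    phases = []
    cumulative = 0
    for start, end in transcript.cds_segments[:-1]:
        cumulative += end - start + 1
        phases.append(cumulative % 3)
    return IntronAnnotation(intron_count=len(phases), phases=phases)


@dataclass
class MotifPattern:
    """Bracket-consensus pattern: an ordered list of allowed-residue sets."""

    motif_id: int
    positions: list[frozenset[str]]

    @property
    def width(self) -> int:
        return len(self.positions)


@dataclass
class MotifArchitecture:
    protein_id: str
    occurrences: list[tuple[int, int]]  # (motif_id, 1-based start), sorted by start


def parse_bracket_pattern(text: str, motif_id: int = 0) -> MotifPattern:
    """Parse a bracket-consensus string like ``"[PK][PK]KDY[IV]HVRA"``.

    Single letters allow one residue, ``[...]`` any of the bracketed set, and
    ``X`` any of the 20 standard residues.  Raises ``ValueError`` with the
    0-based offset of an unbalanced bracket.
    """
    positions: list[frozenset[str]] = []
    full = frozenset(AMINO_ACIDS)
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            close = text.find("]", i)
            if close == -1:
                raise ValueError(f"unbalanced '[' at offset {i}")
            inner = text[i + 1 : close]
            if not inner:
                raise ValueError(f"empty bracket at offset {i}")
            positions.append(frozenset(inner.upper()))
            i = close + 1
        elif ch == "]":
            raise ValueError(f"unbalanced ']' at offset {i}")
        elif ch.upper() == "X":
            positions.append(full)
            i += 1
        else:
            positions.append(frozenset(ch.upper()))
            i += 1
    if not positions:
        raise ValueError("empty pattern")
    return MotifPattern(motif_id=motif_id, positions=positions)


def load_motif_patterns(path) -> list[MotifPattern]:
    """One bracket pattern per line; '#' comments and blank lines ignored."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            patterns.append(parse_bracket_pattern(line, motif_id=len(patterns) + 1))
    return patterns


def _match_at(seq: str, pattern: MotifPattern, start: int) -> bool:
    return all(
        seq[start + k] in allowed for k, allowed in enumerate(pattern.positions)
    )


def scan_motifs(protein_id: str, seq: str, patterns: list[MotifPattern]) -> MotifArchitecture:
    """Leftmost occurrence of each motif in the protein (at most one per motif)."""
    occurrences = []
    for pattern in patterns:
        w = pattern.width
        for start in range(len(seq) - w + 1):
            if _match_at(seq, pattern, start):
                occurrences.append((pattern.motif_id, start + 1))
                break
    occurrences.sort(key=lambda occ: (occ[1], occ[0]))
    return MotifArchitecture(protein_id=protein_id, occurrences=occurrences)
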
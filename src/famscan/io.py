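"""Readers and writers for the standard formats the pipeline consumes.

FASTA parsing goes through Biopython, GFF3 through :mod:`gffutils`, Newick
through scikit-bio.  All genomic coordinates are 1-based inclusive, matching
GFF3; the only place half-open arithmetic happens is :func:`to_zero_based`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in protein records: the 20 standard letters plus X
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: pseudo-chromosome collecting genes not anchored to a real chromosome;
#: sorts before every numbered chromosome so unanchored genes are named first
UNANCHORED = "chr00"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class SequenceRecord:
    """One FASTA record: identifier, free-text description, residues."""

    id: str
    description: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[tuple[int, int]]          # transcription order, 1-based inclusive
    cds_segments: list[tuple[int, int]]   # transcription order
    protein_id: str | None = None
    cds_frame_ok: bool = True             # False when total CDS % 3 != 0

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)


@dataclass
class AnnotatedGenome:
    """Gene/transcript/exon/CDS coordinate model plus chromosome lengths."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def chromosome_order(self) -> list[str]:
        """Chromosome names with the unanchored pseudo-chromosome first."""
        names = [n for n, _ in self.chromosomes]
        return sorted(names, key=lambda n: (n != UNANCHORED, n))

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        """All genes on one chromosome, sorted by start (whole-genome order)."""
        return sorted(
            (g for g in self.genes if g.chromosome == chromosome),
            key=lambda g: (g.start, g.gene_id),
        )


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive span -> 0-based half-open; the only ±1 in the package."""
    return start - 1, end


def read_fasta(path: str | Path, *, alphabet: frozenset[str] | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Raises :class:`FormatError` on an empty file, a duplicate identifier, or
    (when *alphabet* is given) a residue outside the alphabet.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        if alphabet is not None:
            bad = set(residues) - alphabet
            if bad:
                raise FormatError(
                    f"record {rec.id!r} contains illegal characters {sorted(bad)}"
                )
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _span(feature) -> tuple[int, int]:
    return int(feature.start), int(feature.end)


def read_gff3(path: str | Path) -> AnnotatedGenome:
    """Build an :class:`AnnotatedGenome` from a GFF3 file.

    Minus-strand transcripts get their exons and CDS segments in transcription
    order (descending genomic coordinate).  A transcript whose CDS total is not
    divisible by 3 is kept but flagged (``cds_frame_ok=False``) with a warning;
    an exon/CDS whose Parent is missing raises :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    if "##gff-version 3" not in text.splitlines()[0]:
        raise FormatError(f"{path}: missing ##gff-version 3 pragma")
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    chromosomes: list[tuple[str, int]] = []
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, name, _start, end = line.split()[:4]
            chromosomes.append((name, int(end)))

    known_ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in known_ids:
                raise FormatError(f"feature {f.id!r} names unknown Parent {parent!r}")

    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene", order_by="start"):
        gene = GeneModel(gf.id, gf.seqid, *_span(gf), gf.strand)
        for mf in db.children(gf, featuretype="mRNA", order_by="start"):
            exons = [_span(x) for x in db.children(mf, featuretype="exon", order_by="start")]
            cds = [_span(x) for x in db.children(mf, featuretype="CDS", order_by="start")]
            if gf.strand == "-":
                exons = exons[::-1]
                cds = cds[::-1]
            protein = mf.attributes.get("protein_id", [None])[0] or mf.id
            tx = TranscriptModel(mf.id, exons, cds, protein_id=protein)
            if cds and tx.cds_length % 3 != 0:
                tx.cds_frame_ok = False
                warnings.warn(
                    f"transcript {mf.id}: CDS length {tx.cds_length} not divisible by 3",
                    stacklevel=2,
                )
            gene.transcripts.append(tx)
        if not gene.transcripts:
            raise FormatError(f"gene {gf.id!r} has no mRNA children")
        genes.append(gene)

    if not chromosomes:
        # fall back to observed seqids with max gene end as length
        by_chrom: dict[str, int] = {}
        for g in genes:
            by_chrom[g.chromosome] = max(by_chrom.get(g.chromosome, 0), g.end)
        chromosomes = sorted(by_chrom.items())

    lengths = dict(chromosomes)
    for g in genes:
        if g.chromosome in lengths and g.end > lengths[g.chromosome]:
            raise FormatError(
                f"gene {g.gene_id} extends past chromosome {g.chromosome} length"
            )
    return AnnotatedGenome(chromosomes, genes)


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """Serialize an :class:`AnnotatedGenome` back to GFF3 (gene/mRNA/exon/CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chromosome}\tfamscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for tx in g.transcripts:
                lo = min(s for s, _ in tx.exons)
                hi = max(e for _, e in tx.exons)
                fh.write(
                    f"{g.chromosome}\tfamscan\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={g.gene_id};protein_id={tx.protein_id}\n"
                )
                # file order is genomic (ascending) regardless of strand
                for s, e in sorted(tx.exons):
                    fh.write(
                        f"{g.chromosome}\tfamscan\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={tx.transcript_id}.exon.{s};Parent={tx.transcript_id}\n"
                    )
                for s, e in sorted(tx.cds_segments):
                    fh.write(
                        f"{g.chromosome}\tfamscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={tx.transcript_id}.cds.{s};Parent={tx.transcript_id}\n"
                    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes × conditions numeric TSV (header row, gene ids in column 1).

    Any missing or non-numeric cell raises :class:`FormatError` naming the
    offending row and column — no silent NA propagation.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: empty matrix")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise FormatError(f"{path}: non-numeric or missing cell at ({row!r}, {col!r})")
    return numeric


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree with branch lengths (and internal supports as node names)."""
    for leaf in tree.tips():
        if not leaf.name:
            raise FormatError("tree contains an unlabeled leaf")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
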
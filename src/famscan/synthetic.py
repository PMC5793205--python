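"""Synthetic genomes, proteomes, expression matrices and qPCR tables with
planted ground truth for every downstream analysis stage.

The generator emulates the structure of a real plant proteome + annotation
bundle: loci with 1–3 transcripts, member proteins carrying a complete
conserved domain, decoys with truncated or absent domains, tandem clusters
and cross-chromosome segmental duplicate pairs, subfamily structure for the
phylogeny, tissue-structured FPKM with a sharp unexpressed band, and
replicate Cq tables with a stable reference gene.  Everything is a pure
function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    AnnotatedGenome,
    GeneModel,
    SequenceRecord,
    TranscriptModel,
    UNANCHORED,
)

#: the twelve tissue/organ libraries the expression matrix emulates
DEFAULT_TISSUES = (
    "leaf", "petiole", "stem", "root", "flower", "petal", "sepal",
    "stamen", "stolon", "tuber", "callus", "shoot_apex",
)

SUBFAMILY_LABELS = "ABCDEFGHIJKLMNO"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic family genome.

    Defaults mirror the scale of a mid-size plant transcription-factor
    family: 124 members over 12 chromosomes plus an unanchored scaffold set,
    eight tandem clusters totalling 20 genes, four segmental pairs, a ~60
    residue conserved domain, and 12 expression libraries.
    """

    seed: int = 0
    n_chromosomes: int = 12
    n_members: int = 124
    n_decoys: int = 66
    n_unanchored_members: int = 3
    tandem_cluster_sizes: tuple[int, ...] = (4, 3, 3, 2, 2, 2, 2, 2)
    n_segmental_pairs: int = 4
    n_subfamilies: int = 15
    n_references_per_subfamily: int = 2
    domain_length: int = 60
    mutation_rate_within_pair: float = 0.05
    subfamily_divergence: float = 0.05   # member vs subfamily ancestor, per site
    subfamily_region_length: int = 100   # subfamily-specific conserved region
    seed_alignment_size: int = 20
    seed_alignment_divergence: float = 0.05
    # expression
    n_tissues: int = 12
    baseline_fpkm: float = 10.0
    tissue_effects: float = 2.0          # sd of log2 tissue effect
    noise_sd: float = 0.25               # sd of log2 measurement noise
    expressed_fraction: float = 94 / 124
    # qPCR
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    reference_cq: float = 20.0
    baseline_cq: float = 25.0
    qpcr_noise_sd: float = 0.0
    induction_log2_sd: float = 1.5

    def validate(self) -> None:
        if min(self.n_chromosomes, self.n_members, self.n_decoys) < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.mutation_rate_within_pair < 1:
            raise ValueError("mutation_rate_within_pair must be in [0, 1)")
        planted = sum(self.tandem_cluster_sizes) + 2 * self.n_segmental_pairs
        if planted + self.n_unanchored_members > self.n_members:
            raise ValueError("planted duplicates exceed n_members")
        if any(s < 2 for s in self.tandem_cluster_sizes):
            raise ValueError("tandem clusters need at least 2 genes")
        if self.n_segmental_pairs > 0 and self.n_chromosomes < 2:
            raise ValueError("segmental pairs need at least 2 chromosomes")
        if self.n_subfamilies > len(SUBFAMILY_LABELS):
            raise ValueError(f"at most {len(SUBFAMILY_LABELS)} subfamilies supported")


@dataclass
class SyntheticTruth:
    """Planted ground truth consumed by tests and the acceptance checks."""

    member_gene_ids: set[str] = field(default_factory=set)
    decoy_gene_ids: set[str] = field(default_factory=set)
    tandem_clusters: list[list[str]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str]] = field(default_factory=list)
    subfamily_of: dict[str, str] = field(default_factory=dict)
    expressed_gene_ids: set[str] = field(default_factory=set)
    reference_records: list[SequenceRecord] = field(default_factory=list)
    reference_labels: dict[str, str] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site independently with probability *rate*."""
    out = list(seq)
    hits = np.where(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# genome + proteome


@dataclass
class _Locus:
    kind: str                       # member | decoy
    protein: str
    subfamily: str | None = None
    cluster_idx: int | None = None
    pair_idx: int | None = None
    extra_transcripts: int = 0
    gene_id: str = ""
    intron_count: int | None = None  # fixed layout (shared within a cluster)


def _member_protein(rng, ancestor_domain, ancestor_tag, cfg) -> str:
    n_flank = _random_protein(rng, int(rng.integers(20, 80)))
    c_flank = _random_protein(rng, int(rng.integers(20, 120)))
    domain = _mutate(rng, ancestor_domain, cfg.subfamily_divergence)
    tag = _mutate(rng, ancestor_tag, cfg.subfamily_divergence)
    return n_flank + domain + tag + c_flank


def _split_cds(rng, cds_len: int, n_introns: int) -> list[int]:
    """Segment lengths of the CDS (transcription order), each >= 30 bp."""
    if n_introns == 0:
        return [cds_len]
    for _ in range(200):
        cuts = np.sort(rng.choice(np.arange(30, cds_len - 29), size=n_introns, replace=False))
        bounds = np.concatenate(([0], cuts, [cds_len]))
        lens = np.diff(bounds)
        if (lens >= 30).all():
            return [int(x) for x in lens]
    # fall back to even split
    base = cds_len // (n_introns + 1)
    lens = [base] * n_introns + [cds_len - base * n_introns]
    return lens


def _build_gene(rng, gene_id, chrom, start, locus: _Locus, intron_count=None):
    protein_len = len(locus.protein)
    cds_len = 3 * (protein_len + 1)          # stop codon included
    max_introns = min(7, cds_len // 60 - 1)
    if intron_count is None:
        intron_count = int(rng.integers(0, max(1, max_introns) + 1))
    intron_count = max(0, min(intron_count, max_introns))
    seg_lens = _split_cds(rng, cds_len, intron_count)
    intron_lens = rng.integers(80, 1500, size=intron_count)

    strand = "+" if rng.random() < 0.5 else "-"
    spans = []
    pos = start
    for k, seg in enumerate(seg_lens):
        spans.append((pos, pos + seg - 1))
        pos = pos + seg
        if k < intron_count:
            pos += int(intron_lens[k])
    end = spans[-1][1]
    # transcription order: ascending genomic for +, descending for -
    tx_spans = spans if strand == "+" else spans[::-1]
    rep = TranscriptModel(
        transcript_id=f"{gene_id}.1",
        exons=list(tx_spans),
        cds_segments=list(tx_spans),
        protein_id=f"{gene_id}.1.p",
    )
    gene = GeneModel(gene_id, chrom, start, end, strand, [rep])

    proteins = {rep.protein_id: locus.protein}
    for extra in range(locus.extra_transcripts):
        # non-representative transcript: a strict exon-prefix, shorter CDS
        if len(tx_spans) > 1:
            kept = list(tx_spans[: max(1, len(tx_spans) - 1 - extra)])
        else:
            kept = list(tx_spans)
        total = sum(e - s + 1 for s, e in kept)
        trim = total % 3
        # trim to a codon boundary and make strictly shorter than the rep
        if total - trim >= rep.cds_length:
            trim += 3 * ((total - trim - rep.cds_length) // 3 + 1)
        s, e = kept[-1]
        if strand == "+":
            kept[-1] = (s, e - trim)
        else:
            kept[-1] = (s + trim, e)
        total = sum(e2 - s2 + 1 for s2, e2 in kept)
        if total < 60:
            continue
        tx_id = f"{gene_id}.{extra + 2}"
        tx = TranscriptModel(
            transcript_id=tx_id,
            exons=kept,
            cds_segments=list(kept),
            protein_id=f"{tx_id}.p",
        )
        gene.transcripts.append(tx)
        proteins[tx.protein_id] = locus.protein[: total // 3 - 1] or locus.protein[:1]
    return gene, end, proteins


def generate_family_genome(
    config: GeneratorConfig,
) -> tuple[AnnotatedGenome, list[SequenceRecord], list[SequenceRecord], SyntheticTruth]:
    """Generate (genome, proteome, seed alignment, truth) for one seed.

    Members carry a complete planted domain (a hidden consensus mutated at a
    few percent of sites); partial decoys carry at most half of it and plain
    decoys none.  Tandem clusters are blocks of near-identical paralogs
    spanning well under 100 kb with at most a couple of intervening decoys;
    segmental pairs are high-similarity members on different chromosomes.
    The identification stage must build its profile from the emitted seed
    alignment — the hidden consensus is never exposed.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])

    consensus = _random_protein(rng, cfg.domain_length)
    seed_alignment = [
        SequenceRecord(f"seed{i + 1:02d}", "domain seed", _mutate(rng, consensus, cfg.seed_alignment_divergence))
        for i in range(cfg.seed_alignment_size)
    ]

    # subfamily ancestors: a domain variant plus a subfamily-specific region
    ancestors = []
    for _ in range(cfg.n_subfamilies):
        ancestors.append(
            (_mutate(rng, consensus, 0.02),
             _random_protein(rng, cfg.subfamily_region_length))
        )

    truth = SyntheticTruth()

    # --- compose loci -----------------------------------------------------
    n_cluster_genes = sum(cfg.tandem_cluster_sizes)
    n_independent = cfg.n_members - n_cluster_genes - 2 * cfg.n_segmental_pairs

    cluster_blocks: list[list[_Locus]] = []
    for ci, size in enumerate(cfg.tandem_cluster_sizes):
        sf = int(rng.integers(cfg.n_subfamilies))
        label = SUBFAMILY_LABELS[sf]
        source = _member_protein(rng, *ancestors[sf], cfg)
        intron_seed = int(rng.integers(0, 4))
        block = [_Locus("member", source, label, cluster_idx=ci, intron_count=intron_seed)]
        for _ in range(size - 1):
            block.append(
                _Locus(
                    "member",
                    _mutate(rng, source, cfg.mutation_rate_within_pair),
                    label,
                    cluster_idx=ci,
                    intron_count=intron_seed,
                )
            )
        cluster_blocks.append(block)

    segmental: list[tuple[_Locus, _Locus]] = []
    for pi in range(cfg.n_segmental_pairs):
        sf = int(rng.integers(cfg.n_subfamilies))
        label = SUBFAMILY_LABELS[sf]
        source = _member_protein(rng, *ancestors[sf], cfg)
        a = _Locus("member", source, label, pair_idx=pi)
        b = _Locus(
            "member", _mutate(rng, source, cfg.mutation_rate_within_pair), label, pair_idx=pi
        )
        segmental.append((a, b))

    independents = []
    for k in range(n_independent):
        sf = int(rng.integers(cfg.n_subfamilies))
        locus = _Locus(
            "member",
            _member_protein(rng, *ancestors[sf], cfg),
            SUBFAMILY_LABELS[sf],
        )
        if rng.random() < 0.25:                 # class-iii decoy transcripts
            locus.extra_transcripts = int(rng.integers(1, 3))
        independents.append(locus)

    decoys = []
    half = cfg.domain_length // 2
    for k in range(cfg.n_decoys):
        if k % 2 == 0:  # domain-free decoy
            protein = _random_protein(rng, int(rng.integers(80, 300)))
        else:           # partial-domain decoy: at most half the domain
            protein = (
                _random_protein(rng, int(rng.integers(20, 80)))
                + _mutate(rng, consensus[:half], 0.05)
                + _random_protein(rng, int(rng.integers(20, 120)))
            )
        decoys.append(_Locus("decoy", protein))

    # --- lay the loci onto chromosomes ------------------------------------
    chrom_names = [UNANCHORED] + [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    # items are either single loci or whole tandem blocks (placed contiguously)
    unanchored_items = [[x] for x in independents[: cfg.n_unanchored_members]]
    pool: list[list[_Locus]] = [[x] for x in independents[cfg.n_unanchored_members :]]
    pool += [[x] for x in decoys]
    rng.shuffle(pool)

    per_chrom: dict[str, list[list[_Locus]]] = {name: [] for name in chrom_names}
    per_chrom[UNANCHORED] = unanchored_items
    for i, block in enumerate(cluster_blocks):
        per_chrom[chrom_names[1 + i % cfg.n_chromosomes]].append(block)
    for pi, (a, b) in enumerate(segmental):
        ca = 1 + (2 * pi) % cfg.n_chromosomes
        cb = 1 + (2 * pi + 1 + cfg.n_chromosomes // 2) % cfg.n_chromosomes
        if ca == cb:
            cb = 1 + (cb % cfg.n_chromosomes)
        per_chrom[chrom_names[ca]].append([a])
        per_chrom[chrom_names[cb]].append([b])
    for i, item in enumerate(pool):
        per_chrom[chrom_names[1 + i % cfg.n_chromosomes]].append(item)

    genes: list[GeneModel] = []
    proteome: dict[str, str] = {}
    chromosomes: list[tuple[str, int]] = []
    gene_serial = 0
    cluster_gene_ids: dict[int, list[str]] = {}
    pair_gene_ids: dict[int, list[str]] = {}

    for chrom in chrom_names:
        items = per_chrom[chrom]
        order = rng.permutation(len(items))
        pos = int(rng.integers(50_000, 150_000))
        chrom_end = 0
        for oi in order:
            block = items[oi]
            for bi, locus in enumerate(block):
                gene_serial += 1
                gene_id = f"SYNG{gene_serial:04d}"
                locus.gene_id = gene_id
                gene, end, prots = _build_gene(
                    rng, gene_id, chrom, pos, locus, intron_count=locus.intron_count
                )
                genes.append(gene)
                proteome.update(prots)
                chrom_end = max(chrom_end, end)
                if locus.kind == "member":
                    truth.member_gene_ids.add(gene_id)
                    truth.subfamily_of[gene_id] = locus.subfamily
                    if locus.cluster_idx is not None:
                        cluster_gene_ids.setdefault(locus.cluster_idx, []).append(gene_id)
                    if locus.pair_idx is not None:
                        pair_gene_ids.setdefault(locus.pair_idx, []).append(gene_id)
                else:
                    truth.decoy_gene_ids.add(gene_id)
                if bi < len(block) - 1 and len(block) > 1:
                    # inside a tandem block: tight spacing, occasional decoy
                    gap_start = end + int(rng.integers(2_000, 5_000))
                    if rng.random() < 0.4:
                        # short intervening decoy keeps cluster spans < 100 kb
                        filler = _Locus(
                            "decoy",
                            _random_protein(rng, int(rng.integers(80, 200))),
                            intron_count=int(rng.integers(0, 3)),
                        )
                        gene_serial += 1
                        fid = f"SYNG{gene_serial:04d}"
                        filler.gene_id = fid
                        fgene, fend, fprots = _build_gene(
                            rng, fid, chrom, gap_start, filler,
                            intron_count=filler.intron_count,
                        )
                        genes.append(fgene)
                        proteome.update(fprots)
                        truth.decoy_gene_ids.add(fid)
                        chrom_end = max(chrom_end, fend)
                        pos = fend + int(rng.integers(2_000, 5_000))
                    else:
                        pos = gap_start
                else:
                    pos = end + int(rng.integers(120_000, 220_000))
        chromosomes.append((chrom, max(chrom_end + 100_000, 500_000)))

    for ci in sorted(cluster_gene_ids):
        ids = cluster_gene_ids[ci]
        by_start = {g.gene_id: g.start for g in genes}
        truth.tandem_clusters.append(sorted(ids, key=lambda g: by_start[g]))
    for pi in sorted(pair_gene_ids):
        a, b = pair_gene_ids[pi]
        truth.segmental_pairs.append(tuple(sorted((a, b))))

    # expressed subset (ground truth for the FPKM filter)
    members_sorted = sorted(truth.member_gene_ids)
    n_expressed = int(round(cfg.expressed_fraction * len(members_sorted)))
    expressed = rng.choice(members_sorted, size=n_expressed, replace=False)
    truth.expressed_gene_ids = set(str(g) for g in expressed)

    # reference proteins per subfamily, for subfamily assignment
    for sf in range(cfg.n_subfamilies):
        label = SUBFAMILY_LABELS[sf]
        for r in range(cfg.n_references_per_subfamily):
            rid = f"REF_{label}{r + 1}"
            rec = SequenceRecord(
                rid, f"reference subfamily {label}",
                _member_protein(rng, *ancestors[sf], cfg),
            )
            truth.reference_records.append(rec)
            truth.reference_labels[rid] = label

    proteome_records = [
        SequenceRecord(pid, "", seq) for pid, seq in sorted(proteome.items())
    ]
    genome = AnnotatedGenome(chromosomes, genes)
    return genome, proteome_records, seed_alignment, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression_matrix(
    truth: SyntheticTruth, config: GeneratorConfig
) -> pd.DataFrame:
    """Genes × tissues FPKM with a sharp planted expressed/unexpressed split.

    Expressed genes draw log-normal FPKM around gene- and tissue-specific
    means (guaranteed to reach the conventional FPKM >= 2 threshold in at
    least one tissue); unexpressed genes draw uniformly from [0, 2) in every
    tissue.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    tissues = list(DEFAULT_TISSUES[: cfg.n_tissues])
    while len(tissues) < cfg.n_tissues:
        tissues.append(f"tissue{len(tissues) + 1}")
    genes = sorted(truth.member_gene_ids)
    data = np.empty((len(genes), len(tissues)))
    for gi, gene in enumerate(genes):
        if gene in truth.expressed_gene_ids:
            effects = rng.normal(0.0, cfg.tissue_effects, size=len(tissues))
            means = cfg.baseline_fpkm * 2.0 ** effects
            noise = rng.normal(0.0, cfg.noise_sd, size=len(tissues))
            row = means * 2.0 ** noise
            if row.max() < 2.5:     # keep the planted label sharp
                row[int(np.argmax(row))] = cfg.baseline_fpkm
            data[gi] = row
        else:
            data[gi] = rng.uniform(0.0, 2.0, size=len(tissues))
    return pd.DataFrame(data, index=genes, columns=tissues)


# ---------------------------------------------------------------------------
# qPCR


def generate_qpcr_table(
    genes: list[str],
    conditions: list[str],
    config: GeneratorConfig,
    reference_gene: str = "ef1a",
    planted_folds: dict[tuple[str, str], float] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Replicate Cq table (long format) with planted relative abundances.

    The first condition is the control (planted fold 1).  Per biological
    replicate, ``Cq = baseline_cq - log2(abundance) + noise``; the reference
    gene sits at ``reference_cq`` in every condition (in expectation).
    Returns the table (columns gene, condition, bio_rep, tech_rep, cq) and
    the planted fold per (gene, condition).
    """
    if not conditions:
        raise ValueError("need at least one condition (the control)")
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    control = conditions[0]
    if planted_folds is None:
        planted_folds = {}
        for gene in genes:
            for cond in conditions:
                planted_folds[(gene, cond)] = (
                    1.0 if cond == control
                    else float(2.0 ** rng.normal(0.0, cfg.induction_log2_sd))
                )
    rows = []
    for gene in list(genes) + [reference_gene]:
        for cond in conditions:
            for bio in range(1, cfg.n_bio_reps + 1):
                if gene == reference_gene:
                    cq_bio = cfg.reference_cq
                else:
                    fold = planted_folds[(gene, cond)]
                    cq_bio = cfg.baseline_cq - np.log2(fold)
                cq_bio = cq_bio + rng.normal(0.0, cfg.qpcr_noise_sd)
                for tech in range(1, cfg.n_tech_reps + 1):
                    rows.append((gene, cond, bio, tech, float(cq_bio)))
    table = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "cq"])
    return table, planted_folds
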
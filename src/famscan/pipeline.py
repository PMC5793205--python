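"""End-to-end orchestration: identify -> characterize -> duplications ->
phylogeny/classification -> expression, plus the family-level summary with
paper-style one-decimal percentages.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterize import intron_phases, load_motif_patterns, protein_stats, scan_motifs
from .duplication import call_duplications, classify_duplications
from .expression import (
    cluster_heatmap,
    filter_expressed,
    normalize_matrix,
    relative_expression,
)
from .identify import build_profile, identify_family
from .io import read_fasta, read_gff3, read_matrix_tsv, write_newick
from .phylogeny import assign_subfamilies, bootstrap_supports, progressive_align

log = logging.getLogger("famscan")


def percent(count: int, total: int) -> float:
    """Share as a one-decimal percentage, rounded half away from zero.

    This is the printed-report convention: e.g. 12/124 -> 9.7, 28/124 -> 22.6.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    value = Decimal(100 * count) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    proteome: str
    gff: str
    seed_alignment: str
    fpkm: str | None = None
    cq: str | None = None
    motifs: str | None = None
    reference_fasta: str | None = None
    reference_labels: str | None = None
    prefix: str = "Fam"
    completeness: float = 0.9
    coverage: float = 0.70
    similarity: float = 0.70
    tandem_window_bp: int = 100_000
    max_intervening_genes: int = 5
    fpkm_threshold: float = 2.0
    support_min: float = 50.0
    bootstrap: int = 1000
    seed: int = 0
    qpcr_reference: str = "ef1a"
    qpcr_mode: str = "dct"
    control_condition: str | None = None
    outdir: str = "famscan_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        for name, value in (("completeness", self.completeness),
                            ("coverage", self.coverage),
                            ("similarity", self.similarity)):
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.bootstrap < 0 or self.tandem_window_bp <= 0:
            raise ValueError("bootstrap and tandem window must be positive")
        for label, path in (("proteome", self.proteome), ("gff", self.gff),
                            ("seed_alignment", self.seed_alignment),
                            ("fpkm", self.fpkm), ("cq", self.cq),
                            ("motifs", self.motifs),
                            ("reference_fasta", self.reference_fasta),
                            ("reference_labels", self.reference_labels)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} file not found: {path}")
        if self.qpcr_mode == "ddct" and self.cq and not self.control_condition:
            raise ValueError("ddct mode requires control_condition")


@dataclass
class FamilySummary:
    n_members: int
    per_chromosome: dict[str, int]
    intronless: int
    intronless_pct: float
    one_intron: int
    one_intron_pct: float
    phase_counts: dict[int, int]          # over all introns
    phase_pct: dict[int, float]           # percent of introns
    n_tandem_genes: int
    tandem_pct: float
    n_tandem_clusters: int
    n_segmental_pairs: int
    n_duplicated_genes: int
    duplicated_pct: float
    length_range: tuple[int, str, int, str]       # min, who, max, who
    mw_range: tuple[float, str, float, str]
    pi_range: tuple[float, str, float, str]
    n_expressed: int | None = None
    n_excluded: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_members", self.n_members),
            ("intronless", f"{self.intronless} ({self.intronless_pct}%)"),
            ("one_intron", f"{self.one_intron} ({self.one_intron_pct}%)"),
            ("tandem_genes", f"{self.n_tandem_genes} ({self.tandem_pct}%)"),
            ("tandem_clusters", self.n_tandem_clusters),
            ("segmental_pairs", self.n_segmental_pairs),
            ("duplicated_genes", f"{self.n_duplicated_genes} ({self.duplicated_pct}%)"),
            ("length_range", f"{self.length_range[0]} ({self.length_range[1]}) – "
                             f"{self.length_range[2]} ({self.length_range[3]})"),
            ("mw_range_da", f"{self.mw_range[0]:.1f} ({self.mw_range[1]}) – "
                            f"{self.mw_range[2]:.1f} ({self.mw_range[3]})"),
            ("pi_range", f"{self.pi_range[0]:.2f} ({self.pi_range[1]}) – "
                         f"{self.pi_range[2]:.2f} ({self.pi_range[3]})"),
        ]
        for phase in (0, 1, 2):
            rows.append(
                (f"introns_phase{phase}",
                 f"{self.phase_counts.get(phase, 0)} ({self.phase_pct.get(phase, 0.0)}% of introns)")
            )
        for chrom, n in sorted(self.per_chromosome.items()):
            rows.append((f"members_{chrom}", n))
        if self.n_expressed is not None:
            rows.append(("expressed_genes", self.n_expressed))
            rows.append(("excluded_low_fpkm", self.n_excluded))
        return pd.DataFrame(rows, columns=["statistic", "value"]).set_index("statistic")


def family_summary(members, genome, stats_df, intron_df, clusters, segmental,
                   expressed=None, excluded=None) -> FamilySummary:
    """Aggregate stage outputs into the family-level summary statistics."""
    n = len(members)
    if n == 0:
        raise ValueError("no family members")
    member_names = {m.name for m in members}
    tandem_genes = sorted({name for c in clusters for name in c.members})
    seg_genes = {g for call in segmental for g in (call.gene_a, call.gene_b)}
    if not set(tandem_genes) <= member_names or not seg_genes <= member_names:
        raise ValueError("duplication results reference unknown members")
    duplicated = set(tandem_genes) | seg_genes

    per_chrom: dict[str, int] = {}
    for m in members:
        chrom = genome.gene(m.gene_id).chromosome
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1

    intronless = int((intron_df["intron_count"] == 0).sum())
    one_intron = int((intron_df["intron_count"] == 1).sum())
    phase_counts = {0: 0, 1: 0, 2: 0}
    for phases in intron_df["phases"]:
        for ph in phases:
            phase_counts[ph] += 1
    total_introns = sum(phase_counts.values())
    phase_pct = {
        ph: percent(c, total_introns) if total_introns else 0.0
        for ph, c in phase_counts.items()
    }

    def extreme(col):
        lo, hi = stats_df[col].idxmin(), stats_df[col].idxmax()
        return stats_df.loc[lo, col], lo, stats_df.loc[hi, col], hi

    return FamilySummary(
        n_members=n,
        per_chromosome=per_chrom,
        intronless=intronless,
        intronless_pct=percent(intronless, n),
        one_intron=one_intron,
        one_intron_pct=percent(one_intron, n),
        phase_counts=phase_counts,
        phase_pct=phase_pct,
        n_tandem_genes=len(tandem_genes),
        tandem_pct=percent(len(tandem_genes), n),
        n_tandem_clusters=len(clusters),
        n_segmental_pairs=len(segmental),
        n_duplicated_genes=len(duplicated),
        duplicated_pct=percent(len(duplicated), n),
        length_range=extreme("length"),
        mw_range=extreme("molecular_weight"),
        pi_range=extreme("isoelectric_point"),
        n_expressed=None if expressed is None else len(expressed),
        n_excluded=None if excluded is None else len(excluded),
    )


def run_pipeline(config: PipelineConfig) -> FamilySummary:
    """Run every stage in order and write all artifacts under ``config.outdir``.

    Stage order: identify -> characterize -> duplications -> tree/classify ->
    expression/qPCR -> summary.  Reruns with identical inputs and seed give
    byte-identical outputs.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> FamilySummary:
    log.info("famscan %s seed=%d", __version__, config.seed)
    log.info("thresholds: completeness=%.2f coverage=%.2f similarity=%.2f "
             "tandem_window=%d max_intervening=%d fpkm=%.1f support=%.0f",
             config.completeness, config.coverage, config.similarity,
             config.tandem_window_bp, config.max_intervening_genes,
             config.fpkm_threshold, config.support_min)

    # --- identify ---------------------------------------------------------
    proteome = read_fasta(config.proteome)
    genome = read_gff3(config.gff)
    seed_aln = read_fasta(config.seed_alignment)
    profile = build_profile(seed_aln)
    members = identify_family(
        proteome, genome, profile,
        completeness_min=config.completeness, prefix=config.prefix,
    )
    if not members:
        raise RuntimeError("identification stage accepted no family members")
    log.info("identification: %d members", len(members))
    members_df = pd.DataFrame(
        [
            {
                "name": m.name,
                "gene_id": m.gene_id,
                "transcript_id": m.representative_transcript_id,
                "chromosome": genome.gene(m.gene_id).chromosome,
                "start": genome.gene(m.gene_id).start,
                "end": genome.gene(m.gene_id).end,
                "strand": genome.gene(m.gene_id).strand,
                "score": round(m.hit.score, 3),
                "coverage": round(m.hit.profile_coverage, 4),
            }
            for m in members
        ]
    ).set_index("name")
    members_df.to_csv(outdir / "members.tsv", sep="\t")

    # --- characterize -----------------------------------------------------
    stats_rows, intron_rows = [], []
    patterns = load_motif_patterns(config.motifs) if config.motifs else None
    motif_rows = []
    for m in members:
        st = protein_stats(m.protein.residues)
        stats_rows.append(
            {"name": m.name, "length": st.length,
             "molecular_weight": round(st.molecular_weight, 2),
             "isoelectric_point": round(st.isoelectric_point, 2)}
        )
        gene = genome.gene(m.gene_id)
        tx = next(
            t for t in gene.transcripts
            if t.transcript_id == m.representative_transcript_id
        )
        ann = intron_phases(tx)
        intron_rows.append(
            {"name": m.name, "intron_count": ann.intron_count, "phases": ann.phases}
        )
        if patterns:
            arch = scan_motifs(m.name, m.protein.residues, patterns)
            for motif_id, start in arch.occurrences:
                motif_rows.append({"name": m.name, "motif": motif_id, "start": start})
    stats_df = pd.DataFrame(stats_rows).set_index("name")
    intron_df = pd.DataFrame(intron_rows).set_index("name")
    merged = stats_df.join(intron_df)
    merged["phases"] = merged["phases"].map(lambda p: ",".join(map(str, p)))
    merged.to_csv(outdir / "stats.tsv", sep="\t")
    if motif_rows:
        pd.DataFrame(motif_rows).to_csv(outdir / "motifs.tsv", sep="\t", index=False)

    # --- duplications -----------------------------------------------------
    calls = call_duplications(members, config.coverage, config.similarity)
    clusters, segmental = classify_duplications(
        calls, members, genome,
        window_bp=config.tandem_window_bp,
        max_intervening=config.max_intervening_genes,
    )
    cluster_of = {
        name: f"TC{idx + 1}" for idx, c in enumerate(clusters) for name in c.members
    }
    dup_df = pd.DataFrame(
        [
            {"gene_a": c.gene_a, "gene_b": c.gene_b,
             "coverage": round(c.coverage, 4), "similarity": round(c.similarity, 4),
             "class": c.classification,
             "cluster_id": cluster_of.get(c.gene_a, "")}
            for c in calls
        ],
        columns=["gene_a", "gene_b", "coverage", "similarity", "class", "cluster_id"],
    )
    dup_df.to_csv(outdir / "dup.tsv", sep="\t", index=False)
    log.info("duplication: %d calls, %d tandem clusters, %d segmental pairs",
             len(calls), len(clusters), len(segmental))

    # --- phylogeny / classification ----------------------------------------
    leaves = [m.protein.__class__(m.name, "", m.protein.residues) for m in members]
    ref_labels: dict[str, str] = {}
    if config.reference_fasta and config.reference_labels:
        refs = read_fasta(config.reference_fasta)
        labels_df = pd.read_csv(config.reference_labels, sep="\t")
        ref_labels = dict(zip(labels_df.iloc[:, 0], labels_df.iloc[:, 1]))
        leaves += refs
    alignment = progressive_align(leaves)
    tree = bootstrap_supports(alignment, n_replicates=config.bootstrap, seed=config.seed)
    write_newick(tree.tree, outdir / "tree.nwk")
    log.info("phylogeny: %d leaves, %d/%d bootstrap replicates",
             len(alignment), tree.n_successful, tree.n_bootstrap)
    if ref_labels:
        assignment = assign_subfamilies(tree, ref_labels, config.support_min)
        pd.Series(assignment.assignments, name="group").rename_axis("name").to_csv(
            outdir / "groups.tsv", sep="\t"
        )

    # --- expression --------------------------------------------------------
    expressed = excluded = None
    if config.fpkm:
        fpkm = read_matrix_tsv(config.fpkm)
        name_of = {m.gene_id: m.name for m in members}
        fpkm = fpkm.loc[[g for g in fpkm.index if g in name_of]]
        fpkm.index = [name_of[g] for g in fpkm.index]
        expressed, excluded = filter_expressed(fpkm, config.fpkm_threshold)
        norm = normalize_matrix(fpkm.loc[expressed])
        tree_rows = cluster_heatmap(
            norm.logged, image_path=outdir / "heatmap.png"
        )
        pd.Series(
            {name: ("expressed" if name in set(expressed) else "excluded")
             for name in fpkm.index},
            name="status",
        ).rename_axis("name").to_csv(outdir / "expressed.tsv", sep="\t")
        norm.logged.loc[tree_rows.leaf_order()].to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
        log.info("expression: %d expressed / %d excluded", len(expressed), len(excluded))
    if config.cq:
        cq = pd.read_csv(config.cq, sep="\t")
        rel = relative_expression(
            cq, config.qpcr_reference, config.qpcr_mode, config.control_condition
        )
        pd.DataFrame(
            [
                {"gene": r.gene, "condition": r.condition,
                 "fold": round(r.fold, 4), "sd": round(r.fold_sd, 4),
                 "mode": r.mode}
                for r in rel
            ]
        ).to_csv(outdir / "relexpr.tsv", sep="\t", index=False)

    summary = family_summary(
        members, genome, stats_df, intron_df, clusters, segmental, expressed, excluded
    )
    summary.to_frame().to_csv(outdir / "summary.tsv", sep="\t")
    log.info("summary written: %d members", summary.n_members)
    return summary
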
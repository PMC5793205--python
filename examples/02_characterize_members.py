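"""Physicochemical and gene-structure characterization of family members:
length, molecular weight, isoelectric point, intron counts and phases, and
motif architectures scanned from bracket-consensus patterns.
"""

import famscan as fs

config = fs.GeneratorConfig(seed=7, n_members=20, n_decoys=10, n_chromosomes=4,
                            tandem_cluster_sizes=(3,), n_segmental_pairs=1,
                            n_subfamilies=3, n_unanchored_members=1)
genome, proteome, seed_alignment, truth = fs.generate_family_genome(config)
profile = fs.build_profile(seed_alignment)
members = fs.identify_family(proteome, genome, profile, prefix="Fam")

print("name    length   MW(Da)    pI   introns  phases")
phase_counts = {0: 0, 1: 0, 2: 0}
for m in members[:8]:
    stats = fs.protein_stats(m.protein.residues)
    gene = genome.gene(m.gene_id)
    tx = next(t for t in gene.transcripts
              if t.transcript_id == m.representative_transcript_id)
    ann = fs.intron_phases(tx)
    for p in ann.phases:
        phase_counts[p] += 1
    print(f"{m.name:>6}  {stats.length:>5}  {stats.molecular_weight:>9.1f}  "
          f"{stats.isoelectric_point:5.2f}  {ann.intron_count:>5}    "
          f"{','.join(map(str, ann.phases)) or '-'}")

# a short basic-region consensus: brackets = allowed residues at a position
pattern = fs.parse_bracket_pattern("[PK][PK]KDY[IV]HVRA", motif_id=16)
arch = fs.scan_motifs("demo", "MVPKKDYIHVRAGG", [pattern])
print(f"\nmotif 16 in demo peptide: {arch.occurrences}  (leftmost start, 1-based)")
# The intron phase is the cumulative coding length upstream of each intron
# mod 3 (0 = splice between codons); MW uses average residue masses and pI
# solves net charge = 0 by bisection.
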
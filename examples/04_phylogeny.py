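"""Bootstrapped Neighbor-joining tree from Poisson-corrected distances and
reference-guided subfamily assignment.
"""

import warnings

import famscan as fs

warnings.filterwarnings("ignore")

config = fs.GeneratorConfig(seed=7, n_members=20, n_decoys=10, n_chromosomes=4,
                            tandem_cluster_sizes=(3,), n_segmental_pairs=1,
                            n_subfamilies=3, n_unanchored_members=1)
genome, proteome, seed_alignment, truth = fs.generate_family_genome(config)
profile = fs.build_profile(seed_alignment)
members = fs.identify_family(proteome, genome, profile, prefix="Fam")

leaves = [fs.SequenceRecord(m.name, "", m.protein.residues) for m in members]
leaves += truth.reference_records                     # labelled references
alignment = fs.progressive_align(leaves)
tree = fs.bootstrap_supports(alignment, n_replicates=100, seed=7)
print(f"tree: {len(tree.leaf_names())} leaves, "
      f"{tree.n_successful}/{tree.n_bootstrap} bootstrap replicates used")

assignment = fs.assign_subfamilies(tree, truth.reference_labels, support_min=50)
name_of = {m.gene_id: m.name for m in members}
expected = {name_of[g]: lbl for g, lbl in truth.subfamily_of.items()}
correct = sum(assignment.assignments[q] == expected[q] for q in expected)
print(f"subfamily assignments correct: {correct}/{len(expected)}")
for q in sorted(assignment.assignments)[:6]:
    print(f"  {q}: group {assignment.assignments[q]} (planted {expected[q]})")
# Distances are -ln(1-p) with pairwise deletion; supports are the percentage
# of column-resampled replicates containing each bipartition; each query gets
# the label of its nearest well-supported single-label reference clade.
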
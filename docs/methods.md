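# Methods

This note records the models, conventions and design choices behind
`famscan`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and what the synthetic
tests do and do not demonstrate.

## Coordinate and sequence conventions

All genomic coordinates are 1-based inclusive, matching GFF3; the single
place half-open arithmetic occurs is `famscan.io.to_zero_based`. Transcript
exons and CDS segments are stored in transcription order (descending genomic
coordinate on the minus strand), so downstream code never branches on
strand. Genes that cannot be anchored to a chromosome live on a
pseudo-chromosome `chr00` that sorts before `chr01`, so unanchored members
are named first — mirroring how published family catalogs order unplaced
scaffold genes. The protein alphabet is the 20 standard residues plus `X`;
`X` contributes the mean residue mass and no charge, and scores 0 against
any profile column.

## Family identification

The family is defined operationally by a conserved domain. From a seed
alignment of domain sequences a position-specific log-odds profile is built:
column score for residue *a* is `log2(((n_a + τ·b_a)/(n + τ))/b_a)` with
pseudocount τ (default 1), background *b* (default uniform), and *n* the
non-gap count in the column; columns that are more than half gaps are
dropped. Scanning is a glocal dynamic programme — the profile is aligned end
to end, the target contributes any contiguous substring with free overhangs
— with affine gap costs (open 11, extend 1, in score units). This replaces a
full profile-HMM with explicit insert/delete state probabilities: for a
single-domain completeness decision the log-odds profile is sufficient,
fully reproducible, and exactly testable against brute-force alignment
enumeration (the test suite verifies DP/enumeration equality on random small
profiles).

A hit is reported at score ≥ 0 bits; the decisive filter is **completeness**,
`profile_coverage = matched columns / profile width ≥ 0.9` (configurable).
At domain scale (60 columns) unrelated 200-residue sequences essentially
never reach the reporting threshold (tested at 0/100); with toy 10-column
profiles chance positives do occur, which is why the package is meant to be
used with domain-width seed alignments.

One candidate is evaluated per locus: the representative transcript, defined
as the longest CDS with a lexicographic tie-break. This is the standard
proxy for the "representative model" flag of genome annotation projects,
whose exact internal criteria are not reproducible from the outside.

## Protein statistics

Molecular weight uses average (not monoisotopic) residue masses plus one
water (18.0153 Da), the convention of common proteomics web calculators.
The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14]
using a Bjellqvist-style pKa set (N-term 9.094, C-term 2.869, C 7.555,
D 3.872, E 4.412, H 5.637, K 9.052, R 11.84, Y 10.85; config-exposed).
Because the titration curve is nearly flat far from the ionizable pKa's, the
bisection narrows the pH interval to 1e-7 rather than stopping on a small
charge; the returned pH agrees with a 1e-5-resolution grid scan to ~1e-5 pH
and carries residual charge < 1e-4 by construction.

Intron phase is the cumulative coding length upstream of the intron mod 3:
phase 0 = splicing after a complete codon, 1 = after the first nucleotide,
2 = after the second.

Motif patterns are hard bracket-consensus sets (``[PK]`` = P or K, ``X`` =
any residue), matched exactly with no mismatch allowance, and only the
leftmost occurrence per motif per protein is reported — consensus-set
patterns carry no per-position scores that would justify anything more
permissive, and family surveys report single occurrences per protein.

## Duplication calling

Protein pairs are globally aligned (Needleman–Wunsch/Gotoh affine gaps,
BLOSUM62, gap open 10 / extend 1; a gap of length L costs open + L·extend).
Two strict criteria define a duplicate pair: aligned (residue-to-residue)
positions must exceed 70% of the longer sequence's length, and identical
positions must exceed 70% of aligned columns. "Similarity" is computed as
identity — the strictest reproducible reading — with a config switch for
conservative-substitution groups. Distances for the tandem rule are
start-to-start; "≤ 5 intervening genes" counts genes whose whole span lies
strictly between the pair, over the whole annotation (not family members
only). Tandem pairs merge into clusters by single linkage. Segmental
duplicates are defined *closed-form* as called pairs on different
chromosomes or ≥ 100 kb apart — a deliberate substitute for lookups in
external synteny databases, which are version-dependent and not
reproducible offline; same-chromosome in-window pairs with too many
intervening genes remain "unclassified" rather than being forced into
either category.

## Phylogeny

Distances: per pair, alignment columns gapped in either sequence are removed
(pairwise deletion), p = mismatch fraction of the remainder, and
d = −ln(1−p) (Poisson multiple-hit correction). Pairs with no comparable
columns or p = 1 raise errors naming the pair, since the correction is
undefined there; bootstrap replicates hitting such pairs are skipped and
excluded from the support denominator.

Tree building is canonical Saitou–Nei NJ on the Q criterion with the
standard branch-length formulas. Two numerical conventions make it
deterministic and order-independent: co-minimal Q pairs are joined by the
lexicographically smallest pair of subtree-minimum leaf labels, and negative
branch lengths (which NJ can produce on noisy matrices) are clamped to zero
with a warning. NJ is exact on additive matrices; the tests verify topology
and path-length recovery to 1e-9 on random 4–8 leaf trees, with a full
topology-enumeration + least-squares oracle at 5 leaves, and cross-check
against an independent NJ implementation.

Bootstrap supports resample alignment columns with replacement, rebuild the
matrix and tree, and report the percentage of successful replicates
containing each internal-edge bipartition; supports annotate the full-data
tree (the display convention of standard phylogenetics GUIs), not a
consensus tree.

Subfamily assignment walks outward from each query leaf: candidate edges
need support ≥ 50 (pendant edges count as fully supported — a leaf is a
trivially certain bipartition) and a far side whose references carry exactly
one label; candidates are ranked by patristic distance from the query to the
edge's near end. Ranking by branch length rather than topological hop count
matters: an edge subtending a *foreign* subfamily's entire clade is pure and
can be few hops away, but it is never nearer in path length than the query's
own clade when the tree separates subfamilies at all.

Multiple sequence alignment itself is not this package's contribution: the
pipeline accepts any precomputed alignment, and the built-in
`progressive_align` (NJ guide tree from pairwise global-alignment identity,
profile–profile Needleman–Wunsch with expected BLOSUM62 scores and linear
gap cost) exists to make the synthetic end-to-end path self-contained. It is
adequate for well-separated synthetic families and is not a general MSA
tool; for production data use a dedicated aligner and feed the result in.

## Expression and qPCR

"Equalized" FPKM divides every cell by the single grand mean of the matrix
(read literally from the normalization wording of family surveys; a per-gene
switch exists), making the normalized views scale-invariant. log2 uses
pseudocount 0.01, small enough to preserve ordering among expressed values
while keeping zeros finite. The low-expression filter excludes a gene iff
FPKM < 2 in *every* condition — a boundary value of exactly 2.0 anywhere
keeps the gene. Row clustering is average linkage on Euclidean distances of
the logged values (metric config-exposed, correlation available; no row
scaling by default), verified against a naive O(n³) re-agglomeration.

qPCR: technical replicates collapse to one Cq per biological replicate by
mean, then ΔCT = Cq(target) − Cq(reference) per biological replicate; 2^−ΔCT
gives tissue profiles, and ΔΔCT subtracts the mean control ΔCT so the
control's fold is 1 by construction in the noise-free case. Mean ± sd over
biological replicates is reported. Amplification-efficiency correction is
out of scope.

## Summary report

Percentages in the family summary are one decimal, rounded half away from
zero — the convention that reproduces every ratio printed in published
family surveys (e.g. 12/124 → 9.7%, 28/124 → 22.6%). Intron-phase
percentages are per intron; all other percentages are per member. The
pipeline always recomputes every stage rather than caching on input hashes:
desk-scale runs finish in seconds and recomputation removes a class of
stale-cache bugs.

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (config, seed) — identical inputs give
byte-identical FASTA/GFF3/TSV output (integer-state PCG64 generator). Its
defaults mirror the scale of a mid-size plant TF family survey: 124 members
on 12 chromosomes plus 3 unanchored genes, ~70 decoys (the surplus a
first-pass domain scan typically yields before completeness filtering),
eight tandem clusters totalling 20 genes, four segmental pairs, a 60-residue
domain, 12 tissue libraries, and 94/124 genes expressed. Test and acceptance
runs use a scaled-down configuration (30 members, 14 decoys, 6 chromosomes,
clusters of 4+2, 2 segmental pairs, 4 subfamilies) chosen as the smallest
layout that still exercises every rule — multi-gene clusters with
intervening decoys, cross-chromosome pairs, unanchored naming.

Member proteins are member-specific random flanks around a shared mutated
domain copy (≤ 10% divergence from a hidden consensus) plus a
subfamily-specific conserved region (100 residues, ~5% within-subfamily
divergence). This geometry makes the three decision boundaries sharp by
construction: within-subfamily identity (~50%) sits well below the 70%
duplication criterion, planted duplicate pairs (95% identity) sit well
above it, and partial decoys carry ≤ half the domain, well below the 90%
completeness bar. The identification profile is built from an emitted seed
alignment of 20 mutated domain copies — never from the hidden consensus — so
profile construction is exercised honestly. Unexpressed genes draw FPKM
uniformly from [0, 2) while expressed genes are guaranteed to reach the
threshold somewhere, making the expression filter's truth exact.

Consequently, green tests demonstrate *internal correctness* — every rule
implemented as stated, exact recovery when the data satisfy the generator's
separations — not performance on real proteomes, where domain divergence,
fragmented gene models, alignment errors and borderline paralogs blur every
one of these margins. The generator also simplifies biology deliberately:
no codon-usage realism, no UTRs (exons coincide with CDS segments), no
birth–death paralog evolution, no read-level RNA-seq noise.

## Problem sizes

Default test/acceptance problem sizes: 30-member genomes; 100 random 4–8
leaf trees for the NJ oracle; 200 length-≤8 pairs for the alignment oracle;
50 random peptides for the pI solver; 100 bootstrap replicates (a
scaled-down stand-in for the 1000 replicates a production run would use, and
the pipeline default). With these sizes the full test suite runs in well
under a minute of compute-heavy work and the acceptance script in ~10 s.

## Known limitations

- The glocal scanner is not a Plan-7 profile HMM: no position-specific
  transition probabilities, no E-value calibration. Scores are comparable
  within one profile only.
- Segmental-duplication calls are a closed rule, not synteny evidence;
  they will overcall segmental pairs relative to collinearity-based methods.
- `progressive_align` degrades on divergent or low-complexity inputs;
  the tree and classification stages are only as good as the alignment fed
  to them.
- The expression module assumes FPKM-like non-negative intensities; it does
  not model library-size normalization or differential-expression testing.
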
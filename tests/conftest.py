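import warnings

import pytest

import famscan as fs


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down family genome: 30 members (two tandem clusters of 4 and 2,
    two segmental pairs, 2 unanchored), 14 decoys, 4 subfamilies."""
    return fs.GeneratorConfig(
        seed=1,
        n_members=30,
        n_decoys=14,
        n_chromosomes=6,
        tandem_cluster_sizes=(4, 2),
        n_segmental_pairs=2,
        n_subfamilies=4,
        n_unanchored_members=2,
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    """(genome, proteome, seed_alignment, truth) for the small config."""
    return fs.generate_family_genome(small_config)


@pytest.fixture(scope="session")
def profile(bundle):
    return fs.build_profile(bundle[2])


@pytest.fixture(scope="session")
def members(bundle, profile):
    genome, proteome, _, _ = bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fs.identify_family(proteome, genome, profile, prefix="Syn")


@pytest.fixture(scope="session")
def bundle_files(tmp_path_factory, bundle, small_config):
    """The synthetic bundle written to disk as FASTA/GFF3/TSV."""
    genome, proteome, seed_aln, truth = bundle
    root = tmp_path_factory.mktemp("bundle")
    fs.write_fasta(proteome, root / "proteome.fasta")
    fs.write_fasta(seed_aln, root / "seed_alignment.fasta")
    fs.write_gff3(genome, root / "annotation.gff3")
    fpkm = fs.generate_expression_matrix(truth, small_config)
    fs.write_matrix_tsv(fpkm, root / "fpkm.tsv")
    fs.write_fasta(truth.reference_records, root / "references.fasta")
    with open(root / "reference_labels.tsv", "w") as fh:
        fh.write("name\tgroup\n")
        for name, label in truth.reference_labels.items():
            fh.write(f"{name}\t{label}\n")
    return root
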
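import pytest

from orfatlas import fixtures, pipeline


@pytest.fixture(scope="session")
def locus7(tmp_path_factory):
    """Seed-7 synthetic locus set with planted ground truth."""
    out = tmp_path_factory.mktemp("locus7")
    return fixtures.generate_locus_set(7, out_dir=out)


@pytest.fixture(scope="session")
def catalog7(locus7):
    """Catalog built end-to-end from the seed-7 locus set files."""
    return pipeline.build_catalog_from_files(
        locus7.genome_fasta,
        [
            (locus7.gtf_path, "gtf", "annotation_a"),
            (locus7.gff3_path, "gff3", "annotation_b"),
        ],
        locus7.known_fastas,
    )


@pytest.fixture(scope="session")
def genome7(locus7):
    from orfatlas.annotation_io import load_genome

    return load_genome(locus7.genome_fasta)


@pytest.fixture(scope="session")
def proteomes10(tmp_path_factory):
    """Three species at 10 % divergence with a planted duplication."""
    out = tmp_path_factory.mktemp("proteomes")
    return fixtures.generate_proteomes(
        11, n_species=3, divergence=0.1, out_dir=out)


@pytest.fixture(scope="session")
def evidence7(tmp_path_factory, catalog7, locus7):
    out = tmp_path_factory.mktemp("evidence7")
    fx = fixtures.generate_evidence_tables(7, catalog7.entries, locus7.truth, out)
    report = pipeline.run_evidence(
        catalog7.entries, [fx.peptide_path], [fx.riboseq_path])
    return fx, report
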
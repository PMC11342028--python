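import json

import pytest

from varprimer import reference
from varprimer.synthetic import default_manifest, generate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Standard synthetic fixture (seed 1), generated once per session."""
    out = tmp_path_factory.mktemp("fixture")
    files = generate(default_manifest(1), out)
    return files


@pytest.fixture(scope="session")
def manifest_doc(fixture_dir):
    with open(fixture_dir.manifest) as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return reference.read_genome(fixture_dir.fasta)


@pytest.fixture(scope="session")
def transcript_g1(fixture_dir, genome):
    """3-exon + strand transcript, exon lengths 120/80/200."""
    return reference.load_transcript(fixture_dir.gff3, genome, "G1-RA")


@pytest.fixture(scope="session")
def transcript_g2(fixture_dir, genome):
    """4-exon - strand transcript."""
    return reference.load_transcript(fixture_dir.gff3, genome, "G2-RA")


@pytest.fixture(scope="session")
def template_g1(genome, transcript_g1):
    return reference.extract_template(None, "cDNA", genome, transcript_g1)


@pytest.fixture(scope="session")
def template_g2(genome, transcript_g2):
    return reference.extract_template(None, "cDNA", genome, transcript_g2)


@pytest.fixture(scope="session")
def variants(fixture_dir):
    from varprimer.variation import VariantTable

    return VariantTable.from_vcf(fixture_dir.vcf)


@pytest.fixture(scope="session")
def metadata(fixture_dir):
    import pandas as pd

    return pd.read_csv(fixture_dir.metadata, sep="\t", dtype=str)
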
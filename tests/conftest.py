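from pathlib import Path

import pytest

from apobecscan import GenomeSequence, read_variants

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    return GenomeSequence.from_fasta(DATA / "toy_ams.fa")


@pytest.fixture(scope="session")
def toy_seq(toy_genome) -> str:
    return toy_genome.contigs["toy"]


@pytest.fixture(scope="session")
def ams_records():
    return read_variants(DATA / "toy_ams.vcf")


@pytest.fixture(scope="session")
def catalog_records():
    return read_variants(DATA / "toy_catalog.vcf")
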
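import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from neoscan.models import MissenseVariant, ProteinRecord
from neoscan.simulate import (
    H3_1_CONTEXT,
    H3_3_CONTEXT,
    KRAS_CONTEXT,
    make_bundle,
    write_bundle,
)


@pytest.fixture(scope="session")
def kras_protein():
    return ProteinRecord("KRAS_P", "KRAS", KRAS_CONTEXT, mrna_accession="KRAS_T")


@pytest.fixture(scope="session")
def h31_protein():
    return ProteinRecord("H31_P", "HIST1H3B", H3_1_CONTEXT, mrna_accession="H31_T")


@pytest.fixture(scope="session")
def h33_protein():
    return ProteinRecord("H33_P", "H3F3A", H3_3_CONTEXT, mrna_accession="H33_T")


@pytest.fixture(scope="session")
def kras_g13d():
    return MissenseVariant(
        sample="SJSMP001",
        chrom="chr_KRAS",
        pos=1,
        ref_allele="G",
        mut_allele="A",
        gene="KRAS",
        mrna_accession="KRAS_T",
        aa_ref="G",
        aa_pos=13,
        aa_mut="D",
    )


@pytest.fixture(scope="session")
def bundle():
    return make_bundle(seed=20170831)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, d)
    return paths
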
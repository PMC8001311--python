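import pytest

from utcedit.pileup_variants import ConversionType
from utcedit.synthetic_data import EditSpec, SynthConfig, simulate_reference


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A compact two-sample genome with planted edits and SNPs, no errors."""
    plan = (
        EditSpec(0, "3'UTR", 10, ConversionType.U_TO_C, (0.5, 0.3)),
        EditSpec(1, "5'UTR", 25, ConversionType.U_TO_C, (0.773, 0.6574)),
        EditSpec(2, "CDS", 40, ConversionType.C_TO_U, (0.4, 0.0)),
        EditSpec(3, "3'UTR", 5, ConversionType.U_TO_C, (0.0, 0.25)),
    )
    return SynthConfig(
        seed=7,
        n_genes=6,
        gene_length=300,
        utr5_len=60,
        utr3_len=80,
        intergenic_len=100,
        coverage=40.0,
        error_rate=0.0,
        n_snp_sites=4,
        editing_plan=plan,
        read_length=80,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_reference(small_config)
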
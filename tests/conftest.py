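import numpy as np
import pytest

from tipnpred.synthetic_cohort import SimulationConfig, simulate_cohort

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=CADD,Number=1,Type=Float,Description="Deleteriousness score">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAM1\tSAM2\tSAM3
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    """Three samples, five sites covering the parser's corner cases."""
    rows = [
        "chr1\t100\trs1\tA\tG\t50\tPASS\tDP=90\tGT\t0/0\t0/1\t1/1",
        "chr1\t200\trs2\tC\tA,T\t50\tPASS\tDP=90\tGT\t0/0\t0/1\t1/2",
        "chr1\t300\trs3\tG\tT\t50\tPASS\tDP=90\tGT\t./.\t0/1\t0/0",
        "chr1\t400\trs4\tT\tC\t50\tLowQual\tDP=90\tGT\t0/0\t0/0\t0/1",
        "chr1\t500\t.\tA\tC\t50\tPASS\tDP=9;CADD=21.5\tGT\t0/1\t0/0\t0/0",
    ]
    path = tmp_path / "tiny.vcf"
    path.write_text(VCF_HEADER + "\n".join(rows) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def small_cohort():
    """400 samples x 1500 variants with planted effects; shared across tests."""
    return simulate_cohort(
        SimulationConfig(n_samples=400, n_variants=1500, seed=42, causal_beta=1.2)
    )


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic or covariate effects: outcomes independent of genotypes."""
    return simulate_cohort(
        SimulationConfig(n_samples=400, n_variants=1000, seed=7, n_causal_per_symptom=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
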
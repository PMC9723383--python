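
import numpy as np
import pytest

from tlsub.synthetic_data import SimulationConfig, simulate_feature_dataset, write_toy_vcf

# A small hand-written VCF exercising the parser's dialect handling:
# INFO flags, comma pairs, missing fields, a phased genotype, a missing QUAL.
TOY_VCF = """\
##fileformat=VCFv4.1
##contig=<ID=chr1,length=1000000>
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="CI around POS">
##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=QR,Number=1,Type=Float,Description="Ref quality sum">
##FORMAT=<ID=QA,Number=1,Type=Float,Description="Alt quality sum">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
chr1\t1000\tv1\tN\t<DEL>\t50\t.\tIMPRECISE;CIPOS=-10,10;PE=7;DP=100\tGT:QR:QA\t0/1:70:30
chr1\t5000\tv2\tA\tT\t.\t.\tDP=80\tGT:QR:QA\t1|1:0:0
chr1\t9000\tv3\tN\t<INS>\t12\t.\tPE=2;DP=60\tGT:QR:QA\t./.:55:5
"""


@pytest.fixture
def toy_vcf_path(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture
def small_config():
    """2 replicates x 50 calls at 20% proportion: fast but non-trivial."""
    return SimulationConfig(
        proportion=0.20, n_variants_per_replicate=50, n_replicates=2, seed=7
    )


@pytest.fixture
def small_dataset(small_config):
    return simulate_feature_dataset(small_config)


@pytest.fixture
def generated_vcf(tmp_path, small_dataset):
    """A synthetic dataset materialised as VCF + truth intervals."""
    vcf_path, truth_path = write_toy_vcf(small_dataset, tmp_path / "sim.vcf")
    return small_dataset, vcf_path, truth_path


def make_dataset(proportion, seed, n_variants=100, n_replicates=2, **kw):
    cfg = SimulationConfig(
        proportion=proportion,
        n_variants_per_replicate=n_variants,
        n_replicates=n_replicates,
        seed=seed,
        **kw,
    )
    return simulate_feature_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
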
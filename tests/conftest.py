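import numpy as np
import pytest

from gbsimpute.vcf_io import ReadCountMatrix, Site


def make_matrix(ref, alt, samples=None, sites=None) -> ReadCountMatrix:
    """ReadCountMatrix from count arrays with auto-generated labels."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n_samples, n_sites = ref.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if sites is None:
        sites = [Site(f"v{j}", "1", j + 1, "A", "C") for j in range(n_sites)]
    return ReadCountMatrix(samples, sites, ref, alt)


def matrix_from_genotypes(genotypes, depth=40) -> ReadCountMatrix:
    """Noise-free high-depth counts encoding the given genotype matrix."""
    g = np.asarray(genotypes)
    alt = np.where(g == 2, depth, np.where(g == 1, depth // 2, 0))
    ref = depth - alt
    return make_matrix(ref, alt)


@pytest.fixture
def tiny_vcf(tmp_path):
    """Hand-written 2-sample VCF: 4 biallelic SNPs plus one triallelic."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1
1\t100\tv0\tA\tC\t.\t.\t.\tGT:AD\t0/0:3,1\t1/1:0,9
1\t200\tv1\tG\tT\t.\t.\t.\tGT:AD\t0/1:5,5\t./.:.
1\t300\tv2\tA\tG,T\t.\t.\t.\tGT:AD\t0/0:4,1,0\t0/0:2,0,0
1\t400\tv3\tC\tT\t.\t.\t.\tGT:AD\t./.\t0/0:12,0
1\t500\tv4\tT\tA\t.\t.\t.\tGT:AD\t0/1:7,6\t0/0:30,0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
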
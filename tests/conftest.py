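import numpy as np
import pytest

from woodpop.variants import GenotypeMatrix


def make_gm(genotypes, chrom=None, pos=None, dp=None, sample_ids=None,
            contig_lengths=None):
    """Build a GenotypeMatrix from a plain genotype array with defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_variants = g.shape
    if chrom is None:
        chrom = np.array(["chr1"] * n_variants, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    if pos is None:
        pos = np.zeros(n_variants, dtype=np.int64)
        for c in np.unique(chrom):
            m = chrom == c
            pos[m] = np.arange(1, m.sum() + 1)
    if dp is None:
        dp = np.full(n_variants, 30.0)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        genotypes=g, chrom=chrom, pos=np.asarray(pos, dtype=np.int64),
        dp=np.asarray(dp, dtype=np.float64), sample_ids=sample_ids,
        contig_lengths=contig_lengths or {},
    )


@pytest.fixture(scope="session")
def sim_vcf(tmp_path_factory):
    """A small simulated VCF (4 diploids, 6 loci) plus its haplotype truth."""
    from woodpop import simdata as sd

    spec = sd.SimulationSpec(n_diploids=4, theta_per_locus=3.0, n_loci=6,
                             seed=17)
    haps = sd.simulate_loci(spec)
    path = tmp_path_factory.mktemp("vcf") / "sim.vcf"
    sd.write_vcf(haps, str(path),
                 chrom_labels={"chrZ": [0], "chr1": [1, 2, 3, 4, 5]},
                 seed=17)
    return str(path), haps
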
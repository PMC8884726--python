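import numpy as np
import pandas as pd
import pytest

from asemap import haplotypes as hp
from asemap.sim import CrossConfig, simulate_incross


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sat_experiment():
    """A compact SAT-style wild-type incross shared across test modules."""
    cfg = CrossConfig.sat_cross(seed=42, n_chromosomes=6, n_genes=600)
    return simulate_incross(cfg, include_pools=False)


@pytest.fixture(scope="session")
def sat_haplotypes(sat_experiment):
    """Haplotype map, parental windows and informative regions for the SAT cross."""
    exp = sat_experiment
    cfg = exp.config
    snps = exp.snp_table[["chrom", "pos", "alt_strain"]]
    pw = hp.parental_window_genotypes(exp.parent_snp_genotypes, snps)
    lengths = {c: cfg.chrom_length for c in cfg.chrom_names()}
    hap_map = hp.build_haplotype_map(
        exp.embryo_snp_calls, snps, parental_windows=pw, chrom_lengths=lengths
    )
    regions = hp.define_informative_regions(pw, hap_map)
    return pw, hap_map, regions


@pytest.fixture(scope="session")
def mapping_experiment():
    """A small pooled mutant-mapping cross with pooled SNP sites."""
    cfg = CrossConfig(
        n_embryos=120, n_chromosomes=3, n_genes=400, n_snps_per_chrom=400,
        causal_locus=(0, 12_500_000), seed=7,
    )
    return simulate_incross(cfg)


def nb_counts(mean, dispersion, size, rng):
    """Reference NB sampler (gamma-Poisson) used to build test matrices."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    return rng.poisson(lam)


@pytest.fixture()
def nb_sampler():
    return nb_counts
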
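"""Shared fixtures: small simulated populations and handmade panels."""

import numpy as np
import pandas as pd
import pytest

from awmnet import simpop
from awmnet.core import GenotypeMatrix


def make_genotypes(dosages, chrom=None, bp=None, samples=None) -> GenotypeMatrix:
    """GenotypeMatrix from a raw array with an auto-generated map."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = ["1"] * m if chrom is None else list(chrom)
    bp = np.arange(1, m + 1) * 1000 if bp is None else np.asarray(bp)
    samples = [f"a{i}" for i in range(n)] if samples is None else samples
    snp_map = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": chrom, "bp": bp}
    )
    return GenotypeMatrix(dosages, samples, snp_map)


def hwe_panel(rng, n_animals, n_snps, p=None) -> GenotypeMatrix:
    """Random Hardy-Weinberg panel (no LD, no missing)."""
    if p is None:
        p = rng.uniform(0.1, 0.5, n_snps)
    dos = rng.binomial(2, p, size=(n_animals, n_snps)).astype(float)
    return make_genotypes(dos)


@pytest.fixture(scope="session")
def small_pop():
    """10-sire x 20-sib population with moderate LD; shared across tests."""
    spec = simpop.PopulationSpec(
        n_sires=10,
        sibs_per_sire=[20] * 10,
        n_snps=800,
        n_chromosomes=2,
        chrom_length_bp=8_000_000,
        founder_pool_size=300,
        ld_decay_rate=1e-6,
        shared_dam_prob=0.05,
        seed=11,
    )
    ped = simpop.simulate_pedigree(spec)
    geno = simpop.simulate_genotypes(ped, spec)
    return spec, ped, geno


@pytest.fixture(scope="session")
def small_pop_pheno(small_pop):
    spec, ped, geno = small_pop
    traits = [
        simpop.TraitSpec("T1", 0.4, 100.0, 10.0, n_qtl=20, cg_effect_sd=2.0),
        simpop.TraitSpec("T2", 0.2, 50.0, 5.0, n_qtl=20, cg_effect_sd=1.0),
    ]
    pheno, truth = simpop.simulate_phenotypes(geno, ped, traits, seed=7)
    return spec, ped, geno, pheno, truth
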
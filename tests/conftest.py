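import numpy as np
import pandas as pd
import pytest

from gspanel.genio import GenotypeMatrix
from gspanel.simdata import SimConfig, simulate_genotypes, simulate_trait


def make_geno(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array with stub metadata."""
    d = np.asarray(dosages)
    n, m = d.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    pos = pos if pos is not None else list(range(1, m + 1))
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(d, [f"s{i}" for i in range(n)], variants)


@pytest.fixture(scope="session")
def sim_population():
    """Mid-sized unrelated population with a 50-QTL trait (shared, read-only)."""
    cfg = SimConfig(
        n_individuals=400,
        n_chromosomes=4,
        snps_per_chrom=250,
        n_families=0,
        n_qtl=50,
        h2=0.4,
        ld_rho=0.5,
        seed=11,
    )
    geno = simulate_genotypes(cfg)
    phenos, truth = simulate_trait(geno, cfg)
    return cfg, geno, phenos, truth
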
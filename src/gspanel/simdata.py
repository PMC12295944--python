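"""Synthetic genotypes and additive traits for genomic-prediction experiments.

The generator emulates the statistical structure of a farmed sturgeon
breeding population: a single generation of full-sib families, biallelic
SNPs with a configurable MAF spectrum, block-wise linkage disequilibrium,
and additive quantitative traits (default scale matches caviar yield:
mean 0.193, CV ~29.4%).

LD model
--------
Haplotypes are built per chromosome with a first-order copying chain: each
locus either re-uses the latent uniform draw of the previous locus (with
probability ``ld_rho``) or draws a fresh one, and the allele is the
indicator ``u < p_j``.  Marginal allele frequencies are exact and adjacent
dosage r2 rises monotonically with ``ld_rho``; at ``ld_rho = 0`` loci are
independent.  This is deliberately not a coalescent model — it produces
tunable local LD cheaply, which is all the downstream analyses require.

Family structure: ``n_families`` random parent pairs are simulated from the
haplotype chain and each offspring receives one recombinant gamete per
parent (per-interval switch probability 0.01), so offspring dosages are
Mendelian-consistent with their parents at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, ConfigError, GenotypeMatrix

#: Probability of switching parental haplotype between adjacent loci when
#: forming a gamete.  Fixed: family LD decay is not a study variable here.
GAMETE_SWITCH_PROB = 0.01


@dataclass
class SimConfig:
    """Configuration for genotype and trait simulation.

    Defaults mirror the study population this package targets: 971
    individuals from 192 full-sib families, and a trait on the caviar-yield
    scale.  ``h2`` defaults to 0.3 (a free parameter — field heritabilities
    for these traits are not established).
    """

    n_individuals: int = 971
    n_chromosomes: int = 10
    snps_per_chrom: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.7
    n_families: int = 192
    n_qtl: int = 100
    h2: float = 0.3
    trait_mean: float = 0.193
    trait_cv: float = 29.414
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range {self.maf_range} not within (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho {self.ld_rho} not in [0, 1)")
        if not (0.0 <= self.h2 <= 1.0):
            raise ConfigError(f"h2 {self.h2} not in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate {self.missing_rate} not in [0, 1)")
        for name in ("n_individuals", "n_chromosomes", "snps_per_chrom"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_families < 0 or self.n_qtl < 0:
            raise ConfigError("n_families and n_qtl must be >= 0")
        if self.n_qtl > self.n_chromosomes * self.snps_per_chrom:
            raise ConfigError("n_qtl exceeds total SNP count")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chrom


@dataclass
class TruthRecord:
    """Ground truth from a trait simulation, for parameter-recovery tests."""

    qtl_ids: list[str]
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray  # aligned to sample order, deviations
    realized_h2: float


def _haplotype_chain(rng: np.random.Generator, n_hap: int, p: np.ndarray, rho: float) -> np.ndarray:
    """First-order copying chain over one chromosome.

    Latent uniforms: u_0 fresh; u_j = u_{j-1} with prob rho, else fresh.
    Allele_j = (u_j < p_j).  Returns (n_hap, m) int8 alleles.
    """
    m = p.size
    fresh = rng.random((n_hap, m))
    copy = rng.random((n_hap, m)) < rho
    u = fresh[:, 0].copy()
    out = np.empty((n_hap, m), dtype=np.int8)
    out[:, 0] = u < p[0]
    for j in range(1, m):
        u = np.where(copy[:, j], u, fresh[:, j])
        out[:, j] = u < p[j]
    return out


def _gamete(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray) -> np.ndarray:
    """Recombinant gamete from a parent's two haplotypes (Markov switching)."""
    m = hap_a.size
    switch = rng.random(m - 1) < GAMETE_SWITCH_PROB
    which = np.empty(m, dtype=bool)
    which[0] = rng.random() < 0.5
    which[1:] = np.logical_xor.accumulate(switch) ^ which[0]
    return np.where(which, hap_a, hap_b)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Simulate an n x m dosage matrix with LD and optional family structure.

    Deterministic given ``cfg.seed`` (bit-identical dosages).  Missing
    genotypes (sentinel) are masked in at rate ``cfg.missing_rate`` after
    the population is formed.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m_per = cfg.n_individuals, cfg.snps_per_chrom
    lo, hi = cfg.maf_range

    chrom_blocks: list[np.ndarray] = []
    records: list[tuple] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        maf = rng.uniform(lo, hi, size=m_per)
        # random choice of which allele is minor, so ALT freq spans (0, 1)
        flip = rng.random(m_per) < 0.5
        p = np.where(flip, 1.0 - maf, maf)

        if cfg.n_families > 0:
            n_parents = 2 * cfg.n_families
            parent_haps = _haplotype_chain(rng, 2 * n_parents, p, cfg.ld_rho)
            sire = parent_haps[0::4], parent_haps[1::4]
            dam = parent_haps[2::4], parent_haps[3::4]
            # family sizes as even as possible
            base, extra = divmod(n, cfg.n_families)
            doses = np.empty((n, m_per), dtype=np.int8)
            i = 0
            for f in range(cfg.n_families):
                size = base + (1 if f < extra else 0)
                for _ in range(size):
                    g1 = _gamete(rng, sire[0][f], sire[1][f])
                    g2 = _gamete(rng, dam[0][f], dam[1][f])
                    doses[i] = g1 + g2
                    i += 1
            chrom_blocks.append(doses)
        else:
            haps = _haplotype_chain(rng, 2 * n, p, cfg.ld_rho)
            chrom_blocks.append((haps[0::2] + haps[1::2]).astype(np.int8))

        for j in range(m_per):
            pos = (j + 1) * 1000  # 1 kb spacing
            records.append((chrom, pos, f"{chrom}_snp{j + 1}", "A", "G"))

    dosages = np.concatenate(chrom_blocks, axis=1)
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, np.int8(MISSING), dosages)

    if cfg.n_families > 0:
        base, extra = divmod(n, cfg.n_families)
        sample_ids = []
        for f in range(cfg.n_families):
            size = base + (1 if f < extra else 0)
            for k in range(size):
                sample_ids.append(f"fam{f + 1:03d}_ind{len(sample_ids) + 1:04d}")
    else:
        sample_ids = [f"ind{i + 1:04d}" for i in range(n)]
    variants = pd.DataFrame(records, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(dosages, sample_ids, variants)


def simulate_trait(
    geno: GenotypeMatrix, cfg: SimConfig, trait: str = "trait"
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate an additive trait on ``geno`` and return phenotypes + truth.

    ``cfg.n_qtl`` variants are drawn uniformly (seeded by ``cfg.seed``),
    effects are standard normal, and genetic and residual variances are
    scaled so the sample-level heritability equals ``cfg.h2`` before an
    affine map to ``trait_mean`` / ``trait_cv`` (CV in percent).  True
    breeding values are returned on the phenotype scale, as deviations.
    """
    if cfg.n_qtl > geno.n_variants:
        raise ConfigError("n_qtl exceeds available variants")
    rng = np.random.default_rng((cfg.seed * 1_000_003 + 17) % 2**31)
    n = geno.n_samples

    d = geno.dosages.astype(float)
    miss = geno.missing_mask()
    if miss.any():  # TBV uses observed-mean-filled dosages
        n_obs = (~miss).sum(axis=0)
        means = np.where(miss, 0.0, d).sum(axis=0) / np.maximum(n_obs, 1)
        d = np.where(miss, means[None, :], d)

    if cfg.n_qtl > 0:
        qtl_idx = np.sort(rng.choice(geno.n_variants, size=cfg.n_qtl, replace=False))
        effects = rng.standard_normal(cfg.n_qtl)
    else:
        qtl_idx = np.array([], dtype=int)
        effects = np.zeros(0)
    if cfg.n_qtl > 0 and cfg.h2 > 0:
        tbv_raw = d[:, qtl_idx] @ effects
        tbv_raw = tbv_raw - tbv_raw.mean()
        sd = tbv_raw.std()
        if sd == 0:
            raise ConfigError("all selected QTLs are monomorphic; no genetic variance")
        g = tbv_raw / sd * np.sqrt(cfg.h2)
    else:
        g = np.zeros(n)

    e = rng.standard_normal(n) * np.sqrt(1.0 - cfg.h2)
    y0 = g + e

    target_sd = abs(cfg.trait_mean) * cfg.trait_cv / 100.0 if cfg.trait_mean != 0 else 1.0
    y = cfg.trait_mean + y0 * target_sd
    tbv = g * target_sd

    var_y = y.var()
    realized_h2 = float(tbv.var() / var_y) if var_y > 0 else 0.0
    phenos = pd.DataFrame({trait: y}, index=pd.Index(geno.sample_ids, name="sample_id"))
    truth = TruthRecord(
        qtl_ids=[geno.variants["id"].iloc[i] for i in qtl_idx],
        qtl_effects=effects,
        true_breeding_values=tbv,
        realized_h2=realized_h2,
    )
    return phenos, truth


def write_truth(truth: TruthRecord, path) -> None:
    """Persist QTL ids/effects as TSV (breeding values go with phenotypes)."""
    pd.DataFrame({"qtl_id": truth.qtl_ids, "effect": truth.qtl_effects}).to_csv(
        path, sep="\t", index=False
    )
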
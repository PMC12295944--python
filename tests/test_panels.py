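import numpy as np
import pandas as pd
import pytest

from gspanel.genio import impute_mean
from gspanel.gwas import GwasModelSpec, assoc_scan
from gspanel.panels import (
    panel_pvalue_profile,
    select_gwas,
    select_ld,
    select_random,
)
from gspanel.popstruct import compute_grm
from gspanel.simdata import SimConfig, simulate_genotypes, simulate_trait

from _oracles import ld_all_pairs


def _gwas_table(pvals, chroms=None, positions=None):
    m = len(pvals)
    return pd.DataFrame(
        {
            "chrom": chroms or ["chr1"] * m,
            "pos": positions or list(range(1, m + 1)),
            "id": [f"snp{j}" for j in range(m)],
            "maf": [0.3] * m,
            "beta": [0.0] * m,
            "se": [1.0] * m,
            "p": pvals,
            "pve": [0.0] * m,
        }
    )


class TestSelectGwas:
    def test_smallest_pvalues_chosen(self):
        panel = select_gwas(_gwas_table([0.5, 1e-8, 0.03]), density=2)
        assert set(panel.variant_ids) == {"snp1", "snp2"}

    def test_tie_broken_by_position(self):
        panel = select_gwas(_gwas_table([0.01, 0.5, 0.01]), density=1)
        assert panel.variant_ids == ["snp0"]  # earlier position wins the tie

    def test_density_exceeding_records_rejected(self):
        with pytest.raises(ValueError):
            select_gwas(_gwas_table([0.1, 0.2]), density=3)

    def test_output_position_sorted(self):
        table = _gwas_table([0.9, 1e-6, 1e-5, 1e-4], positions=[40, 30, 20, 10])
        panel = select_gwas(table, density=3)
        pos = table.set_index("id").loc[panel.variant_ids, "pos"]
        assert list(pos) == sorted(pos)

    def test_planted_qtls_enriched(self):
        cfg = SimConfig(n_individuals=800, n_chromosomes=5, snps_per_chrom=1000,
                        n_families=0, n_qtl=50, h2=0.4, ld_rho=0.3, seed=21)
        geno = simulate_genotypes(cfg)
        phenos, truth = simulate_trait(geno, cfg)
        gi = impute_mean(geno)
        grm = compute_grm(gi)
        table = assoc_scan(gi, phenos.iloc[:, 0].to_numpy(), GwasModelSpec(grm, 5))
        panel = select_gwas(table, 1000)
        # QTLs individually explaining >= 1% of variance should be captured
        d = gi.dosages
        var_y = phenos.iloc[:, 0].var()
        strong = []
        idx = {v: i for i, v in enumerate(gi.variants["id"])}
        scale = truth.true_breeding_values.std() / (d[:, [idx[q] for q in truth.qtl_ids]] @ truth.qtl_effects).std()
        for q, eff in zip(truth.qtl_ids, truth.qtl_effects):
            x = d[:, idx[q]]
            if (eff * scale) ** 2 * x.var() / var_y >= 0.01:
                strong.append(q)
        assert len(strong) > 0
        captured = sum(q in set(panel.variant_ids) for q in strong)
        assert captured / len(strong) >= 0.8


@pytest.fixture(scope="module")
def ld_geno():
    cfg = SimConfig(n_individuals=300, n_chromosomes=2, snps_per_chrom=150,
                    n_families=0, n_qtl=0, ld_rho=0.9, seed=22)
    return impute_mean(simulate_genotypes(cfg))


class TestSelectLd:
    def test_density_equals_total_is_identity(self, ld_geno):
        panel = select_ld(ld_geno, ld_geno.n_variants)
        assert panel.variant_ids == ld_geno.variant_ids

    def test_exact_density_contract(self, ld_geno):
        for dens in (20, 75, 150):
            panel = select_ld(ld_geno, dens, window_snps=50, step_snps=10)
            assert len(panel.variant_ids) == dens
            assert len(set(panel.variant_ids)) == dens

    def test_less_redundant_than_random(self, ld_geno):
        dens = 60
        ld_panel = select_ld(ld_geno, dens, window_snps=50, step_snps=10)
        rnd_panel = select_random(ld_geno.variants, dens, seed=1)

        def mean_r2(ids):
            sub = ld_geno.subset_variants(np.asarray(ids, dtype=object))
            vals = ld_all_pairs(sub.dosages)
            return np.mean(list(vals.values()))

        assert mean_r2(ld_panel.variant_ids) <= mean_r2(rnd_panel.variant_ids)


class TestSelectRandom:
    def test_seed_reproducible(self, sim_population):
        _, geno, _, _ = sim_population
        a = select_random(geno.variants, 100, seed=5)
        b = select_random(geno.variants, 100, seed=5)
        assert a.variant_ids == b.variant_ids

    def test_density_equals_population(self, sim_population):
        _, geno, _, _ = sim_population
        panel = select_random(geno.variants, geno.n_variants, seed=0)
        assert sorted(panel.variant_ids) == sorted(geno.variant_ids)

    def test_overlap_matches_hypergeometric_expectation(self):
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": range(1, 5001),
             "id": [f"v{j}" for j in range(5000)],
             "ref": "A", "alt": "G"}
        )
        overlaps = []
        for s in range(20):
            a = set(select_random(variants, 100, seed=2 * s).variant_ids)
            b = set(select_random(variants, 100, seed=2 * s + 1).variant_ids)
            overlaps.append(len(a & b))
        assert np.mean(overlaps) == pytest.approx(2.0, abs=1.5)  # 100*100/5000


class TestPvalueProfile:
    def test_gwas_panel_has_smaller_median_than_random(self, sim_population):
        _, geno, phenos, _ = sim_population
        gi = impute_mean(geno)
        table = assoc_scan(gi, phenos.iloc[:, 0].to_numpy(),
                           GwasModelSpec(compute_grm(gi), 5))
        gw = select_gwas(table, 100)
        rnd = select_random(gi.variants, 100, seed=0)
        assert (
            panel_pvalue_profile(gw, table)["median_p"]
            <= panel_pvalue_profile(rnd, table)["median_p"]
        )

    def test_full_panel_profile_equals_table(self, sim_population):
        _, geno, phenos, _ = sim_population
        gi = impute_mean(geno)
        table = assoc_scan(gi, phenos.iloc[:, 0].to_numpy(),
                           GwasModelSpec(compute_grm(gi), 5))
        panel = select_random(gi.variants, gi.n_variants, seed=0)
        prof = panel_pvalue_profile(panel, table)
        assert prof["min_p"] == table["p"].min()
        assert prof["max_p"] == table["p"].max()
        assert prof["median_p"] == pytest.approx(table["p"].median())

    def test_disjoint_panel_rejected(self, sim_population):
        _, geno, _, _ = sim_population
        from gspanel.panels import Panel, PanelSpec

        panel = Panel(PanelSpec("random", 2), ["nope1", "nope2"])
        with pytest.raises(ValueError, match="overlap"):
            panel_pvalue_profile(panel, _gwas_table([0.1, 0.2]))
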
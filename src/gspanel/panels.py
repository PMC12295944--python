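"""SNP panel construction at fixed densities by three selection strategies.

* ``gwas``  — top-N variants by association p-value (trait-aware).
* ``ld``    — LD pruning tightened by binary search until at least N
  survive, then uniform positional thinning to exactly N (trait-blind,
  targets independence and genome coverage).
* ``random``— seeded uniform sample without replacement (control).

All strategies return exactly-density, duplicate-free panels ordered by
genomic position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .popstruct import ld_prune

STRATEGIES = ("gwas", "ld", "random")
STANDARD_DENSITIES = (1000, 3000, 5000, 10000, 30000, 50000)


@dataclass
class PanelSpec:
    strategy: str
    density: int
    seed: int = 0
    leakage_mode: str = "within_fold"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.density < 1:
            raise ValueError("density must be >= 1")
        if self.leakage_mode not in ("within_fold", "whole_data"):
            raise ValueError(f"unknown leakage_mode {self.leakage_mode!r}")


@dataclass
class Panel:
    spec: PanelSpec
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.variant_ids) != self.spec.density:
            raise ValueError(
                f"panel has {len(self.variant_ids)} variants, spec wants {self.spec.density}"
            )
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate variant IDs in panel")

    def write(self, path, sidecar_path=None) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.variant_ids) + "\n")
        if sidecar_path is not None:
            meta = {"strategy": self.spec.strategy, "density": self.spec.density,
                    "seed": self.spec.seed, "leakage_mode": self.spec.leakage_mode,
                    **self.provenance}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _position_sorted(table: pd.DataFrame, ids: list[str]) -> list[str]:
    sub = table.set_index("id").loc[ids]
    return sub.sort_values(["chrom", "pos"], kind="mergesort").index.tolist()


def select_gwas(gwas_table: pd.DataFrame, density: int, leakage_mode: str = "within_fold") -> Panel:
    """Top-``density`` variants by p-value; ties broken by (chrom, pos)."""
    if density > len(gwas_table):
        raise ValueError(f"density {density} exceeds {len(gwas_table)} GWAS records")
    ranked = gwas_table.sort_values(["p", "chrom", "pos"], kind="mergesort")
    chosen = ranked.head(density)
    ids = _position_sorted(gwas_table[["chrom", "pos", "id"]], chosen["id"].tolist())
    spec = PanelSpec("gwas", density, leakage_mode=leakage_mode)
    return Panel(spec, ids, {"max_p": float(chosen["p"].max())})


def select_ld(
    geno: GenotypeMatrix,
    density: int,
    window_snps: int = 100,
    step_snps: int = 25,
    max_iter: int = 30,
) -> Panel:
    """LD panel of exactly ``density`` variants.

    Binary-searches the pruning r2 threshold for the tightest value whose
    survivor set still has >= density members, then thins survivors
    uniformly along the genome to exactly density.
    """
    m = geno.n_variants
    if density > m:
        raise ValueError(f"density {density} exceeds {m} variants")
    if density == m:
        ids = geno.variants["id"].tolist()
        return Panel(PanelSpec("ld", density), ids, {"r2_threshold": 1.0})

    hi_ids = ld_prune(geno, 0.999, window_snps, step_snps)
    if len(hi_ids) < density:
        raise ValueError(
            f"cannot reach density {density}: only {len(hi_ids)} variants survive "
            "even at r2 threshold ~1"
        )
    lo_t, hi_t = 0.01, 0.999
    best_t, best_ids = 0.999, hi_ids
    for _ in range(max_iter):
        mid = 0.5 * (lo_t + hi_t)
        ids = ld_prune(geno, mid, window_snps, step_snps)
        if len(ids) >= density:
            best_t, best_ids = mid, ids
            hi_t = mid
        else:
            lo_t = mid
        if hi_t - lo_t < 1e-4:
            break
    take = np.unique(np.round(np.linspace(0, len(best_ids) - 1, density)).astype(int))
    # rounding collisions are impossible here since density <= len(best_ids)
    ids = [best_ids[i] for i in take]
    spec = PanelSpec("ld", density)
    return Panel(spec, ids, {"r2_threshold": round(best_t, 6), "n_survivors": len(best_ids)})


def select_random(variant_table: pd.DataFrame, density: int, seed: int = 0) -> Panel:
    """Seeded uniform sample without replacement, position-sorted."""
    m = len(variant_table)
    if density > m:
        raise ValueError(f"density {density} exceeds {m} variants")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=density, replace=False))
    ids = variant_table["id"].iloc[idx].tolist()
    ids = _position_sorted(variant_table[["chrom", "pos", "id"]], ids)
    return Panel(PanelSpec("random", density, seed=seed), ids, {"seed": seed})


def panel_pvalue_profile(panel: Panel, gwas_table: pd.DataFrame) -> dict:
    """Min/median/max association p within a panel (diagnostics for plots)."""
    sub = gwas_table[gwas_table["id"].isin(panel.variant_ids)]
    if sub.empty:
        raise ValueError("panel has no overlap with the GWAS table")
    p = sub["p"].to_numpy()
    return {
        "n": int(p.size),
        "min_p": float(p.min()),
        "median_p": float(np.median(p)),
        "max_p": float(p.max()),
    }
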
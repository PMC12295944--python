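"""Population structure: VanRaden GRM, PCA, and dosage-based LD.

The genomic relationship matrix follows VanRaden's first method,
``G = ZZ' / (2 * sum_j p_j (1 - p_j))`` with ``Z`` the dosage matrix
centered by twice the ALT allele frequency.  LD r2 is the squared Pearson
correlation between dosage vectors (composite LD on unphased genotypes,
the estimator PLINK's ``--r2`` uses for genotype data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list[str]
    n_markers_used: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(idx, idx)]

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class PCAResult:
    scores: np.ndarray  # n x k, columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # k, descending

    def write_tsv(self, path, sample_ids: list[str]) -> None:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        pd.DataFrame(self.scores, index=sample_ids, columns=cols).to_csv(path, sep="\t")


@dataclass
class LDPair:
    id_a: str
    id_b: str
    r2: float


def _dosage_matrix(geno: GenotypeMatrix) -> np.ndarray:
    d = geno.dosages.astype(float)
    if geno.missing_mask().any():
        raise ValueError("missing dosages present; run impute_mean first")
    return d


def compute_grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden GRM from imputed dosages; monomorphic markers are excluded."""
    d = _dosage_matrix(geno)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("compute_grm: excluded %d monomorphic markers", n_dropped)
    d = d[:, poly]
    p = p[poly]
    z = d - 2.0 * p[None, :]
    c = 2.0 * float(np.sum(p * (1.0 - p)))
    g = (z @ z.T) / c
    g = 0.5 * (g + g.T)  # enforce exact symmetry
    return GRM(g, list(geno.sample_ids), int(poly.sum()))


def pca(grm: GRM, k: int) -> PCAResult:
    """Top-k principal components of the GRM (scores = U * sqrt(lambda))."""
    if k > grm.n:
        raise ValueError(f"k={k} exceeds n={grm.n}")
    if not np.isfinite(grm.matrix).all():
        raise ValueError("GRM contains non-finite entries")
    w, v = np.linalg.eigh(grm.matrix)
    order = np.argsort(w)[::-1][:k]
    eigvals = np.clip(w[order], 0.0, None)
    scores = v[:, order] * np.sqrt(eigvals)[None, :]
    return PCAResult(scores, eigvals)


def ld_r2(geno: GenotypeMatrix, window_snps: int) -> Iterator[LDPair]:
    """Yield r2 for every variant pair within a sliding window, per chromosome.

    Pairs are emitted once, in (left index, right index) order; pairs with a
    zero-variance member are skipped and logged.
    """
    d = _dosage_matrix(geno)
    ids = geno.variants["id"].to_numpy()
    chroms = geno.variants["chrom"].to_numpy()
    sd = d.std(axis=0)
    n_skipped = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a_pos, i in enumerate(idx):
            if sd[i] == 0:
                n_skipped += 1
                continue
            right = idx[a_pos + 1 : a_pos + 1 + window_snps]
            right = right[sd[right] > 0]
            if right.size == 0:
                continue
            xi = d[:, i] - d[:, i].mean()
            block = d[:, right] - d[:, right].mean(axis=0)
            r = (xi @ block) / (np.linalg.norm(xi) * np.linalg.norm(block, axis=0))
            for j, rij in zip(right, r):
                yield LDPair(ids[i], ids[j], float(min(rij * rij, 1.0)))
    if n_skipped:
        logger.info("ld_r2: skipped %d zero-variance variants", n_skipped)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise dosage r2 for a (n x k) block; zero-variance columns give 0."""
    z = d - d.mean(axis=0)
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = np.inf
    zn = z / norms
    r = zn.T @ zn
    np.fill_diagonal(r, 0.0)
    return r * r


def ld_prune(
    geno: GenotypeMatrix,
    r2_threshold: float,
    window_snps: int = 100,
    step_snps: int = 25,
) -> list[str]:
    """Greedy windowed LD pruning; returns surviving variant IDs in order.

    Within each window (per chromosome, advanced by ``step_snps``) the
    highest-r2 pair above threshold is found repeatedly and its lower-MAF
    member dropped (MAF tie: the later-positioned member is dropped).  The
    survivors contain no within-window pair with r2 above the threshold.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    if window_snps < 2 or step_snps < 1:
        raise ValueError("window_snps >= 2 and step_snps >= 1 required")
    d = _dosage_matrix(geno)
    maf = geno.maf()
    chroms = geno.variants["chrom"].to_numpy()
    alive = np.ones(geno.n_variants, dtype=bool)
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < cidx.size:
            widx = cidx[start : start + window_snps]
            live = widx[alive[widx]]
            if live.size >= 2:
                r2 = _r2_matrix(d[:, live])
                local_alive = np.ones(live.size, dtype=bool)
                while True:
                    masked = np.where(
                        local_alive[:, None] & local_alive[None, :], r2, 0.0
                    )
                    a, b = np.unravel_index(np.argmax(masked), masked.shape)
                    if masked[a, b] <= r2_threshold:
                        break
                    ia, ib = live[a], live[b]
                    if maf[ia] < maf[ib]:
                        drop = a
                    elif maf[ib] < maf[ia]:
                        drop = b
                    else:
                        drop = b if a < b else a  # tie: later position goes
                    local_alive[drop] = False
                alive[live[~local_alive]] = False
            if start + window_snps >= cidx.size:
                break
            start += step_snps
    return geno.variants["id"][alive].tolist()
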
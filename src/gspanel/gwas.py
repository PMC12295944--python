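"""Single-marker linear mixed-model association with a polygenic GRM term.

Model per SNP: ``y = 1*mu + P*alpha + Z*g + x*b + e`` with
``g ~ N(0, G*sigma_a2)`` and ``e ~ N(0, I*sigma_e2)``; ``P`` holds the top
principal components (default 10) as fixed effects against stratification.

Variance components are estimated once under the null (no marker) by REML
on the spectral transform of G, then held fixed for the per-marker
generalized least squares scan (the EMMAX approximation).  Each marker gets
a Wald test: ``(beta/se)^2 ~ chi2_1``.

Per-SNP variance explained uses the sampling-variance-corrected form
``PVE = 2 b^2 pq / (2 b^2 pq + se^2 * 2 N * pq)`` with ``pq = MAF(1-MAF)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix
from .popstruct import GRM, pca

__all__ = [
    "GwasModelSpec",
    "VarianceComponents",
    "fit_null_lmm",
    "assoc_scan",
    "snp_pve",
]


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("require sigma_a2 >= 0 and sigma_e2 > 0")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


@dataclass
class GwasModelSpec:
    grm: GRM
    n_pcs: int = 10
    trait: str = "trait"

    def __post_init__(self) -> None:
        if self.n_pcs >= self.grm.n:
            raise ValueError("n_pcs must be < n samples")


def _reml_neg_loglik(
    log_delta: float, lam: np.ndarray, ystar: np.ndarray, xstar: np.ndarray
) -> float:
    """REML negative log-likelihood profiled over sigma_a2; delta=se2/sa2."""
    delta = np.exp(log_delta)
    n, p = xstar.shape
    w = 1.0 / (lam + delta)
    xtw = xstar.T * w
    xtwx = xtw @ xstar
    beta = np.linalg.solve(xtwx, xtw @ ystar)
    r = ystar - xstar @ beta
    rss = float(np.sum(w * r * r))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    df = n - p
    ll = -0.5 * (
        df * np.log(2.0 * np.pi * rss / df)
        + df
        + np.sum(np.log(lam + delta))
        + logdet_xtwx
    )
    return -ll


def fit_null_lmm(y: np.ndarray, covariates: np.ndarray, grm: GRM) -> VarianceComponents:
    """REML variance components for y = X*b + g + e via the spectral transform.

    ``covariates`` is the full fixed-effect design including the intercept
    column.  The GRM is eigendecomposed once and the REML likelihood is
    optimized over the variance ratio delta = sigma_e2/sigma_a2 in log space.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != y.size:
        raise ValueError("covariates and y disagree on n")
    lam, u = np.linalg.eigh(grm.matrix)
    if lam.min() < -1e-6:
        raise ValueError("GRM is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)
    ystar = u.T @ y
    xstar = u.T @ x

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(-12.0, 12.0),
        args=(lam, ystar, xstar),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    n, p = xstar.shape
    w = 1.0 / (lam + delta)
    xtw = xstar.T * w
    beta = np.linalg.solve(xtw @ xstar, xtw @ ystar)
    r = ystar - xstar @ beta
    sigma_a2 = float(np.sum(w * r * r) / (n - p))
    sigma_e2 = delta * sigma_a2
    return VarianceComponents(max(sigma_a2, 1e-12), max(sigma_e2, 1e-12))


def assoc_scan(
    geno: GenotypeMatrix,
    y: np.ndarray,
    spec: GwasModelSpec,
    vc: VarianceComponents | None = None,
) -> pd.DataFrame:
    """Single-marker GLS scan under the null-fitted covariance (EMMAX-style).

    Returns one row per variant: chrom, pos, id, maf, beta, se, p, pve,
    sorted by (chrom, pos).  Markers collinear with the covariates are
    flagged (``ok=False``) with beta=0, p=1.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if geno.n_samples != n or spec.grm.n != n:
        raise ValueError("geno, y and GRM disagree on sample count")
    d = geno.dosages.astype(float)
    if geno.missing_mask().any():
        raise ValueError("missing dosages present; impute first")

    pcs = pca(spec.grm, spec.n_pcs).scores if spec.n_pcs > 0 else np.empty((n, 0))
    x0 = np.column_stack([np.ones(n), pcs])
    if vc is None:
        vc = fit_null_lmm(y, x0, spec.grm)

    lam, u = np.linalg.eigh(spec.grm.matrix)
    lam = np.clip(lam, 0.0, None)
    w = 1.0 / (vc.sigma_a2 * lam + vc.sigma_e2)
    sw = np.sqrt(w)
    yw = sw * (u.T @ y)
    xw = sw[:, None] * (u.T @ x0)
    gw = sw[:, None] * (u.T @ d)

    q, _ = np.linalg.qr(xw)
    yr = yw - q @ (q.T @ yw)
    gr = gw - q @ (q.T @ gw)

    gtg = np.einsum("ij,ij->j", gr, gr)
    ok = gtg > 1e-10 * n
    safe = np.where(ok, gtg, 1.0)
    beta = (gr.T @ yr) / safe
    se = np.sqrt(1.0 / safe)
    chi2 = np.where(ok, (beta / se) ** 2, 0.0)
    pvals = np.where(ok, stats.chi2.sf(chi2, df=1), 1.0)
    beta = np.where(ok, beta, 0.0)
    se = np.where(ok, se, np.nan)

    maf = geno.maf()
    pve = np.array(
        [
            snp_pve(b, s, f, n) if o and f > 0 else 0.0
            for b, s, f, o in zip(beta, se, maf, ok)
        ]
    )
    out = geno.variants[["chrom", "pos", "id"]].copy()
    out["maf"] = maf
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out["pve"] = pve
    out["ok"] = ok
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def snp_pve(beta: float, se: float, maf: float, n: int) -> float:
    """Proportion of phenotypic variance explained by one SNP.

    ``PVE = 2 b^2 pq / (2 b^2 pq + se^2 * 2 N * pq)``, ``pq = MAF(1-MAF)``.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf={maf} outside (0, 0.5]")
    if se <= 0:
        raise ValueError("se must be > 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    pq = maf * (1.0 - maf)
    num = 2.0 * beta * beta * pq
    return float(num / (num + se * se * 2.0 * n * pq))


def write_gwas_tsv(table: pd.DataFrame, path, sort_by_p: bool = False) -> None:
    t = table.sort_values("p") if sort_by_p else table
    t.to_csv(path, sep="\t", index=False)
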
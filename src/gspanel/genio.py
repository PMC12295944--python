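"""Genotype/phenotype I/O and marker quality control.

The in-memory currency between pipeline stages is :class:`GenotypeMatrix`:
an ``n_samples x n_variants`` additive-dosage matrix (count of ALT alleles,
0/1/2, with ``-1`` as the missing sentinel) plus sample identifiers and a
variant table.  Readers exist for VCF (via cyvcf2) and PLINK-1 binary
(.bed/.bim/.fam, SNP-major); writers round-trip both at dosage level.

QC follows standard practice for WGS-derived SNP data: drop variants with
call rate below 90%, minor allele frequency below 0.05, or exact
Hardy-Weinberg p below 1e-7, in that order.  Missing dosages left after QC
are filled by the per-variant mean (``impute_mean``) — a deliberately naive
stand-in for LD-aware imputation, adequate when missingness is low and
random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-dosage sentinel used throughout the package.
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])


class ConfigError(ValueError):
    """Invalid configuration values."""


class ParseError(ValueError):
    """Malformed genotype file."""


class EmptyPanelError(ValueError):
    """A filter or selection left zero variants."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix with sample IDs and variant metadata.

    ``dosages`` is ``(n_samples, n_variants)``; integer 0/1/2 with -1 for
    missing before imputation, float after :func:`impute_mean`.
    ``variants`` is a DataFrame with columns chrom, pos (1-based), id, ref,
    alt, sorted by (chrom, pos).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        ids = self.variants["id"]
        if ids.duplicated().any():
            raise ValueError("variant IDs must be unique")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        if np.issubdtype(self.dosages.dtype, np.floating):
            return np.isnan(self.dosages) | (self.dosages == MISSING)
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - self.missing_mask().mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency over observed genotypes."""
        miss = self.missing_mask()
        d = np.where(miss, 0.0, self.dosages.astype(float))
        n_obs = (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = d.sum(axis=0) / (2.0 * n_obs)
        return p

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, index: np.ndarray | list) -> "GenotypeMatrix":
        """Column subset by boolean mask, integer index, or variant IDs."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        elif idx.dtype.kind in "US" or (idx.dtype == object and idx.size and isinstance(idx.flat[0], str)):
            pos = pd.Index(self.variants["id"])
            idx = pos.get_indexer(idx)
            if (idx < 0).any():
                raise KeyError("unknown variant IDs in subset")
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, index: np.ndarray | list) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.sample_ids[i] for i in idx],
            self.variants.copy(),
        )

    def sort_variants(self) -> "GenotypeMatrix":
        order = self.variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.subset_variants(order)


@dataclass
class QCConfig:
    """Variant-filter thresholds; defaults are the standard WGS-QC values."""

    min_call_rate: float = 0.90
    min_maf: float = 0.05
    hwe_p_threshold: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_p_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_output: int
    config: QCConfig = field(default_factory=QCConfig)

    @property
    def n_removed(self) -> int:
        return self.removed_call_rate + self.removed_maf + self.removed_hwe

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["call_rate", "maf", "hwe", "retained"],
                "threshold": [
                    self.config.min_call_rate,
                    self.config.min_maf,
                    self.config.hwe_p_threshold,
                    np.nan,
                ],
                "n_variants": [
                    self.removed_call_rate,
                    self.removed_maf,
                    self.removed_hwe,
                    self.n_output,
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. 2005).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    # het counts share parity with n_rare
    het_max = min(n_rare, 2 * n - n_rare)
    probs = np.zeros(het_max + 1)
    # start at the modal het count (parity-adjusted) to avoid under/overflow
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if (mid % 2) != (n_rare % 2):
        mid += 1
    mid = min(mid, het_max)
    probs[mid] = 1.0
    # downward: P(h-2)/P(h) = h*(h-1) / (4*(r+1)*(c+1)), r/c = hom counts at h
    h = mid
    while h > 1:
        rare_hom = (n_rare - h) // 2
        common_hom = n - rare_hom - h
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
        h -= 2
    # upward: P(h+2)/P(h) = 4*r*c / ((h+2)*(h+1))
    h = mid
    while h + 2 <= het_max:
        rare_hom = (n_rare - h) // 2
        common_hom = n - rare_hom - h
        probs[h + 2] = probs[h] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
        h += 2
    total = probs.sum()
    probs /= total
    p_obs = probs[n_Aa]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    d = geno.dosages
    miss = geno.missing_mask()
    out = np.ones(geno.n_variants)
    for j in range(geno.n_variants):
        col = d[~miss[:, j], j]
        if col.size == 0:
            continue
        n_aa_alt = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_rr = int((col == 0).sum())
        out[j] = hwe_exact_test(n_rr, n_het, n_aa_alt)
    return out


# ---------------------------------------------------------------------------
# QC and imputation


def apply_qc(geno: GenotypeMatrix, qc: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by call rate, then MAF, then HWE.

    Boundary handling: a variant is kept when call rate >= min_call_rate,
    MAF >= min_maf (so MAF exactly at the threshold survives) and HWE
    p >= hwe_p_threshold.  Counts in the report are attributed to the first
    criterion that removes a variant.
    """
    if qc is None:
        qc = QCConfig()
    if geno.n_variants == 0:
        raise EmptyPanelError("no variants in input")

    cr = geno.call_rate()
    keep_cr = cr >= qc.min_call_rate
    removed_cr = int((~keep_cr).sum())

    g1 = geno.subset_variants(keep_cr)
    maf = g1.maf()
    keep_maf = maf >= qc.min_maf
    removed_maf = int((~keep_maf).sum())

    g2 = g1.subset_variants(keep_maf)
    hwe_p = _hwe_pvalues(g2)
    keep_hwe = hwe_p >= qc.hwe_p_threshold
    removed_hwe = int((~keep_hwe).sum())

    g3 = g2.subset_variants(keep_hwe)
    report = QCReport(geno.n_variants, removed_cr, removed_maf, removed_hwe, g3.n_variants, qc)
    logger.info(
        "QC: %d in, removed call_rate=%d maf=%d hwe=%d, %d retained",
        report.n_input, removed_cr, removed_maf, removed_hwe, report.n_output,
    )
    if g3.n_variants == 0:
        raise EmptyPanelError("QC removed every variant")
    return g3, report


def impute_mean(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean of observed dosages.

    Preserves each variant's observed allele frequency exactly; output is
    float-valued with no missing entries.
    """
    miss = geno.missing_mask()
    d = geno.dosages.astype(float)
    if not miss.any():
        return GenotypeMatrix(d, list(geno.sample_ids), geno.variants.copy())
    n_obs = (~miss).sum(axis=0)
    if (n_obs == 0).any():
        bad = geno.variants["id"][n_obs == 0].tolist()
        raise ValueError(f"variant(s) with 100% missing genotypes: {bad[:5]}")
    d_obs = np.where(miss, 0.0, d)
    means = d_obs.sum(axis=0) / n_obs
    d = np.where(miss, means[None, :], d)
    return GenotypeMatrix(d, list(geno.sample_ids), geno.variants.copy())


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Multiallelic and non-SNP records are skipped (count logged).  Dosage is
    the ALT-allele count; any missing genotype maps to the sentinel.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # noqa: BLE001 - cyvcf2 raises bare Exceptions
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    records: list[tuple] = []
    skipped = 0
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0,1,2, 3=unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        records.append((str(v.CHROM), int(v.POS), vid, v.REF, v.ALT[0]))
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    if not records:
        raise ParseError(f"no biallelic SNP records in {path}")
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    geno = GenotypeMatrix(np.stack(rows, axis=1), samples, variants)
    return geno.sort_variants()


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    d = geno.dosages
    miss = geno.missing_mask()
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in geno.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.sample_ids) + "\n")
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            dj = d[:, j]
            calls = [
                "./." if miss[i, j] else gt_strings[int(round(dj[i]))]
                for i in range(geno.n_samples)
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK-1 binary I/O (SNP-major .bed + .bim + .fam)

# 2-bit codes in a .bed byte, per sample: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# A1 is taken as ALT so the code maps to ALT dosage {2, missing, 1, 0}.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read PLINK-1 binary genotypes (``prefix``.bed/.bim/.fam)."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    sample_ids = fam[1].tolist()
    n, m = len(sample_ids), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ParseError(
            f"{prefix}.bed: bad magic bytes {raw[:3].tobytes().hex()} "
            "(expected 6c1b01, PLINK-1 SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ParseError(f"{prefix}.bed: size mismatch for {n} samples x {m} variants")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample i at bit offset (i % 4) * 2 (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T.copy()
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "id": bim["id"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    geno = GenotypeMatrix(dosages, sample_ids, variants)
    return geno.sort_variants()


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write PLINK-1 binary genotypes (SNP-major .bed + .bim + .fam)."""
    prefix = str(prefix)
    n, m = geno.n_samples, geno.n_variants
    v = geno.variants
    with open(prefix + ".bim", "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.id}\t0\t{row.pos}\t{row.alt}\t{row.ref}\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in geno.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    d = geno.dosages
    miss = geno.missing_mask()
    codes = np.empty((n, m), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        if dosage == MISSING:
            codes[miss] = code
        else:
            codes[(~miss) & (np.round(d).astype(int) == dosage)] = code
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded.reshape(m, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2, dtype=np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV (``sample_id`` column + one column per trait)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    return df.set_index("sample_id")


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=True, index_label="sample_id")
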
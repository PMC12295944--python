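import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gspanel.genio import (
    MISSING,
    EmptyPanelError,
    GenotypeMatrix,
    ParseError,
    QCConfig,
    apply_qc,
    hwe_exact_test,
    impute_mean,
    read_plink,
    read_vcf,
    write_plink,
    write_vcf,
)

from conftest import make_geno
from _oracles import hwe_enumeration


@pytest.fixture
def small_fixture():
    # 3 samples x 5 SNPs with one missing call
    d = np.array(
        [
            [0, 1, 2, 1, MISSING],
            [1, 0, 2, 0, 1],
            [2, 1, 0, 1, 2],
        ],
        dtype=np.int8,
    )
    return make_geno(d, chrom=["chr1"] * 3 + ["chr2"] * 2, pos=[100, 200, 300, 50, 60])


class TestVcfRoundTrip:
    def test_round_trip_bit_identical(self, small_fixture, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf(small_fixture, path)
        back = read_vcf(path)
        assert np.array_equal(back.dosages, small_fixture.sort_variants().dosages)
        assert back.sample_ids == small_fixture.sample_ids
        assert back.variants["pos"].tolist() == small_fixture.sort_variants().variants["pos"].tolist()

    def test_missing_genotype_maps_to_sentinel(self, small_fixture, tmp_path):
        path = tmp_path / "x.vcf"
        write_vcf(small_fixture, path)
        back = read_vcf(path)
        col = back.variants.index[back.variants["id"] == "snp4"][0]
        assert back.dosages[0, col] == MISSING


class TestPlink:
    def test_round_trip(self, small_fixture, tmp_path):
        prefix = tmp_path / "geno"
        write_plink(small_fixture, prefix)
        back = read_plink(prefix)
        srt = small_fixture.sort_variants()
        assert np.array_equal(back.dosages, srt.dosages)
        assert back.sample_ids == small_fixture.sample_ids
        assert back.variants["id"].tolist() == srt.variants["id"].tolist()

    def test_magic_bytes_enforced(self, small_fixture, tmp_path):
        prefix = tmp_path / "geno"
        write_plink(small_fixture, prefix)
        raw = bytearray((tmp_path / "geno.bed").read_bytes())
        assert raw[:3] == bytes([0x6C, 0x1B, 0x01])
        raw[0] = 0x00
        (tmp_path / "geno.bed").write_bytes(bytes(raw))
        with pytest.raises(ParseError, match="magic"):
            read_plink(prefix)


class TestHwe:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_matches_enumeration_oracle_on_examples(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(
            hwe_enumeration(25, 50, 25), abs=1e-12
        )

    def test_all_homozygotes_fails_qc_threshold(self):
        p = hwe_exact_test(50, 0, 50)
        assert p < 1e-7
        assert p == pytest.approx(hwe_enumeration(50, 0, 50), rel=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_agrees_with_enumeration(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration(a, h, b), abs=1e-12
        )


def _hwe_column(n: int, maf: float) -> np.ndarray:
    """Genotype column with exact-HWE-proportion counts at the given MAF."""
    n_hom = int(round(n * maf * maf))
    n_het = int(round(n * 2 * maf * (1 - maf)))
    col = np.zeros(n, dtype=np.int8)
    col[:n_hom] = 2
    col[n_hom : n_hom + n_het] = 1
    return col


class TestApplyQc:
    def test_maf_boundary_inclusive(self):
        n = 100
        cols = [_hwe_column(n, f) for f in (0.0, 0.04, 0.05, 0.20, 0.50)]
        geno = make_geno(np.column_stack(cols))
        out, report = apply_qc(geno, QCConfig())
        assert out.n_variants == 3  # MAF 0.05 kept (boundary inclusive)
        assert report.removed_maf == 2
        assert report.removed_call_rate == 0 and report.removed_hwe == 0

    def test_call_rate_rule(self):
        n = 100
        good = _hwe_column(n, 0.3)
        bad = good.copy()
        bad[:11] = MISSING  # call rate 0.89 < 0.90
        geno = make_geno(np.column_stack([good, bad]))
        out, report = apply_qc(geno, QCConfig())
        assert out.n_variants == 1
        assert report.removed_call_rate == 1

    def test_zero_thresholds_identity(self):
        geno = make_geno(np.column_stack([_hwe_column(50, 0.01), _hwe_column(50, 0.4)]))
        out, report = apply_qc(geno, QCConfig(0.0, 0.0, 0.0))
        assert out.n_variants == geno.n_variants
        assert report.n_removed == 0

    def test_report_counts_sum(self, small_fixture):
        out, report = apply_qc(small_fixture, QCConfig(0.0, 0.0, 0.0))
        assert report.n_input - report.n_output == report.n_removed

    def test_all_removed_raises(self):
        geno = make_geno(np.column_stack([_hwe_column(60, 0.01)]))
        with pytest.raises(EmptyPanelError):
            apply_qc(geno, QCConfig())


class TestImputeMean:
    def test_no_missing_is_identity(self, small_fixture):
        g = small_fixture.subset_variants(np.array([0, 1, 2, 3]))
        out = impute_mean(g)
        assert np.array_equal(out.dosages, g.dosages.astype(float))

    def test_missing_filled_with_observed_mean(self):
        geno = make_geno(np.array([[0], [2], [MISSING]], dtype=np.int8))
        out = impute_mean(geno)
        assert out.dosages[2, 0] == pytest.approx(1.0)

    def test_allele_frequency_preserved(self, small_fixture):
        before = small_fixture.alt_freq()
        after = impute_mean(small_fixture).alt_freq()
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_fully_missing_variant_rejected(self):
        geno = make_geno(np.full((3, 1), MISSING, dtype=np.int8))
        with pytest.raises(ValueError, match="missing"):
            impute_mean(geno)


class TestGenotypeMatrix:
    def test_duplicate_sample_ids_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            GenotypeMatrix(
                np.zeros((2, 1), dtype=np.int8),
                ["a", "a"],
                make_geno(np.zeros((2, 1), dtype=np.int8)).variants,
            )

    def test_subset_by_ids(self, small_fixture):
        sub = small_fixture.subset_variants(np.array(["snp2", "snp0"], dtype=object))
        assert sub.variants["id"].tolist() == ["snp2", "snp0"]
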
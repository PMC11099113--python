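"""Variant QC: VCF ingestion, Hardy-Weinberg exact test, MAF, filters, codings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipnpred.genotype_qc import (
    GenotypeMatrix,
    QCThresholds,
    VariantRecord,
    compute_maf,
    filter_variants,
    hwe_exact_p,
    read_vcf,
    recode,
    write_vcf,
)


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force exact HWE p: enumerate every heterozygote count compatible
    with the observed allele counts, with probabilities from log-factorials."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab  # allele A count
    lf = [math.lgamma(k + 1) for k in range(2 * n + 1)]

    def log_prob(het: int) -> float:
        homa = (na - het) // 2
        homb = n - homa - het
        return (
            lf[n] - lf[homa] - lf[het] - lf[homb]
            + het * math.log(2.0)
            + lf[na] + lf[2 * n - na] - lf[2 * n]
        )

    hets = [h for h in range(min(na, 2 * n - na) + 1) if (na - h) % 2 == 0]
    logs = [log_prob(h) for h in hets]
    mx = max(logs)
    probs = [math.exp(v - mx) for v in logs]
    total = sum(probs)
    obs = probs[hets.index(n_ab)] / total
    return min(1.0, sum(p for p in probs if p / total <= obs * (1 + 1e-12)) / total)


class TestReadVcf:
    def test_basic_dosage_coding(self, tiny_vcf):
        matrix, records = read_vcf(tiny_vcf)
        assert matrix.sample_ids == ["SAM1", "SAM2", "SAM3"]
        np.testing.assert_array_equal(matrix.column("rs1"), [0, 1, 2])
        assert records[0].mean_coverage == pytest.approx(30.0)

    def test_multiallelic_flagged_not_split(self, tiny_vcf):
        _, records = read_vcf(tiny_vcf)
        rec = {r.variant_id: r for r in records}["rs2"]
        assert not rec.biallelic
        assert rec.alt_allele == "A,T"

    def test_missing_genotype_and_rate(self, tiny_vcf):
        matrix, records = read_vcf(tiny_vcf)
        col = matrix.column("rs3")
        assert np.isnan(col[0]) and col[1] == 1 and col[2] == 0
        rec = {r.variant_id: r for r in records}["rs3"]
        assert rec.genotyping_rate == pytest.approx(2 / 3)

    def test_fallback_id_and_score(self, tiny_vcf):
        _, records = read_vcf(tiny_vcf)
        rec = records[4]
        assert rec.variant_id == "chr1:500:A:C"
        assert rec.deleterious_score == pytest.approx(21.5)

    def test_roundtrip_write_read(self, tiny_vcf, tmp_path):
        matrix, records = read_vcf(tiny_vcf)
        keep = [r for r in records if r.biallelic]
        sub = matrix.subset_variants([r.variant_id for r in keep])
        out = tmp_path / "out.vcf"
        write_vcf(str(out), sub, keep)
        m2, r2 = read_vcf(str(out))
        assert m2.sample_ids == matrix.sample_ids
        np.testing.assert_array_equal(m2.column("rs1"), sub.column("rs1"))


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 7) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(57, 78, 28), (10, 5, 1), (0, 5, 0), (3, 3, 3), (100, 20, 80), (1, 1, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_property_matches_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_p(a, b, c) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), abs=1e-12
        )

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 2)


class TestMaf:
    def test_examples(self):
        assert compute_maf(np.array([0.0, 0, 0, 0])) == 0.0
        assert compute_maf(np.array([1.0, 1, 0, 2])) == 0.5

    def test_missing_excluded_from_denominator(self):
        assert compute_maf(np.array([np.nan, 1.0, 1.0])) == pytest.approx(0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            compute_maf(np.array([np.nan, np.nan]))

    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fold_invariance(self, geno):
        col = np.array(geno)
        assert compute_maf(col) == pytest.approx(compute_maf(2.0 - col), abs=1e-12)
        assert compute_maf(col) <= 0.5


def _make_record(vid, **kw):
    defaults = dict(
        variant_id=vid, chrom="chr1", pos=1, ref_allele="A", alt_allele="G",
        filter_label="PASS", biallelic=True, mean_coverage=30.0,
        genotyping_rate=1.0, maf=0.2, hwe_p=0.5,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


class TestFilterVariants:
    def _toy(self):
        records = [
            _make_record("v_rate", genotyping_rate=0.94),
            _make_record("v_cov", mean_coverage=9.9),
            _make_record("v_hwe", hwe_p=9e-5),
            _make_record("v_multi", biallelic=False),
            _make_record("v_lowq", filter_label="LowQual"),
            _make_record("v_boundary", genotyping_rate=0.95, mean_coverage=10.0, hwe_p=1e-4),
            _make_record("v_clean"),
        ]
        matrix = GenotypeMatrix(
            sample_ids=["a", "b"],
            variant_ids=[r.variant_id for r in records],
            dosage=np.zeros((2, len(records))),
        )
        return records, matrix

    def test_one_rule_each_plus_clean(self):
        records, matrix = self._toy()
        kept, kept_m, log = filter_variants(records, matrix)
        assert {r.variant_id for r in kept} == {"v_boundary", "v_clean"}
        assert dict(log) == {
            "v_rate": "genotyping_rate",
            "v_cov": "mean_coverage",
            "v_hwe": "hwe",
            "v_multi": "not_biallelic",
            "v_lowq": "not_pass",
        }

    def test_boundary_values_kept(self):
        # thresholds are removal conditions (<), so equality survives
        records, matrix = self._toy()
        kept, _, _ = filter_variants(records, matrix)
        assert "v_boundary" in {r.variant_id for r in kept}

    def test_idempotent(self):
        records, matrix = self._toy()
        kept1, m1, _ = filter_variants(records, matrix)
        kept2, m2, log2 = filter_variants(kept1, m1)
        assert [r.variant_id for r in kept2] == [r.variant_id for r in kept1]
        assert log2 == []
        np.testing.assert_array_equal(m1.dosage, m2.dosage)

    def test_unknown_coverage_not_removed_by_coverage_rule(self):
        records = [_make_record("v_nocov", mean_coverage=None)]
        matrix = GenotypeMatrix(["a", "b"], ["v_nocov"], np.zeros((2, 1)))
        kept, _, _ = filter_variants(records, matrix)
        assert len(kept) == 1


class TestRecode:
    @pytest.mark.parametrize(
        "coding,expected",
        [
            ("additive", [0, 1, 2]),
            ("dominant", [0, 1, 1]),
            ("recessive", [0, 0, 1]),
        ],
    )
    def test_definitions(self, coding, expected):
        np.testing.assert_array_equal(
            recode(np.array([0.0, 1.0, 2.0]), coding), expected
        )

    def test_missing_propagates(self):
        out = recode(np.array([np.nan, 1.0]), "recessive")
        assert np.isnan(out[0]) and out[1] == 0.0

    def test_unknown_coding(self):
        with pytest.raises(ValueError):
            recode(np.array([0.0]), "codominant")

    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_properties(self, geno):
        col = np.array(geno)
        np.testing.assert_array_equal(recode(col, "additive"), col)
        assert np.all(recode(col, "dominant") >= recode(col, "recessive"))
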
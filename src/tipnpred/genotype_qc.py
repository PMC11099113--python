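"""Variant-level quality control of a multi-sample VCF.

Ingests diploid genotypes as a samples x variants dosage matrix (reference allele
coded 0, heterozygote 1, alternate homozygote 2, missing as NaN), computes per-variant
genotyping rate, minor allele frequency and the Hardy-Weinberg exact test, and applies
the hard filters of the analysis: a variant is retained iff

* genotyping rate >= 0.95,
* mean coverage across samples >= 10 reads,
* Hardy-Weinberg exact p >= 1e-4,
* the site is biallelic, and
* FILTER is PASS.

Thresholds are removal conditions exactly as stated (rate < 0.95 removes), so equality
keeps the variant.  Multi-allelic rows are flagged and dropped, never decomposed, and
missing genotypes are never imputed at this stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pysam
from scipy import special

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "QCThresholds",
    "read_vcf",
    "write_vcf",
    "hwe_exact_p",
    "compute_maf",
    "genotyping_rate",
    "filter_variants",
    "recode",
    "CODINGS",
]

CODINGS = ("additive", "dominant", "recessive")


@dataclass
class VariantRecord:
    """Per-variant metadata carried through QC and downstream selection."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    filter_label: str = "PASS"
    biallelic: bool = True
    mean_coverage: float | None = None
    genotyping_rate: float = 1.0
    maf: float = 0.0
    hwe_p: float = 1.0
    genes: set[str] = field(default_factory=set)
    deleterious_score: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix; missing genotypes are NaN."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray  # float, values in {0, 1, 2, nan}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape does not match sample/variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def subset_variants(self, keep: np.ndarray | list[str]) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {v: i for i, v in enumerate(self.variant_ids)}
            idx = np.array([pos[v] for v in keep], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_ids=[self.variant_ids[i] for i in idx],
            dosage=self.dosage[:, idx],
        )

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            dosage=self.dosage[idx, :],
        )


@dataclass(frozen=True)
class QCThresholds:
    """Removal thresholds; defaults are the analysis' published filter settings."""

    min_genotyping_rate: float = 0.95
    min_mean_coverage: float = 10.0
    min_hwe_p: float = 1e-4
    require_pass: bool = True
    require_biallelic: bool = True


def read_vcf(
    path: str, coverage_field: str = "DP"
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a VCF 4.x into a dosage matrix plus per-variant records.

    ``coverage_field`` names the INFO key holding total depth at the site; the
    per-variant mean coverage is that value divided by the sample count.  A missing
    key yields a warning and ``mean_coverage=None`` for that record.  Multi-allelic
    rows are kept but flagged not-biallelic (their dosage counts any non-reference
    allele, capped at 2).  variant_id is the rsID when present, else
    chrom:pos:ref:alt.
    """
    vcf = pysam.VariantFile(path)
    sample_ids = list(vcf.header.samples)
    n = len(sample_ids)
    if n == 0:
        raise ValueError(f"{path}: VCF has no samples")
    records: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    warned_coverage = False
    for rec in vcf.fetch() if vcf.index is not None else vcf:
        alts = rec.alts or ()
        biallelic = len(alts) == 1
        alt = ",".join(a or "." for a in alts) if alts else "."
        vid = rec.id if rec.id not in (None, ".") else (
            f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
        )
        col = np.full(n, np.nan)
        for i, s in enumerate(sample_ids):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[i] = float(min(sum(1 for a in gt if a != 0), 2))
        filt = list(rec.filter.keys())
        filter_label = filt[0] if filt else "PASS"
        mean_cov: float | None = None
        if coverage_field in rec.info:
            val = rec.info[coverage_field]
            if isinstance(val, tuple):
                val = val[0]
            mean_cov = float(val) / n
        elif not warned_coverage:
            warnings.warn(
                f"{path}: INFO field '{coverage_field}' absent; "
                "mean coverage unknown for affected records",
                stacklevel=2,
            )
            warned_coverage = True
        n_called = int(np.sum(~np.isnan(col)))
        rate = n_called / n
        score = None
        if "CADD" in rec.info:
            sc = rec.info["CADD"]
            score = float(sc[0] if isinstance(sc, tuple) else sc)
        vr = VariantRecord(
            variant_id=vid,
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=rec.ref or ".",
            alt_allele=alt,
            filter_label=filter_label,
            biallelic=biallelic,
            mean_coverage=mean_cov,
            genotyping_rate=rate,
            deleterious_score=score,
        )
        if n_called > 0:
            vr.maf = compute_maf(col)
            counts = _genotype_counts(col)
            vr.hwe_p = hwe_exact_p(*counts)
        records.append(vr)
        columns.append(col)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=[r.variant_id for r in records],
        dosage=np.column_stack(columns) if columns else np.empty((n, 0)),
    )
    return matrix, records


def write_vcf(path: str, matrix: GenotypeMatrix, records: list[VariantRecord]) -> None:
    """Write the (filtered) matrix back to an uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_line(
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="Deleteriousness score">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality">')
    chroms = {r.chrom for r in records}
    for c in sorted(chroms):
        header.add_line(f"##contig=<ID={c}>")
    for s in matrix.sample_ids:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    idx_sorted = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    for i in idx_sorted:
        r = records[i]
        rec = out.new_record(
            contig=r.chrom,
            start=r.pos - 1,
            alleles=(r.ref_allele, *r.alt_allele.split(",")),
            id=r.variant_id if not r.variant_id.startswith(r.chrom + ":") else None,
        )
        rec.filter.add(r.filter_label)
        if r.mean_coverage is not None:
            rec.info["DP"] = int(round(r.mean_coverage * matrix.n_samples))
        if r.deleterious_score is not None:
            rec.info["CADD"] = float(r.deleterious_score)
        col = matrix.dosage[:, i]
        for j, s in enumerate(matrix.sample_ids):
            d = col[j]
            if np.isnan(d):
                rec.samples[s]["GT"] = (None, None)
            else:
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[int(d)]
        out.write(rec)
    out.close()


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    col = col[~np.isnan(col)]
    return int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one (no mid-p).  A
    monomorphic site returns 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # log-probabilities over admissible het counts via the standard recurrence,
    # normalized by logsumexp (log space avoids overflow at large n)
    het_min = n_rare % 2
    hets = list(range(het_min, n_rare + 1, 2))
    logp = np.empty(len(hets))
    logp[0] = 0.0
    for k, h in enumerate(hets[:-1]):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[k + 1] = logp[k] + (
            math.log(4.0 * rare_hom * common_hom) - math.log((h + 2.0) * (h + 1.0))
        )
    logp -= special.logsumexp(logp)
    obs = logp[hets.index(n_het)]
    p = float(np.exp(special.logsumexp(logp[logp <= obs + 1e-12])))
    return min(1.0, p)


def compute_maf(col: np.ndarray) -> float:
    """Minor allele frequency of a dosage column, folding to <= 0.5."""
    col = np.asarray(col, dtype=float)
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError("all genotypes missing")
    af = float(col.sum()) / (2.0 * col.size)
    return min(af, 1.0 - af)


def genotyping_rate(col: np.ndarray) -> float:
    col = np.asarray(col, dtype=float)
    return float(np.mean(~np.isnan(col)))


# Order in which rules are checked; the exclusion log records the first failure.
_RULES = ("not_biallelic", "not_pass", "genotyping_rate", "mean_coverage", "hwe")


def _first_failure(rec: VariantRecord, thr: QCThresholds) -> str | None:
    if thr.require_biallelic and not rec.biallelic:
        return "not_biallelic"
    if thr.require_pass and rec.filter_label != "PASS":
        return "not_pass"
    if rec.genotyping_rate < thr.min_genotyping_rate:
        return "genotyping_rate"
    if rec.mean_coverage is not None and rec.mean_coverage < thr.min_mean_coverage:
        return "mean_coverage"
    if rec.hwe_p < thr.min_hwe_p:
        return "hwe"
    return None


def filter_variants(
    records: list[VariantRecord],
    matrix: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
) -> tuple[list[VariantRecord], GenotypeMatrix, list[tuple[str, str]]]:
    """Apply the hard variant filters; returns kept records/matrix and an exclusion log.

    The log lists ``(variant_id, first_failing_rule)`` for each removed variant.
    Records with unknown coverage are not removed by the coverage rule.
    """
    thr = thresholds or QCThresholds()
    if [r.variant_id for r in records] != list(matrix.variant_ids):
        raise ValueError("records and matrix are not aligned")
    keep_mask = np.zeros(len(records), dtype=bool)
    log: list[tuple[str, str]] = []
    for i, rec in enumerate(records):
        rule = _first_failure(rec, thr)
        if rule is None:
            keep_mask[i] = True
        else:
            log.append((rec.variant_id, rule))
    kept_records = [replace(r, genes=set(r.genes)) for r, k in zip(records, keep_mask) if k]
    return kept_records, matrix.subset_variants(keep_mask), log


def recode(col: np.ndarray, coding: str) -> np.ndarray:
    """Re-express a dosage column under an inheritance coding.

    additive is the identity; dominant maps {0,1,2} to {0,1,1}; recessive to
    {0,0,1}.  Missing (NaN) propagates.
    """
    col = np.asarray(col, dtype=float)
    if coding == "additive":
        return col.copy()
    if coding == "dominant":
        return np.where(np.isnan(col), np.nan, (col >= 1).astype(float))
    if coding == "recessive":
        return np.where(np.isnan(col), np.nan, (col >= 2).astype(float))
    raise ValueError(f"unknown coding {coding!r}; expected one of {CODINGS}")
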
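"""Synthetic whole-exome cohort generator.

Emulates the statistical structure of a taxane-treated breast-cancer survivor cohort:
a samples x variants genotype matrix with a realistic minor-allele-frequency spectrum
(each variant in Hardy-Weinberg proportions marginally, optional LD blocks via a
Gaussian copula), four clinical covariates (age, BMI, taxane type, diabetes
treatment), and five correlated binary neuropathy symptoms generated from a logistic
liability with planted causal variant effects under additive / dominant / recessive
codings.  Per-symptom intercepts are calibrated by root-finding so the expected
prevalence matches the configured target.

Defaults reproduce the study conditions: 337 survivors, five symptoms with
moderate-severe prevalences between 12.1% and 27.6%, covariate moments from the
cohort characteristics table, and a variant pool of which roughly a third is common
(MAF >= 0.01).  The generator writes the same VCF + phenotype CSV formats the
pipeline consumes, plus a truth JSON for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .genotype_qc import (
    CODINGS,
    GenotypeMatrix,
    VariantRecord,
    compute_maf,
    hwe_exact_p,
    recode,
    write_vcf,
)

__all__ = [
    "SYMPTOMS",
    "CausalEffect",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
]

#: The five persistent neuropathy symptoms modelled, with target prevalence of
#: moderate-severe reports in the emulated cohort.
SYMPTOMS = (
    "cramps_in_feet",
    "difficulty_opening_jar",
    "numbness_in_feet",
    "tingling_in_feet",
    "difficulty_climbing_stairs",
)
_DEFAULT_PREVALENCES = (0.276, 0.261, 0.255, 0.246, 0.121)

#: Four-level symptom response scale (patient-reported outcome instrument style).
RESPONSE_LEVELS = ("not at all", "a little", "quite a bit", "very much")


@dataclass(frozen=True)
class CausalEffect:
    """A planted variant effect on one symptom's liability."""

    variant_index: int
    beta: float  # log-odds per encoded unit
    coding: str = "additive"

    def __post_init__(self) -> None:
        if self.coding not in CODINGS:
            raise ValueError(f"unknown coding {self.coding!r}")


@dataclass
class SimulationConfig:
    n_samples: int = 337
    n_variants: int = 20_000
    common_fraction: float = 0.316  # share of variants with MAF >= 0.01
    maf_fixed: float | None = None  # short-circuit the spectrum (calibration runs)
    n_causal_per_symptom: int = 10
    causal_beta: float = 0.8  # default |log-odds| for auto-planted effects
    causal_min_maf: float = 0.05  # auto-planted effects sit on detectable variants
    # pre-QC blemishes so the variant filters have work to do; qc_artifacts=False
    # gives a pristine matrix for statistical calibration runs
    qc_artifacts: bool = True
    genotype_missing_shape: tuple[float, float] = (0.3, 60.0)  # Beta per-variant rate
    low_quality_fraction: float = 0.02  # FILTER != PASS
    low_coverage_fraction: float = 0.02  # mean coverage < 10
    hwe_violation_fraction: float = 0.01  # fully inbred draws -> het deficit
    causal_effects: dict[str, list[CausalEffect]] | None = None
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "bmi": 0.0, "paclitaxel": 0.0, "diabetes": 0.0}
    )
    target_prevalences: tuple[float, ...] = _DEFAULT_PREVALENCES
    symptoms: tuple[str, ...] = SYMPTOMS
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_item_rate: float = 0.006  # ~2 of 337 item non-responses
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 < p < 1.0 for p in self.target_prevalences):
            raise ValueError("target prevalences must lie in (0,1)")
        if len(self.target_prevalences) != len(self.symptoms):
            raise ValueError("one target prevalence per symptom required")
        if self.n_causal_per_symptom > self.n_variants:
            raise ValueError("more causal variants requested than variants simulated")


@dataclass
class SyntheticCohort:
    matrix: GenotypeMatrix
    records: list[VariantRecord]
    phenotypes: pd.DataFrame  # index sample_id; covariates + per-symptom binary + responses
    truth: dict

    def write(self, vcf_path: str, phenotype_csv: str, truth_json: str) -> None:
        write_vcf(vcf_path, self.matrix, self.records)
        self.phenotypes.to_csv(phenotype_csv, index_label="sample_id")
        with open(truth_json, "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _draw_mafs(rng: np.random.Generator, m: int, common_fraction: float) -> np.ndarray:
    """MAF spectrum: common variants uniform on [0.01, 0.5], rare variants a
    Beta(1, 25)-shaped mass truncated below 0.01 (floored at 5e-4)."""
    is_common = rng.random(m) < common_fraction
    maf = np.empty(m)
    maf[is_common] = rng.uniform(0.01, 0.5, is_common.sum())
    n_rare = int((~is_common).sum())
    rare = rng.beta(1.0, 25.0, size=2 * n_rare + 16)
    rare = rare[rare < 0.01][:n_rare]
    while rare.size < n_rare:  # pragma: no cover - rejection nearly always fills
        extra = rng.beta(1.0, 25.0, size=2 * n_rare)
        rare = np.concatenate([rare, extra[extra < 0.01]])[:n_rare]
    maf[~is_common] = np.maximum(rare, 5e-4)
    return maf


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Draw genotypes variant by variant as two Bernoulli(MAF) allele draws per
    sample, so each variant is in Hardy-Weinberg proportions marginally.

    With ``ld_block_size > 1`` consecutive variants share a per-sample latent
    Gaussian factor with correlation ``ld_rho`` (Gaussian copula on the allele
    draws), giving positive within-block dosage correlation.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    if config.maf_fixed is not None:
        maf = np.full(m, float(config.maf_fixed))
    else:
        maf = _draw_mafs(rng, m, config.common_fraction)

    artifacts = config.qc_artifacts
    hwe_bad = (
        rng.random(m) < config.hwe_violation_fraction
        if artifacts
        else np.zeros(m, dtype=bool)
    )
    if config.ld_block_size <= 1 or config.ld_rho == 0.0:
        dosage = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    else:
        rho = config.ld_rho
        dosage = np.empty((n, m))
        for start in range(0, m, config.ld_block_size):
            stop = min(start + config.ld_block_size, m)
            width = stop - start
            # two allele draws per genotype, correlated within block via a
            # shared factor per (sample, allele copy)
            shared = rng.standard_normal((n, 2, 1))
            noise = rng.standard_normal((n, 2, width))
            z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            thresh = stats.norm.ppf(maf[start:stop])[None, None, :]
            dosage[:, start:stop] = (z < thresh).sum(axis=1)

    # inbred (F=1) draws at a small fraction of sites: hom-only genotypes with a
    # pronounced heterozygote deficit that the Hardy-Weinberg filter should catch
    if hwe_bad.any():
        k = int(hwe_bad.sum())
        dosage[:, hwe_bad] = 2.0 * rng.binomial(1, maf[None, hwe_bad], size=(n, k))

    if artifacts:
        # per-variant genotype missingness; occasionally heavy enough to fail QC
        a_m, b_m = config.genotype_missing_shape
        miss_rate = rng.beta(a_m, b_m, size=m)
        miss_mask = rng.random((n, m)) < miss_rate[None, :]
        dosage[miss_mask] = np.nan
        low_qual = rng.random(m) < config.low_quality_fraction
        low_cov = rng.random(m) < config.low_coverage_fraction
    else:
        low_qual = np.zeros(m, dtype=bool)
        low_cov = np.zeros(m, dtype=bool)

    records = []
    for j in range(m):
        col = dosage[:, j]
        called = col[~np.isnan(col)]
        rate = called.size / n
        if called.size:
            emp_maf = compute_maf(col)
            n_het = int(np.sum(called == 1))
            n_alt = int(np.sum(called == 2))
            hwe_p = hwe_exact_p(called.size - n_het - n_alt, n_het, n_alt)
        else:
            emp_maf, hwe_p = 0.0, 1.0
        cov = float(rng.uniform(2.0, 9.5)) if low_cov[j] else float(
            np.round(rng.gamma(20.0, 4.0), 1)
        )
        records.append(
            VariantRecord(
                variant_id=f"rs{1_000_000 + j}",
                chrom=f"chr{(j % 22) + 1}",
                pos=10_000 + 100 * (j // 22),
                ref_allele="A",
                alt_allele="G",
                filter_label="LowQual" if low_qual[j] else "PASS",
                mean_coverage=cov,
                genotyping_rate=rate,
                maf=float(emp_maf),
                hwe_p=float(hwe_p),
                genes={f"GENE{j // 4}"},  # ~4 variants per gene
            )
        )
    matrix = GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        variant_ids=[r.variant_id for r in records],
        dosage=dosage,
    )
    return matrix, records


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # moments match the survivor characteristics of the emulated cohort
    a, b = (31 - 62) / 10.0, (86 - 62) / 10.0
    age = stats.truncnorm.rvs(a, b, loc=62.0, scale=10.0, size=n, random_state=rng)
    bmi = rng.normal(26.9, 4.7, n)
    pac = (rng.random(n) < 0.445).astype(int)
    dia = (rng.random(n) < 0.047).astype(int)
    return pd.DataFrame(
        {"age": np.round(age, 1), "bmi": np.round(bmi, 1), "paclitaxel": pac, "diabetes": dia}
    )


def _default_effects(
    config: SimulationConfig, rng: np.random.Generator, matrix: GenotypeMatrix
) -> dict[str, list[CausalEffect]]:
    """Auto-plant effects: each symptom gets its own causal set, with the first
    quarter of indices shared across symptoms to induce symptom correlation.
    Effects land only on variants common enough (empirical MAF >= causal_min_maf)
    to be detectable at the cohort's sample size."""
    k = config.n_causal_per_symptom
    if k == 0:
        return {s: [] for s in config.symptoms}
    with np.errstate(invalid="ignore"):
        af = np.nanmean(matrix.dosage, axis=0) / 2.0
    emp_maf = np.minimum(af, 1.0 - af)
    pool = np.flatnonzero(emp_maf >= config.causal_min_maf)
    if pool.size < k:
        pool = np.argsort(-emp_maf)[: max(k, 1)]
    shared = rng.choice(pool, size=max(1, k // 4), replace=False)
    effects: dict[str, list[CausalEffect]] = {}
    for s in config.symptoms:
        own = rng.choice(pool, size=min(k, pool.size), replace=False)
        idx = np.unique(np.concatenate([shared, own]))[:k]
        codings = rng.choice(CODINGS, size=len(idx), p=[0.459, 0.353, 0.188])
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        effects[s] = [
            CausalEffect(int(i), float(sg * config.causal_beta), str(c))
            for i, sg, c in zip(idx, signs, codings)
        ]
    return effects


def _liability(
    matrix: GenotypeMatrix,
    covariates: pd.DataFrame,
    effects: list[CausalEffect],
    cov_effects: dict[str, float],
) -> np.ndarray:
    lin = np.zeros(matrix.n_samples)
    for eff in effects:
        g = recode(matrix.dosage[:, eff.variant_index], eff.coding)
        lin += eff.beta * np.nan_to_num(g)
    for name, gamma in cov_effects.items():
        if gamma:
            x = covariates[name].to_numpy(dtype=float)
            if name in ("age", "bmi"):
                x = x - x.mean()  # center so the intercept carries the prevalence
            lin += gamma * x
    return lin


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    def gap(b0: float) -> float:
        return float(np.mean(special.expit(b0 + lin))) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"target prevalence {target} unattainable for given effects")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate covariates and the five symptom outcomes from the logistic liability.

    Returns the phenotype table (covariates, four-level responses, binary
    indicators with NaN for missing items) and the planted truth (causal variant
    ids, betas, codings, calibrated intercepts).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = matrix.n_samples
    covariates = _draw_covariates(rng, n)
    covariates.index = pd.Index(matrix.sample_ids, name="sample_id")
    effects = config.causal_effects
    if effects is None:
        effects = _default_effects(config, rng, matrix)
    truth: dict = {"seed": config.seed, "symptoms": {}}
    pheno = covariates.copy()
    for s, target in zip(config.symptoms, config.target_prevalences):
        lin = _liability(matrix, covariates, effects.get(s, []), config.covariate_effects)
        b0 = _calibrate_intercept(lin, target)
        y = (rng.random(n) < special.expit(b0 + lin)).astype(float)
        miss = rng.random(n) < config.missing_item_rate
        y[miss] = np.nan
        # four-level self-report consistent with the dichotomization rule
        resp = np.where(
            np.isnan(y),
            "",
            np.where(
                y == 1,
                rng.choice(RESPONSE_LEVELS[2:], n),
                rng.choice(RESPONSE_LEVELS[:2], n),
            ),
        )
        pheno[s] = y
        pheno[s + "_response"] = resp
        truth["symptoms"][s] = {
            "intercept": b0,
            "target_prevalence": target,
            "causal": [
                {
                    "variant_id": matrix.variant_ids[e.variant_index],
                    "beta": e.beta,
                    "coding": e.coding,
                }
                for e in effects.get(s, [])
            ],
        }
    return pheno, truth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full genotype + phenotype simulation under a single seed."""
    rng = np.random.default_rng(config.seed)
    matrix, records = simulate_genotypes(config, rng)
    pheno, truth = simulate_phenotypes(matrix, config, rng)
    return SyntheticCohort(matrix=matrix, records=records, phenotypes=pheno, truth=truth)
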
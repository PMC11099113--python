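"""Per-SNV logistic association scan and permutation-based FDR thresholding.

Each variant is tested under the additive, dominant and recessive inheritance
codings with a two-parameter logistic model (intercept + encoded genotype); the
best coding is the one with the smallest Wald p, ties broken additive > dominant >
recessive.  The scan is genotype-only (covariates enter later, at model building)
and complete-case per variant.

The false-discovery-rate threshold is chosen by permuting the outcome labels
(genotype LD structure preserved), re-running the full scan per permutation, and
for each candidate p-value threshold t estimating

    FDR(t) = min(1, mean_over_permutations #{best_p <= t} / max(1, #{observed best_p <= t})).

The chosen threshold minimizes the estimated FDR, smallest t on ties.  The scan is
implemented on grouped sufficient statistics (per-genotype-category counts), which
makes the permutation loop a handful of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import fit_binary_counts
from .genotype_qc import CODINGS, GenotypeMatrix

__all__ = [
    "FDRCurve",
    "snv_scan",
    "permutation_fdr",
    "select_snvs",
    "DEFAULT_THRESHOLD_GRID",
]

#: Candidate p-value thresholds examined for the permutation FDR (the analysis
#: explored thresholds between 1e-5 and 5e-3).
DEFAULT_THRESHOLD_GRID = tuple(
    float(t)
    for t in np.concatenate(
        [
            np.array([1e-5, 2e-5, 5e-5, 1e-4, 2e-4]),
            np.arange(0.00025, 0.005001, 0.00025),
        ]
    )
)

# encoded genotype value per category (hom-ref, het, hom-alt) for each coding;
# duplicate x values make the grouped likelihood identical to merging categories
_X_BY_CODING = {
    "additive": np.array([0.0, 1.0, 2.0]),
    "dominant": np.array([0.0, 1.0, 1.0]),
    "recessive": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class FDRCurve:
    thresholds: np.ndarray
    observed_hits: np.ndarray
    mean_null_hits: np.ndarray
    fdr: np.ndarray
    n_permutations: int
    chosen_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed_hits": self.observed_hits,
                "mean_null_hits": self.mean_null_hits,
                "fdr": self.fdr,
            }
        )


def _category_indicators(dosage: np.ndarray) -> np.ndarray:
    """Stack of {0,1,2}-category indicator matrices, shape (3, n_samples, n_variants)."""
    return np.stack([(dosage == k).astype(float) for k in (0.0, 1.0, 2.0)])


def _scan_from_counts(
    n_cat: np.ndarray, y_cat: np.ndarray, min_count: int
) -> dict[str, np.ndarray]:
    """Run all three codings on grouped counts.

    ``n_cat``/``y_cat`` have shape (..., m, 3).  Returns per-coding p/beta/se/z
    arrays of shape (3, ..., m) ordered as CODINGS, plus the eligibility mask.
    """
    out_p, out_beta, out_se, out_z, out_ok = [], [], [], [], []
    nonzero = n_cat.sum(axis=-1) - n_cat[..., 0]  # carriers of >=1 alt allele
    for coding in CODINGS:
        x = _X_BY_CODING[coding]
        if coding == "recessive":
            m1 = n_cat[..., 2]
        else:
            m1 = nonzero
        m0 = n_cat.sum(axis=-1) - m1
        eligible = (np.minimum(m0, m1) >= min_count)
        fit = fit_binary_counts(n_cat, y_cat, x)
        ok = fit["ok"] & eligible
        out_p.append(np.where(ok, fit["p1"], 1.0))
        out_beta.append(np.where(ok, fit["beta1"], np.nan))
        out_se.append(np.where(ok, fit["se1"], np.nan))
        out_z.append(np.where(ok, fit["z1"], np.nan))
        out_ok.append(ok)
    return {
        "p": np.stack(out_p),
        "beta": np.stack(out_beta),
        "se": np.stack(out_se),
        "z": np.stack(out_z),
        "ok": np.stack(out_ok),
    }


def _grouped_counts(
    dosage: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant category totals and positive counts, complete-case in both the
    genotype and the outcome."""
    y = np.asarray(y, dtype=float)
    valid_y = ~np.isnan(y)
    ind = _category_indicators(dosage[valid_y])
    yv = np.nan_to_num(y[valid_y])
    n_cat = ind.sum(axis=1).T  # (m, 3)
    y_cat = np.einsum("kij,i->jk", ind, yv)
    return n_cat, y_cat


def snv_scan(
    matrix: GenotypeMatrix,
    outcome: np.ndarray,
    codings: tuple[str, ...] = CODINGS,
    min_count: int = 5,
) -> pd.DataFrame:
    """Scan every variant under each inheritance coding.

    Returns a DataFrame indexed by variant_id with per-coding ``{coding}_beta/se/
    z/p`` columns plus ``best_coding`` and ``best_p``.  A coding whose encoded
    minor category holds fewer than ``min_count`` samples is skipped (p = 1);
    a variant with no eligible coding gets best_p = 1.
    """
    for c in codings:
        if c not in CODINGS:
            raise ValueError(f"unknown coding {c!r}")
    n_cat, y_cat = _grouped_counts(matrix.dosage, outcome)
    res = _scan_from_counts(n_cat, y_cat, min_count)
    data: dict[str, np.ndarray] = {}
    coding_idx = [CODINGS.index(c) for c in codings]
    for c in codings:
        k = CODINGS.index(c)
        data[f"{c}_beta"] = res["beta"][k]
        data[f"{c}_se"] = res["se"][k]
        data[f"{c}_z"] = res["z"][k]
        data[f"{c}_p"] = res["p"][k]
    p_sub = res["p"][coding_idx]  # (len(codings), m)
    best_k = np.argmin(p_sub, axis=0)  # ties -> earliest coding (additive first)
    data["best_coding"] = np.array(codings)[best_k]
    data["best_p"] = p_sub[best_k, np.arange(p_sub.shape[1])]
    df = pd.DataFrame(data, index=pd.Index(matrix.variant_ids, name="variant_id"))
    return df


def permutation_fdr(
    matrix: GenotypeMatrix,
    outcome: np.ndarray,
    n_perm: int = 1000,
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
    seed: int = 0,
    min_count: int = 5,
    codings: tuple[str, ...] = CODINGS,
) -> FDRCurve:
    """Estimate the FDR curve over a grid of p-value thresholds by label permutation.

    Only the outcome vector is shuffled; the genotype matrix (and hence LD) is
    untouched.  Samples with a missing outcome are excluded before permuting.
    """
    if len(threshold_grid) == 0:
        raise ValueError("threshold grid is empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    grid = np.sort(np.asarray(threshold_grid, dtype=float))

    y = np.asarray(outcome, dtype=float)
    valid = ~np.isnan(y)
    dosage = matrix.dosage[valid]
    yv = y[valid]
    coding_idx = [CODINGS.index(c) for c in codings]

    ind = _category_indicators(dosage)  # (3, n, m)
    n_cat = ind.sum(axis=1).T
    y_cat = np.einsum("kij,i->jk", ind, yv)
    obs = _scan_from_counts(n_cat, y_cat, min_count)
    obs_best = obs["p"][coding_idx].min(axis=0)
    observed_hits = (obs_best[None, :] <= grid[:, None]).sum(axis=1)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(yv) for _ in range(n_perm)])  # (P, n)
    # positive counts per category under every permutation in three products
    y_cat_perm = np.stack(
        [perms @ ind[k] for k in range(3)], axis=-1
    )  # (P, m, 3)
    null = _scan_from_counts(np.broadcast_to(n_cat, y_cat_perm.shape), y_cat_perm, min_count)
    null_best = null["p"][coding_idx].min(axis=0)  # (P, m)
    null_hits = (null_best[:, :, None] <= grid[None, None, :]).sum(axis=1)  # (P, T)
    mean_null = null_hits.mean(axis=0)

    fdr = np.minimum(1.0, mean_null / np.maximum(1, observed_hits))
    # choose among thresholds that actually select something; an empty selection
    # has a trivial FDR of 0 but is useless downstream
    with_hits = observed_hits >= 1
    if with_hits.any():
        cand = np.where(with_hits, fdr, np.inf)
    else:
        cand = fdr
    chosen = float(grid[int(np.argmin(cand))])  # argmin takes the smallest t on ties
    return FDRCurve(
        thresholds=grid,
        observed_hits=observed_hits.astype(int),
        mean_null_hits=mean_null,
        fdr=fdr,
        n_permutations=n_perm,
        chosen_threshold=chosen,
    )


def select_snvs(
    results: pd.DataFrame,
    threshold: float,
    deleterious_scores: dict[str, float] | None = None,
    min_deleterious_score: float | None = None,
) -> set[str]:
    """Variants with best_p <= threshold, optionally intersected with a
    deleteriousness-score floor (score >= min_deleterious_score, default 13-style
    usage; variants without a score are dropped when the floor is active)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    chosen = set(results.index[results["best_p"] <= threshold])
    if min_deleterious_score is not None:
        scores = deleterious_scores or {}
        chosen = {
            v for v in chosen if scores.get(v) is not None and scores[v] >= min_deleterious_score
        }
    return chosen
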
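"""Staged construction of the per-symptom logistic prediction models.

The six stages compose their SNV feature set differently and share one fitting
path:

* **A1** — a literature panel of meta-analysis variants (additive coding).
* **A2** — a second, larger literature/pathway panel (same machinery as A1; known
  to overfit at realistic panel sizes — a documented failure mode, not an
  endpoint).
* **B1** — variants passing the permutation-FDR p-value threshold from the scan,
  each under its best-fitting inheritance coding.
* **B2** — a wider rank cutoff on scan p-values, combined with significant
  region-test genes, then filtered by gene-set over-representation.
* **C1** — B2's variants plus the literature variants significant at p < 0.05.
* **C2** — C1 refit on the features whose variable importance (|Wald z|) clears a
  threshold, plus any forced clinical covariates.

Every design matrix is intercept + encoded SNVs + covariates; exactly collinear
columns ("singularities") are removed greedily before fitting so the ML estimate
is unique, and an events-per-variable guard refuses fits with more features than
events (warning below 5 events per variable, as the emulated study's feature
counts require permitting low-EPV fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import LogisticFit, fit_logistic
from .genotype_qc import GenotypeMatrix, recode

__all__ = [
    "StageSpec",
    "FittedModel",
    "OverfitError",
    "remove_singularities",
    "assemble_design",
    "build_model",
    "variable_importance",
    "prune_by_vi",
    "grid_search_vi_threshold",
]

CLINICAL_COVARIATES = ("age", "paclitaxel", "bmi", "diabetes")


class OverfitError(RuntimeError):
    """More features than the events-per-variable floor permits."""


@dataclass
class StageSpec:
    """What goes into one model fit: variants (with coding) and covariates."""

    stage: str  # A1 | A2 | B1 | B2 | C1 | C2
    snvs: dict[str, str]  # variant_id -> coding
    covariates: tuple[str, ...] = CLINICAL_COVARIATES
    forced_covariates: tuple[str, ...] = ()
    vi_threshold: float | None = None
    ora_threshold: float | None = None


@dataclass
class FittedModel:
    stage: str
    feature_names: list[str]  # SNV ids (with coding suffix) then covariates
    snv_codings: dict[str, str]
    fit: LogisticFit
    dropped_singularities: list[str]
    vi: dict[str, float] = field(default_factory=dict)
    train_sample_ids: list[str] = field(default_factory=list)
    train_predictions: np.ndarray | None = None

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.fit.beta,
                "se": self.fit.se,
                "wald_z": self.fit.wald_z,
                "p": self.fit.p,
            },
            index=["intercept"] + self.feature_names,
        )

    def predict(
        self, matrix: GenotypeMatrix, covariates: pd.DataFrame
    ) -> np.ndarray:
        X, _, _ = assemble_design(
            matrix,
            covariates,
            self.snv_codings,
            tuple(f for f in self.feature_names if f in covariates.columns),
            feature_order=self.feature_names,
        )
        return self.fit.predict(np.nan_to_num(X))

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "features": self.feature_names,
            "snv_codings": self.snv_codings,
            "beta": [float(b) for b in self.fit.beta],
            "se": [float(s) for s in self.fit.se],
            "wald_z": [float(z) for z in self.fit.wald_z],
            "vi": {k: float(v) for k, v in sorted(self.vi.items())},
            "dropped_singularities": self.dropped_singularities,
            "converged": bool(self.fit.converged),
        }


def remove_singularities(
    X: np.ndarray, col_names: list[str], tol: float = 1e-10
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop exactly collinear columns, later-listed first, until full column rank.

    Greedy Gram-Schmidt sweep: a column is kept iff its residual after projection
    on the span of the already-kept columns exceeds ``tol`` relative to its norm.
    The intercept is expected in column 0 and is always kept.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    kept_idx: list[int] = []
    basis: list[np.ndarray] = []
    dropped: list[str] = []
    for j in range(k):
        col = X[:, j]
        resid = col.copy()
        for b in basis:
            resid = resid - (b @ resid) * b
        norm = np.linalg.norm(col)
        if norm == 0 or np.linalg.norm(resid) <= tol * max(norm, 1.0):
            dropped.append(col_names[j])
            continue
        basis.append(resid / np.linalg.norm(resid))
        kept_idx.append(j)
    return X[:, kept_idx], [col_names[j] for j in kept_idx], dropped


def assemble_design(
    matrix: GenotypeMatrix,
    covariates: pd.DataFrame,
    snv_codings: dict[str, str],
    covariate_names: tuple[str, ...],
    feature_order: list[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + encoded SNV columns + covariate columns, aligned on samples.

    Returns (X, feature names without intercept, column names with intercept).
    ``feature_order`` reproduces an existing model's column order exactly.
    """
    col_of = {v: i for i, v in enumerate(matrix.variant_ids)}
    if feature_order is None:
        feature_order = sorted(snv_codings) + [c for c in covariate_names]
    cols = [np.ones(matrix.n_samples)]
    names = []
    for f in feature_order:
        if f in snv_codings:
            if f not in col_of:
                raise KeyError(f"variant {f} absent from the genotype matrix")
            cols.append(recode(matrix.dosage[:, col_of[f]], snv_codings[f]))
        else:
            cols.append(covariates.loc[matrix.sample_ids, f].to_numpy(dtype=float))
        names.append(f)
    return np.column_stack(cols), names, ["intercept"] + names


def build_model(
    stage: str,
    matrix: GenotypeMatrix,
    covariates: pd.DataFrame,
    outcome: np.ndarray,
    snv_codings: dict[str, str],
    covariate_names: tuple[str, ...] = CLINICAL_COVARIATES,
    epv_floor: float = 1.0,
) -> FittedModel:
    """Assemble, de-singularize and fit one stage's logistic model.

    Samples with a missing outcome are excluded; rows with missing covariates or
    genotypes are dropped complete-case by the fit engine (and counted in the
    fit's ``n_obs``).  Raises :class:`OverfitError` when the feature count
    exceeds ``events / epv_floor``; warns when events per variable fall below 5.
    """
    y = np.asarray(outcome, dtype=float)
    X, names, _ = assemble_design(matrix, covariates, snv_codings, covariate_names)
    X_red, kept_names, dropped = remove_singularities(X, ["intercept"] + names)
    kept_features = [f for f in kept_names if f != "intercept"]

    valid = ~np.isnan(y)
    n_events = int(np.nansum(y[valid]))
    n_events = min(n_events, int(valid.sum()) - n_events)  # minority class count
    k = len(kept_features)
    if n_events <= 0:
        raise ValueError("outcome has no events")
    if k > n_events / max(epv_floor, 1e-9):
        raise OverfitError(
            f"{stage}: {k} features for {n_events} events violates the "
            f"events-per-variable floor of {epv_floor}"
        )
    if k > n_events / 5.0:
        warnings.warn(
            f"{stage}: {n_events / max(k, 1):.1f} events per variable (<5); "
            "coefficients will be unstable",
            stacklevel=2,
        )
    fit = fit_logistic(X_red, y, feature_names=kept_names)
    model = FittedModel(
        stage=stage,
        feature_names=kept_features,
        snv_codings={v: c for v, c in snv_codings.items() if v in kept_features},
        fit=fit,
        dropped_singularities=dropped,
        train_sample_ids=list(matrix.sample_ids),
    )
    model.train_predictions = fit.predict(np.nan_to_num(X_red))
    model.vi = variable_importance(model)
    return model


def variable_importance(model: FittedModel) -> dict[str, float]:
    """VI per non-intercept feature: the absolute Wald z of its coefficient.

    Undefined standard errors (separation) yield +inf so the feature ranks top
    and is visible in diagnostics rather than silently dropped.
    """
    vi = {}
    for name, z, se in zip(model.feature_names, model.fit.wald_z[1:], model.fit.se[1:]):
        vi[name] = float(np.abs(z)) if np.isfinite(se) and se > 0 else float("inf")
    return vi


def prune_by_vi(
    c1_model: FittedModel,
    vi_threshold: float,
    forced_covariates: tuple[str, ...] = (),
    covariate_names: tuple[str, ...] = CLINICAL_COVARIATES,
) -> StageSpec:
    """Stage spec for C2: C1 features with VI >= threshold (boundary inclusive)
    plus the forced covariates regardless of their VI."""
    keep = {f for f, v in c1_model.vi.items() if v >= vi_threshold}
    snvs = {v: c for v, c in c1_model.snv_codings.items() if v in keep}
    kept_covs = tuple(
        c for c in covariate_names if c in keep or c in forced_covariates
    )
    if not snvs and not kept_covs:
        raise ValueError(f"VI threshold {vi_threshold} leaves an empty model")
    return StageSpec(
        stage="C2",
        snvs=snvs,
        covariates=kept_covs,
        forced_covariates=tuple(forced_covariates),
        vi_threshold=vi_threshold,
    )


def grid_search_vi_threshold(
    c1_model: FittedModel,
    matrix: GenotypeMatrix,
    covariates: pd.DataFrame,
    outcome: np.ndarray,
    grid: tuple[float, ...],
    forced_covariates: tuple[str, ...] = (),
    covariate_names: tuple[str, ...] = CLINICAL_COVARIATES,
    epv_floor: float = 1.0,
) -> tuple[float, FittedModel]:
    """Pick the VI threshold whose refit C2 model maximizes training AUC, subject
    to the overfitting guard; ties go to the higher threshold (smaller model)."""
    from .evaluation import roc_auc

    best: tuple[float, float, FittedModel] | None = None
    for t in sorted(grid, reverse=True):
        try:
            spec = prune_by_vi(c1_model, t, forced_covariates, covariate_names)
            model = build_model(
                "C2", matrix, covariates, outcome, spec.snvs, spec.covariates, epv_floor
            )
        except (ValueError, OverfitError):
            continue
        auc = roc_auc(model.train_predictions, outcome)
        if best is None or auc > best[1] + 1e-12:
            best = (t, auc, model)
    if best is None:
        raise ValueError("no VI threshold in the grid yields a fittable model")
    return best[0], best[2]
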
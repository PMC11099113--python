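"""Logistic-regression fitting engine shared by the scan, region tests and model builder.

Two entry points:

* :func:`fit_logistic` — general maximum-likelihood fit of a binary outcome on an
  arbitrary design matrix by iteratively reweighted least squares (IRLS), with
  explicit convergence and separation diagnostics.
* :func:`fit_binary_counts` — the same two-parameter model (intercept + one encoded
  genotype) fitted from grouped sufficient statistics, vectorized across many
  variants/codings/permutations at once.  The grouped likelihood is identical to the
  row-level one because a single-predictor logistic model only sees the per-category
  counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = ["LogisticFit", "fit_logistic", "fit_binary_counts"]

# |beta| beyond this on a standardized-ish genotype/covariate scale means the
# likelihood is drifting to a boundary (quasi-separation).
_DIVERGENCE_GUARD = 15.0
_SCORE_TOL = 1e-8
_MAX_ITER = 50


@dataclass
class LogisticFit:
    """Result of a maximum-likelihood logistic fit."""

    beta: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    p: np.ndarray
    loglik: float
    converged: bool
    separation: bool
    n_obs: int
    n_iter: int
    feature_names: list[str] | None = field(default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return special.expit(np.asarray(X, dtype=float) @ self.beta)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1+exp(eta)), numerically via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _SCORE_TOL,
) -> LogisticFit:
    """Fit ``y ~ X`` (X must already contain the intercept column) by IRLS.

    Rows containing NaN in ``X`` or ``y`` are dropped (complete-case).  Convergence
    is declared when the maximum absolute score falls below ``tol``; separation when
    a coefficient runs past the divergence guard while the likelihood still improves.

    Raises
    ------
    ValueError
        If the outcome has zero variance or the design is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    X, y = X[keep], y[keep]
    n, k = X.shape
    if n == 0:
        raise ValueError("no complete-case observations")
    if y.min() == y.max():
        raise ValueError("outcome has zero variance after complete-case filtering")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(
            "rank-deficient design matrix; remove singular columns first"
        )

    beta = np.zeros(k)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ValueError("singular information matrix") from exc
        # step-halving to keep the likelihood monotone
        new_ll = -np.inf
        for half in range(8):
            cand = beta + step / (2**half)
            cand_eta = X @ cand
            new_ll = _loglik(y, cand_eta)
            if new_ll >= ll - 1e-12:
                beta, eta = cand, cand_eta
                break
        if new_ll > ll and np.max(np.abs(beta)) > _DIVERGENCE_GUARD:
            separation = True
        ll = max(ll, new_ll)
        if separation:
            break

    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        beta=beta,
        se=se,
        wald_z=z,
        p=np.clip(p, np.finfo(float).tiny, 1.0),
        loglik=ll,
        converged=converged,
        separation=separation,
        n_obs=n,
        n_iter=it,
        feature_names=feature_names,
    )


def fit_binary_counts(
    n_cat: np.ndarray,
    y_cat: np.ndarray,
    x_cat: np.ndarray,
    max_iter: int = 30,
    tol: float = _SCORE_TOL,
):
    """Vectorized Newton fit of ``logit P(y=1) = b0 + b1 * x`` from grouped counts.

    Parameters
    ----------
    n_cat, y_cat
        Arrays of shape ``(..., K)``: total and positive counts per genotype
        category.  Leading axes index independent fits.
    x_cat
        Encoded predictor value per category, shape ``(..., K)`` or ``(K,)``.

    Returns
    -------
    dict with ``beta0``, ``beta1``, ``se1``, ``z1``, ``p1``, ``ok`` arrays of the
    leading shape.  ``ok`` is False where the fit is degenerate (no variation in x
    or y) or diverged; there ``p1`` is 1.
    """
    n_cat = np.asarray(n_cat, dtype=float)
    y_cat = np.asarray(y_cat, dtype=float)
    x_cat = np.broadcast_to(np.asarray(x_cat, dtype=float), n_cat.shape)

    tot = n_cat.sum(axis=-1)
    pos = y_cat.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = np.where(tot > 0, (n_cat * x_cat).sum(axis=-1) / np.maximum(tot, 1), 0.0)
    x_var = (n_cat * (x_cat - xbar[..., None]) ** 2).sum(axis=-1)
    ok = (tot > 0) & (pos > 0) & (pos < tot) & (x_var > 0)

    b0 = np.zeros(tot.shape)
    b1 = np.zeros(tot.shape)
    for _ in range(max_iter):
        eta = b0[..., None] + b1[..., None] * x_cat
        mu = special.expit(eta)
        r = y_cat - n_cat * mu
        s0 = r.sum(axis=-1)
        s1 = (x_cat * r).sum(axis=-1)
        w = n_cat * mu * (1.0 - mu)
        i00 = w.sum(axis=-1)
        i01 = (x_cat * w).sum(axis=-1)
        i11 = (x_cat**2 * w).sum(axis=-1)
        det = i00 * i11 - i01**2
        good = ok & (det > 1e-12)
        if not np.any(good & (np.maximum(np.abs(s0), np.abs(s1)) >= tol)):
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            d0 = np.where(good, (i11 * s0 - i01 * s1) / det, 0.0)
            d1 = np.where(good, (i00 * s1 - i01 * s0) / det, 0.0)
        # damp huge steps; divergent fits get flagged below
        step_norm = np.maximum(np.abs(d0), np.abs(d1))
        damp = np.where(step_norm > 5.0, 5.0 / np.maximum(step_norm, 1e-300), 1.0)
        b0 = b0 + d0 * damp
        b1 = b1 + d1 * damp

    diverged = np.abs(b1) > _DIVERGENCE_GUARD
    ok = ok & ~diverged

    eta = b0[..., None] + b1[..., None] * x_cat
    mu = special.expit(eta)
    w = n_cat * mu * (1.0 - mu)
    i00 = w.sum(axis=-1)
    i01 = (x_cat * w).sum(axis=-1)
    i11 = (x_cat**2 * w).sum(axis=-1)
    det = i00 * i11 - i01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = np.where(det > 1e-12, i00 / det, np.inf)
    se1 = np.sqrt(var1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z1 = np.where(ok & np.isfinite(se1) & (se1 > 0), b1 / se1, 0.0)
    p1 = np.where(ok, 2.0 * stats.norm.sf(np.abs(z1)), 1.0)
    return {
        "beta0": b0,
        "beta1": np.where(ok, b1, 0.0),
        "se1": se1,
        "z1": z1,
        "p1": np.clip(p1, np.finfo(float).tiny, 1.0),
        "ok": ok,
    }
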
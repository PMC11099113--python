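"""Cohort splitting, ROC/AUC, cutoff selection and model acceptance.

AUC is computed by the rank (Mann-Whitney) formulation with ties contributing 1/2
and is reported in percent; its confidence interval is a stratified percentile
bootstrap.  The classification rule at a probability cutoff is ``p >= cutoff``
predicts the high-toxicity group.  A model is accepted when the training AUC
exceeds 80% and the test AUC exceeds 60% (both strict), the published acceptance
rule for these prediction models; the cutoff itself is tuned on the training
cohort to bring accuracy as close as possible to a target of about 80%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "split_cohort",
    "roc_auc",
    "auc_ci",
    "confusion_at_cutoff",
    "choose_cutoff",
    "welch_t",
    "accept_model",
    "evaluate",
]


@dataclass
class EvalReport:
    cohort: str
    auc: float  # percent
    auc_ci: tuple[float, float]
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    high_group_toxicity: float  # percent positives among predicted-high
    low_group_toxicity: float
    n_used: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["auc_ci"] = list(self.auc_ci)
        d["confusion"] = list(self.confusion)
        return d


def split_cohort(
    sample_ids: list[str],
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by: np.ndarray | None = None,
    n_test: int | None = None,
) -> tuple[list[str], list[str]]:
    """Random train/test split, deterministic under the seed.

    The test cohort holds floor((1 - fraction) * n) samples and the remainder
    trains.  ``n_test`` overrides that size directly — the emulated study's
    237/100 split of 337 survivors is not reachable from the 70/30 fractions by
    any rounding rule, so its round test-cohort size has to be stated explicitly.
    Optional stratification keeps per-stratum proportions within one sample of
    the global fraction (ignores ``n_test``).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0,1)")
    n = len(sample_ids)
    rng = np.random.default_rng(seed)
    ids = np.asarray(sample_ids, dtype=object)
    if stratify_by is None:
        if n_test is None:
            n_test = int(np.floor((1.0 - train_fraction) * n))
        if n_test <= 0 or n_test >= n:
            raise ValueError("split yields an empty cohort")
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
    else:
        strata = np.asarray(stratify_by)
        test_mask = np.zeros(n, dtype=bool)
        for val in np.unique(strata.astype(str)):
            members = np.flatnonzero(strata.astype(str) == val)
            k = int(np.floor((1.0 - train_fraction) * members.size))
            chosen = rng.permutation(members)[:k]
            test_mask[chosen] = True
        if not test_mask.any() or test_mask.all():
            raise ValueError("split yields an empty cohort")
        test_idx = np.flatnonzero(test_mask)
        train_idx = np.flatnonzero(~test_mask)
    return list(ids[train_idx]), list(ids[test_idx])


def _clean(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(labels))
    return scores[keep], labels[keep]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC in percent via mean rank of the positives; ties count 1/2."""
    scores, labels = _clean(scores, labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(100.0 * u / (n1 * n0))


def auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI of the AUC (percent scale).

    Resampling is within class, so degenerate one-class resamples cannot occur.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    scores, labels = _clean(scores, labels)
    rng = np.random.default_rng(seed)
    pos_scores = scores[labels == 1]
    neg_scores = scores[labels == 0]
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both outcome classes required for AUC CI")
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos_scores, pos_scores.size, replace=True)
        ns = rng.choice(neg_scores, neg_scores.size, replace=True)
        s = np.concatenate([ps, ns])
        y = np.concatenate([np.ones(ps.size), np.zeros(ns.size)])
        aucs[b] = roc_auc(s, y)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def confusion_at_cutoff(
    probabilities: np.ndarray, labels: np.ndarray, cutoff: float
) -> dict:
    """Confusion counts and percent metrics at ``probability >= cutoff`` = high risk.

    ``high/low_group_toxicity`` are the shares of observed positives inside the
    predicted-high and predicted-low groups (the risk-group summaries shown in
    probability violin plots).
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie strictly inside (0,1)")
    probabilities, labels = _clean(probabilities, labels)
    pred = probabilities >= cutoff
    obs = labels == 1
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    tn = int(np.sum(~pred & ~obs))
    fn = int(np.sum(~pred & obs))
    n = tp + fp + tn + fn
    sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    return {
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "n_used": n,
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": sens,
        "specificity": spec,
        "high_group_toxicity": 100.0 * tp / (tp + fp) if tp + fp else np.nan,
        "low_group_toxicity": 100.0 * fn / (fn + tn) if fn + tn else np.nan,
    }


def choose_cutoff(
    probabilities: np.ndarray,
    labels: np.ndarray,
    target_accuracy: float = 0.80,
) -> float:
    """Cutoff whose training accuracy lands "around" the target.

    The grid is the midpoints between consecutive unique predicted probabilities
    (plus near-0/near-1 guards).  Cutoffs reaching at least the target accuracy
    are preferred, closest to the target first — so a model that can do better
    than the target is not dragged below it; when no cutoff attains the target,
    the highest achievable accuracy wins.  Remaining ties are broken toward
    higher sensitivity, then toward the lower cutoff.
    """
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie in (0,1)")
    probabilities, labels = _clean(probabilities, labels)
    uniq = np.unique(probabilities)
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    eps = 1e-9
    grid = np.concatenate([[max(uniq[0] / 2.0, eps)], mids, [min((uniq[-1] + 1) / 2.0, 1 - eps)]])
    best = None
    for c in grid:
        m = confusion_at_cutoff(probabilities, labels, float(c))
        acc = m["accuracy"] / 100.0
        key = (
            acc < target_accuracy,  # at-or-above target preferred
            (acc - target_accuracy) if acc >= target_accuracy else (target_accuracy - acc),
            -(m["sensitivity"] if np.isfinite(m["sensitivity"]) else -1.0),
            c,
        )
        if best is None or key < best[0]:
            best = (key, float(c))
    return best[1]


def welch_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.array_equal(np.sort(a)[:1], np.sort(b)[:1]) and a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def accept_model(train_auc: float, test_auc: float) -> bool:
    """Acceptance rule: train AUC > 80% and test AUC > 60%, both strict."""
    return train_auc > 80.0 and test_auc > 60.0


def evaluate(
    probabilities: np.ndarray,
    labels: np.ndarray,
    cutoff: float,
    cohort: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Full per-cohort report: AUC with bootstrap CI plus cutoff metrics."""
    auc = roc_auc(probabilities, labels)
    ci = auc_ci(probabilities, labels, n_boot=n_boot, seed=seed)
    m = confusion_at_cutoff(probabilities, labels, cutoff)
    return EvalReport(
        cohort=cohort,
        auc=round(auc, 2),
        auc_ci=(round(ci[0], 2), round(ci[1], 2)),
        cutoff=cutoff,
        accuracy=round(m["accuracy"], 2),
        sensitivity=round(m["sensitivity"], 2) if np.isfinite(m["sensitivity"]) else float("nan"),
        specificity=round(m["specificity"], 2) if np.isfinite(m["specificity"]) else float("nan"),
        confusion=(m["TP"], m["FP"], m["TN"], m["FN"]),
        high_group_toxicity=round(m["high_group_toxicity"], 1)
        if np.isfinite(m["high_group_toxicity"])
        else float("nan"),
        low_group_toxicity=round(m["low_group_toxicity"], 1)
        if np.isfinite(m["low_group_toxicity"])
        else float("nan"),
        n_used=m["n_used"],
    )
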
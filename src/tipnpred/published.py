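"""Reference values reported for the original survivor cohort this pipeline emulates.

Two tables are carried as package data:

* :data:`COHORT` — survivor characteristics: cohort sizes, per-symptom counts of
  moderate-severe reports with item missingness, and clinical covariate moments.
  These drive the synthetic-cohort defaults and the prevalence-arithmetic checks.
* :data:`PERFORMANCE` — the reported performance of the literature-panel (A1) and
  final pruned (C2) models per symptom and cohort: AUC, cutoff, accuracy,
  sensitivity and specificity in percent, together with the class counts implied
  by the cohort table.  Used for confusion-matrix arithmetic-consistency checks
  (the identities TP = sens*positives, TN = spec*negatives, accuracy =
  (TP+TN)/n must all reproduce the printed numbers).

No model fitted by this package reads these values; they are consistency anchors
only.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["COHORT", "PERFORMANCE", "PerformanceRow", "class_counts", "reconstruct_confusion"]

#: Cohort characteristics: N=337 survivors, 237 train / 100 test.
COHORT = {
    "n_total": 337,
    "n_train": 237,
    "n_test": 100,
    "median_age": 62,
    "age_range": (31, 86),
    "bmi_mean": 26.9,
    "bmi_sd": 4.7,
    "paclitaxel_fraction": 0.445,
    "diabetes_fraction": 0.047,
    # symptom: (positives_total, n_missing_total, positives_train, positives_test)
    "symptoms": {
        "cramps_in_feet": (93, 2, 72, 21),
        "difficulty_opening_jar": (88, 0, 58, 30),
        "numbness_in_feet": (86, 2, 61, 25),
        "tingling_in_feet": (83, 2, 63, 20),
        "difficulty_climbing_stairs": (41, 0, 28, 13),
    },
    # printed prevalence percentages (one decimal)
    "prevalence_pct": {
        "cramps_in_feet": 27.6,
        "difficulty_opening_jar": 26.1,
        "numbness_in_feet": 25.5,
        "tingling_in_feet": 24.6,
        "difficulty_climbing_stairs": 12.1,
    },
}


@dataclass(frozen=True)
class PerformanceRow:
    symptom: str
    model: str  # "A1" or "C2"
    cohort: str  # "train" or "test"
    auc: float
    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float


PERFORMANCE: tuple[PerformanceRow, ...] = (
    PerformanceRow("numbness_in_feet", "A1", "train", 78.74, 0.291, 75.32, 70.49, 77.01),
    PerformanceRow("numbness_in_feet", "A1", "test", 67.09, 0.291, 73.00, 56.00, 78.67),
    PerformanceRow("tingling_in_feet", "A1", "train", 75.42, 0.497, 79.57, 33.33, 96.51),
    PerformanceRow("tingling_in_feet", "A1", "test", 56.31, 0.497, 75.00, 25.00, 87.50),
    PerformanceRow("cramps_in_feet", "A1", "train", 72.06, 0.463, 75.32, 33.33, 93.87),
    PerformanceRow("cramps_in_feet", "A1", "test", 51.48, 0.463, 68.00, 9.52, 83.54),
    PerformanceRow("difficulty_opening_jar", "A1", "train", 76.00, 0.411, 80.59, 48.28, 91.06),
    PerformanceRow("difficulty_opening_jar", "A1", "test", 55.71, 0.411, 63.00, 20.00, 81.43),
    PerformanceRow("difficulty_climbing_stairs", "A1", "train", 84.04, 0.394, 91.98, 42.86, 98.56),
    PerformanceRow("difficulty_climbing_stairs", "A1", "test", 32.80, 0.394, 78.00, 0.00, 89.66),
    PerformanceRow("numbness_in_feet", "C2", "train", 88.87, 0.324, 83.40, 77.05, 85.63),
    PerformanceRow("numbness_in_feet", "C2", "test", 72.91, 0.324, 74.00, 68.00, 76.00),
    PerformanceRow("tingling_in_feet", "C2", "train", 85.96, 0.346, 80.43, 77.78, 81.40),
    PerformanceRow("tingling_in_feet", "C2", "test", 60.88, 0.346, 69.00, 50.00, 73.75),
    PerformanceRow("cramps_in_feet", "C2", "train", 85.69, 0.448, 80.43, 65.28, 87.12),
    PerformanceRow("cramps_in_feet", "C2", "test", 42.98, 0.448, 52.00, 28.57, 58.23),
    PerformanceRow("difficulty_opening_jar", "C2", "train", 80.34, 0.670, 78.06, 15.52, 98.32),
    PerformanceRow("difficulty_opening_jar", "C2", "test", 51.71, 0.670, 67.00, 13.33, 90.00),
    PerformanceRow("difficulty_climbing_stairs", "C2", "train", 90.02, 0.644, 91.56, 39.29, 98.56),
    PerformanceRow("difficulty_climbing_stairs", "C2", "test", 42.88, 0.644, 75.00, 0.00, 86.21),
)


def class_counts(symptom: str, cohort: str) -> tuple[int, int]:
    """(positives, negatives) for a symptom in one cohort, excluding missing items.

    Item missingness in the reported cohort falls entirely in the training
    cohort, whose per-symptom denominators (e.g., 235 where two responses are
    missing) are required to reproduce the printed training accuracies.
    """
    _, n_missing, pos_train, pos_test = COHORT["symptoms"][symptom]
    if cohort == "train":
        n = COHORT["n_train"] - n_missing
        return pos_train, n - pos_train
    if cohort == "test":
        return pos_test, COHORT["n_test"] - pos_test
    raise ValueError(f"unknown cohort {cohort!r}")


def reconstruct_confusion(row: PerformanceRow) -> dict[str, float]:
    """Rebuild TP/FN/TN/FP from the printed sensitivity/specificity and the class
    counts, and recompute the accuracy the printed metrics imply."""
    pos, neg = class_counts(row.symptom, row.cohort)
    tp = round(row.sensitivity / 100.0 * pos)
    tn = round(row.specificity / 100.0 * neg)
    acc = 100.0 * (tp + tn) / (pos + neg)
    return {
        "TP": tp,
        "FN": pos - tp,
        "TN": tn,
        "FP": neg - tn,
        "n": pos + neg,
        "accuracy": round(acc, 2),
    }
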
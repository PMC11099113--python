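"""Logistic fit engine, per-SNV scan and permutation-FDR thresholding."""

import numpy as np
import pytest

from tipnpred._glm import fit_binary_counts, fit_logistic
from tipnpred.genotype_qc import GenotypeMatrix
from tipnpred.snv_association import permutation_fdr, select_snvs, snv_scan
from tipnpred.synthetic_cohort import SimulationConfig, simulate_genotypes


def newton_raphson_oracle(X, y, iters=200):
    """Independently coded Newton-Raphson for logistic ML (no IRLS shortcuts)."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        g = X.T @ (y - p)
        H = X.T @ (X * (p * (1 - p))[:, None])
        beta = beta + np.linalg.solve(H, g)
    return beta


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 25 + [0.0] * 75)
        fit = fit_logistic(np.ones((100, 1)), y)
        assert fit.beta[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
        assert fit.converged

    def test_perfect_separation_flagged(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert fit.separation

    def test_matches_newton_oracle_on_fixture(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        eta = 0.4 + 0.8 * X[:, 1] - 0.3 * X[:, 2]
        y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(float)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        fit = fit_logistic(X, y)
        oracle = newton_raphson_oracle(X, y)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-6)

    def test_zero_variance_outcome_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_rank_deficient_errors(self):
        X = np.column_stack([np.ones(30), np.arange(30.0), np.arange(30.0)])
        y = np.array([0.0, 1.0] * 15)
        with pytest.raises(ValueError):
            fit_logistic(X, y)

    def test_complete_case_drops_nan_rows(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = rng.integers(0, 2, 50).astype(float)
        X2 = X.copy()
        X2[0, 1] = np.nan
        fit_full = fit_logistic(X[1:], y[1:])
        fit_nan = fit_logistic(X2, y)
        np.testing.assert_allclose(fit_nan.beta, fit_full.beta, atol=1e-10)
        assert fit_nan.n_obs == 49


class TestGroupedFit:
    def test_agrees_with_rowwise_irls(self, rng):
        g = rng.integers(0, 3, 300).astype(float)
        y = (rng.random(300) < 1 / (1 + np.exp(-(-1.0 + 0.5 * g)))).astype(float)
        n_cat = np.array([[np.sum(g == k) for k in range(3)]], dtype=float)
        y_cat = np.array([[np.sum(y[g == k]) for k in range(3)]], dtype=float)
        grouped = fit_binary_counts(n_cat, y_cat, np.array([0.0, 1.0, 2.0]))
        rowwise = fit_logistic(np.column_stack([np.ones(300), g]), y)
        assert grouped["beta1"][0] == pytest.approx(rowwise.beta[1], abs=1e-7)
        assert grouped["se1"][0] == pytest.approx(rowwise.se[1], rel=1e-6)


def _matrix_from(dosage):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
        variant_ids=[f"v{j}" for j in range(dosage.shape[1])],
        dosage=dosage,
    )


class TestScan:
    def test_additive_p_consistent_with_full_fit(self, rng):
        dosage = rng.integers(0, 3, size=(250, 4)).astype(float)
        y = rng.integers(0, 2, 250).astype(float)
        scan = snv_scan(_matrix_from(dosage), y, min_count=1)
        for j in range(4):
            full = fit_logistic(np.column_stack([np.ones(250), dosage[:, j]]), y)
            assert scan.iloc[j]["additive_p"] == pytest.approx(full.p[1], rel=1e-6)

    def test_monomorphic_column_skipped(self):
        dosage = np.zeros((100, 1))
        y = np.array([0.0, 1.0] * 50)
        scan = snv_scan(_matrix_from(dosage), y)
        assert scan.iloc[0]["best_p"] == 1.0

    def test_min_count_floor_skips_sparse_coding(self):
        # only 2 hom-alt carriers: recessive coding must be skipped at floor 5
        dosage = np.array([2.0] * 2 + [1.0] * 40 + [0.0] * 158)
        y = np.array([1.0, 1.0] + [0.0, 1.0] * 20 + [0.0] * 148 + [1.0] * 10)
        scan = snv_scan(_matrix_from(dosage[:, None]), y, min_count=5)
        assert scan.iloc[0]["recessive_p"] == 1.0
        assert scan.iloc[0]["dominant_p"] < 1.0

    def test_tie_break_prefers_additive(self):
        # constructed so additive and dominant give identical fits (no hom-alt)
        dosage = np.array([0.0] * 60 + [1.0] * 60)
        y = np.array([0.0] * 40 + [1.0] * 20 + [0.0] * 20 + [1.0] * 40)
        scan = snv_scan(_matrix_from(dosage[:, None]), y)
        assert scan.iloc[0]["additive_p"] == pytest.approx(scan.iloc[0]["dominant_p"])
        assert scan.iloc[0]["best_coding"] == "additive"

    def test_planted_dominant_effect_recovered(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            g = rng.binomial(2, 0.3, 2000).astype(float)
            carrier = (g >= 1).astype(float)
            eta = -1.5 + 1.5 * carrier
            y = (rng.random(2000) < 1 / (1 + np.exp(-eta))).astype(float)
            scan = snv_scan(_matrix_from(g[:, None]), y)
            hits += scan.iloc[0]["best_coding"] == "dominant"
        assert hits >= 0.8 * n_seeds  # expected ~>=90%; slack for 30 seeds


@pytest.fixture(scope="module")
def null_matrix():
    cfg = SimulationConfig(n_samples=300, n_variants=400, seed=21)
    matrix, _ = simulate_genotypes(cfg)
    rng = np.random.default_rng(99)
    y = rng.binomial(1, 0.25, 300).astype(float)
    return matrix, y


class TestPermutationFdr:
    def test_reproducible_under_seed(self, null_matrix):
        matrix, y = null_matrix
        a = permutation_fdr(matrix, y, n_perm=30, seed=4)
        b = permutation_fdr(matrix, y, n_perm=30, seed=4)
        np.testing.assert_array_equal(a.fdr, b.fdr)
        assert a.chosen_threshold == b.chosen_threshold

    def test_fdr_rederivable_from_stored_fields(self, null_matrix):
        matrix, y = null_matrix
        c = permutation_fdr(matrix, y, n_perm=30, seed=4)
        re_fdr = np.minimum(1.0, c.mean_null_hits / np.maximum(1, c.observed_hits))
        np.testing.assert_allclose(c.fdr, re_fdr)
        assert np.all(np.diff(c.observed_hits) >= 0)

    def test_zero_observed_hits_definition(self):
        # under a hard null with an extreme threshold, fdr = mean_null/1 capped at 1
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(200, 50)).astype(float)
        y = rng.binomial(1, 0.3, 200).astype(float)
        c = permutation_fdr(
            _matrix_from(dosage), y, n_perm=50, threshold_grid=(1e-12,), seed=0
        )
        assert c.observed_hits[0] == 0
        assert c.fdr[0] == pytest.approx(min(1.0, c.mean_null_hits[0]))

    def test_empty_grid_errors(self, null_matrix):
        matrix, y = null_matrix
        with pytest.raises(ValueError):
            permutation_fdr(matrix, y, n_perm=5, threshold_grid=())


class TestSelectSnvs:
    def _results(self):
        import pandas as pd

        return pd.DataFrame(
            {"best_p": [0.0005, 0.001, 0.0015, 0.5, 1.0]},
            index=pd.Index([f"v{i}" for i in range(5)], name="variant_id"),
        )

    def test_threshold_boundary_inclusive(self):
        assert select_snvs(self._results(), 0.001) == {"v0", "v1"}

    def test_threshold_one_selects_all(self):
        assert len(select_snvs(self._results(), 1.0)) == 5

    def test_below_min_p_empty(self):
        assert select_snvs(self._results(), 1e-6) == set()

    def test_deleteriousness_subfilter(self):
        scores = {"v0": 20.0, "v1": 5.0}
        out = select_snvs(
            self._results(), 0.01, deleterious_scores=scores, min_deleterious_score=13.0
        )
        assert out == {"v0"}
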
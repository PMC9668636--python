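"""Covariate residualization, pooled t / Cohen's d, and permutation FDR."""

import itertools

import numpy as np
import pytest
from scipy import stats

from netharm import edgestats as es
from netharm.thresholding import ThresholdConfig, density_threshold


def make_edge_data(values, is_control, age=None, sex=None, edges=None):
    n = len(is_control)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return es.EdgeData(
        values=values,
        is_control=np.asarray(is_control, bool),
        age=np.asarray(age if age is not None else 60.0 + np.arange(n), float),
        sex=np.asarray(sex if sex is not None else np.arange(n) % 2, float),
        edges=edges or [(0, k + 1) for k in range(values.shape[1])],
    )


class TestResidualize:
    def test_orthogonal_covariates_reduce_to_centering(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=200)
        # age/sex independent of values: fitted slopes ~ 0, residuals ~ centered
        age = np.repeat([60.0, 70.0], 100)
        sex = np.tile([0.0, 1.0], 100)
        resid = es.residualize(values, age, sex)
        assert np.allclose(resid.mean(), 0.0, atol=1e-12)
        # slopes are estimated, so allow sampling slack around pure centering
        assert np.allclose(resid, values - values.mean(), atol=0.2)

    def test_perfect_linear_dependence_gives_zero_residuals(self):
        age = np.array([55.0, 60.0, 65.0, 70.0, 75.0, 80.0])
        values = 0.01 * age
        resid = es.residualize(values, age, np.array([0, 1, 0, 1, 0, 1.0]))
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_matches_normal_equations_solve(self):
        rng = np.random.default_rng(1)
        n = 50
        age = rng.uniform(50, 90, n)
        sex = rng.integers(0, 2, n).astype(float)
        values = 0.4 + 0.002 * age - 0.01 * sex + rng.normal(0, 0.05, n)
        design = np.column_stack([np.ones(n), age, sex])
        beta = np.linalg.solve(design.T @ design, design.T @ values)
        assert np.allclose(es.residualize(values, age, sex), values - design @ beta, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            es.residualize(np.ones(5), np.full(5, 70.0), np.zeros(5))


class TestTTestAndCohensD:
    def test_identical_means_give_zero(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        groups = np.array([True, True, False, False])
        assert es.edge_ttest(values, groups) == pytest.approx(0.0)
        assert es.cohens_d(values, groups) == pytest.approx(0.0)

    def test_hand_computed_pooled_t(self):
        """controls {2,4}, patients {1,3}: mean diff 1, pooled sd sqrt(2),
        t = 1 / (sqrt(2) * sqrt(1/2 + 1/2)) = 0.7071."""
        values = np.array([2.0, 4.0, 1.0, 3.0])
        groups = np.array([True, True, False, False])
        assert es.edge_ttest(values, groups) == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert es.cohens_d(values, groups) == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        groups = np.array([True] * 14 + [False] * 16)
        expected = stats.ttest_ind(values[groups], values[~groups], equal_var=True).statistic
        assert es.edge_ttest(values, groups) == pytest.approx(expected, abs=1e-10)

    def test_d_equals_t_scaled_by_sample_sizes(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=25)
        groups = np.array([True] * 10 + [False] * 15)
        t = es.edge_ttest(values, groups)
        d = es.cohens_d(values, groups)
        assert d == pytest.approx(t * np.sqrt(1 / 10 + 1 / 15), abs=1e-12)

    def test_zero_pooled_variance_flagged(self):
        values = np.array([1.0, 1.0, 1.0, 1.0])
        groups = np.array([True, True, False, False])
        with pytest.raises(ValueError, match="pooled"):
            es.edge_ttest(values, groups)

    def test_fewer_than_two_per_group_rejected(self):
        with pytest.raises(ValueError, match="2 usable"):
            es.edge_ttest(np.array([1.0, 2.0, 3.0]), np.array([True, False, False]))


class TestPermutationFDR:
    def test_matches_exhaustive_enumeration_on_3v3(self):
        """3 vs 3 subjects: the empirical permutation p converges to the exact
        p over all C(6,3)=20 group splits."""
        values = np.array([0.50, 0.47, 0.53, 0.40, 0.38, 0.42])
        is_control = np.array([True, True, True, False, False, False])
        age = 60.0 + np.arange(6)
        sex = np.arange(6) % 2
        # labels are permuted with residuals held fixed, so the oracle
        # enumerates splits of the residualized values
        resid = es.residualize(values, age, sex.astype(float))
        t_obs = es.edge_ttest(resid, is_control)
        exceed = total = 0
        for combo in itertools.combinations(range(6), 3):
            labels = np.zeros(6, bool)
            labels[list(combo)] = True
            total += 1
            if abs(es.edge_ttest(resid, labels)) >= abs(t_obs) - 1e-12:
                exceed += 1
        exact_p = exceed / total
        data = make_edge_data(values, is_control)
        res = es.permutation_fdr(data, n_perm=4000, seed=7)
        p_hat = res.table["p_perm"].iloc[0]
        # standard error of the empirical p at 4000 draws
        se = np.sqrt(exact_p * (1 - exact_p) / 4000)
        assert p_hat == pytest.approx(exact_p, abs=max(4 * se, 0.01))

    def test_null_type_one_error_calibrated(self):
        """1000 null edges: fraction with p < 0.05 is 0.05 +/- 0.02."""
        rng = np.random.default_rng(11)
        n_sub, n_edges = 40, 1000
        values = rng.normal(size=(n_sub, n_edges))
        data = make_edge_data(
            values,
            is_control=np.array([True] * 20 + [False] * 20),
            age=rng.uniform(50, 90, n_sub),
        )
        res = es.permutation_fdr(data, n_perm=1000, seed=5)
        frac = float((res.table["p_perm"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_null_pvalues_super_uniform(self):
        """Kolmogorov-Smirnov sanity check: null permutation p-values do not
        deviate grossly from uniform."""
        rng = np.random.default_rng(13)
        values = rng.normal(size=(30, 400))
        data = make_edge_data(
            values,
            is_control=np.array([True] * 15 + [False] * 15),
            age=rng.uniform(50, 90, 30),
        )
        res = es.permutation_fdr(data, n_perm=1000, seed=3)
        ks = stats.kstest(res.table["p_perm"], "uniform")
        assert ks.statistic < 0.08

    def test_strong_shift_on_all_edges_survives_fdr(self):
        rng = np.random.default_rng(17)
        n_edges = 50
        values = rng.normal(size=(60, n_edges))
        values[:30] += 2.0  # controls shifted up on every edge
        data = make_edge_data(
            values,
            is_control=np.array([True] * 30 + [False] * 30),
            age=rng.uniform(50, 90, 60),
        )
        res = es.permutation_fdr(data, n_perm=1000, seed=1)
        assert np.all(res.table["q_fdr"] < 0.05)

    def test_subjects_without_edge_are_excluded(self):
        """Sample sizes per edge count only subjects possessing the edge."""
        values = np.full((8, 1), np.nan)
        values[[0, 1, 2, 4, 5], 0] = [0.5, 0.52, 0.48, 0.40, 0.42]
        data = make_edge_data(
            values, is_control=np.array([True] * 4 + [False] * 4),
            age=np.arange(8, dtype=float),
        )
        res = es.permutation_fdr(data, n_perm=100, seed=2)
        row = res.table.iloc[0]
        assert row["n_control"] == 3 and row["n_patient"] == 2

    def test_too_few_permutations_rejected(self):
        data = make_edge_data(np.arange(6.0), np.array([True] * 3 + [False] * 3))
        with pytest.raises(ValueError, match="at least 100"):
            es.permutation_fdr(data, n_perm=50, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(20, 30))
        data = make_edge_data(
            values, is_control=np.array([True] * 10 + [False] * 10),
            age=rng.uniform(50, 90, 20),
        )
        a = es.permutation_fdr(data, n_perm=200, seed=9)
        b = es.permutation_fdr(data, n_perm=200, seed=9)
        assert a.table.equals(b.table)


class TestStageDetections:
    def _results(self, edges, d, q, testable=None):
        import pandas as pd

        n = len(edges)
        table = pd.DataFrame(
            {
                "node_i": [e[0] for e in edges],
                "node_j": [e[1] for e in edges],
                "n_control": 10,
                "n_patient": 10,
                "t": d,
                "d": d,
                "p_perm": q,
                "q_fdr": q,
                "testable": testable if testable is not None else [True] * n,
            }
        )
        return es.EdgewiseResults(table=table, n_perm=1000, seed=0)

    def test_empty_mask_empties_downstream_stages(self):
        edges = [(0, 1), (1, 2)]
        res = self._results(edges, d=[1.2, 1.5], q=[0.01, 0.01])
        mask = density_threshold(np.zeros((5, 5)), ThresholdConfig(density=0.5))
        det = es.stage_detections(res, mask)
        assert det.large_effect == set(edges)
        assert det.surviving_threshold == set() and det.surviving_fdr == set()

    def test_all_small_effects_give_empty_sets(self):
        edges = [(0, 1), (1, 2)]
        res = self._results(edges, d=[0.3, -0.5], q=[0.001, 0.001])
        prob = np.zeros((5, 5))
        prob[0, 1] = prob[1, 0] = 0.9
        mask = density_threshold(prob, ThresholdConfig(density=0.5))
        det = es.stage_detections(res, mask)
        assert det.large_effect == det.surviving_threshold == det.surviving_fdr == set()

    def test_detection_sets_nest(self):
        rng = np.random.default_rng(5)
        edges = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        d = rng.normal(0.8, 0.5, len(edges))
        q = rng.uniform(0, 0.2, len(edges))
        res = self._results(edges, d=d, q=q)
        raw = np.triu(rng.uniform(0, 1, (8, 8)), 1)
        mask = density_threshold(raw + raw.T, ThresholdConfig(density=0.4))
        det = es.stage_detections(res, mask)
        assert det.surviving_fdr <= det.surviving_threshold <= det.large_effect

    def test_signed_versus_absolute_gating(self):
        edges = [(0, 1), (1, 2)]
        res = self._results(edges, d=[1.0, -1.0], q=[0.01, 0.01])
        prob = np.ones((5, 5)) - np.eye(5)
        mask = density_threshold(prob, ThresholdConfig(density=1.0))
        assert es.stage_detections(res, mask, signed=True).large_effect == {(0, 1)}
        assert es.stage_detections(res, mask, signed=False).large_effect == {(0, 1), (1, 2)}
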
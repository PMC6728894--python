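"""AUC summaries, permutation tests, NBS, and adjusted correlations."""

import numpy as np
import pytest

import oracles
from fcgraph import (
    covariate_adjusted_correlation,
    edgewise_tests,
    metric_auc,
    nodal_tests,
    permutation_test,
)

GRID = np.round(np.arange(0.10, 0.401, 0.01), 2)


class TestMetricAuc:
    def test_constant_curve(self):
        assert metric_auc(np.full(31, 2.5), GRID) == pytest.approx(0.30 * 2.5)

    def test_linear_curve_trapezoid_exact(self):
        vals = np.linspace(1.0, 3.0, 31)
        assert metric_auc(vals, GRID) == pytest.approx(0.30 * 2.0, abs=1e-12)

    def test_matches_knotwise_oracle(self, rng):
        vals = rng.standard_normal(31)
        assert metric_auc(vals, GRID) == pytest.approx(
            oracles.trapezoid(vals, GRID), abs=1e-12)

    def test_nonfinite_value_lists_costs(self):
        vals = np.ones(31)
        vals[5] = np.nan
        with pytest.raises(ValueError, match="0.15"):
            metric_auc(vals, GRID)


class TestPermutationTest:
    def test_identical_multisets_give_high_p(self):
        a = np.arange(1.0, 11.0)
        res = permutation_test(a, a.copy(), n_perm=999, seed=1)
        assert res.t_observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_perm > 0.9

    def test_total_separation_attains_minimum_p(self, rng):
        a = 10.0 + 0.1 * rng.standard_normal(15)
        b = 0.1 * rng.standard_normal(15)
        res = permutation_test(a, b, n_perm=999, seed=2)
        assert res.p_perm == pytest.approx(1.0 / 1000.0)
        assert res.direction == "decreased"  # group B below group A

    def test_p_bounded_below(self, rng):
        res = permutation_test(rng.normal(5, 1, 10), rng.normal(0, 1, 10),
                               n_perm=99, seed=3)
        assert res.p_perm >= 1.0 / 100.0

    def test_label_exchange_symmetry(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 14)
        r1 = permutation_test(a, b, n_perm=2000, seed=7)
        r2 = permutation_test(b, a, n_perm=2000, seed=7)
        # two-sided: swapping labels flips t but leaves p essentially unchanged
        assert r1.t_observed == pytest.approx(-r2.t_observed, abs=1e-12)
        assert abs(r1.p_perm - r2.p_perm) < 0.02

    def test_zero_pooled_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            permutation_test(np.ones(5), np.ones(5), n_perm=99, seed=1)

    def test_type_i_error_calibrated_quick(self, rng):
        # a fast 200-rep check; the full 500-rep calibration runs elsewhere
        hits = 0
        for rep in range(200):
            a = rng.standard_normal(15)
            b = rng.standard_normal(15)
            hits += permutation_test(a, b, n_perm=199, seed=rep).p_perm < 0.05
        assert 0.02 <= hits / 200 <= 0.09


class TestNodalTests:
    def test_single_region_reduces_to_permutation_test(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        single = nodal_tests(vals[:, None], 8, ["r1"], n_perm=999, seed=5)[0]
        ref = permutation_test(vals[:8], vals[8:], n_perm=999, seed=5)
        assert single.t_observed == pytest.approx(ref.t_observed, abs=1e-12)
        assert single.p_perm == pytest.approx(ref.p_perm, abs=1e-12)

    def test_recovers_planted_regions(self, rng):
        # 5 regions of 30 carry a planted group difference
        planted = [2, 7, 11, 19, 23]
        recovered = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal((24, 30))
            x[12:, planted] += 1.6
            res = nodal_tests(x, 12, [f"r{i}" for i in range(30)],
                              n_perm=499, seed=seed)
            hits = {int(t.metric[1:]) for t in res if t.significant}
            recovered += len(hits & set(planted)) >= 4
            for t in res:
                if t.significant and int(t.metric[1:]) in planted:
                    assert t.direction == "increased"
        assert recovered >= 16  # power >= 0.8 over 20 seeds

    def test_null_table_false_positive_rate(self):
        # expected false positives ~ alpha * n_regions, binomial 95% band
        n_regions, alpha, reps = 40, 0.05, 30
        fps = []
        for seed in range(reps):
            r = np.random.default_rng(10_000 + seed)
            x = r.standard_normal((20, n_regions))
            res = nodal_tests(x, 10, [f"r{i}" for i in range(n_regions)],
                              n_perm=199, alpha=alpha, seed=seed)
            fps.append(sum(t.significant for t in res))
        mean_fp = np.mean(fps)
        se = np.sqrt(alpha * (1 - alpha) * n_regions / reps)
        assert abs(mean_fp - alpha * n_regions) < 3 * se + 0.5


class TestEdgewise:
    def labels(self, n):
        return [f"r{i}" for i in range(n)]

    def edge_cols(self, n):
        return np.triu_indices(n, k=1)

    def test_no_suprathreshold_edges_empty_list(self, rng):
        n_rois = 10
        z = rng.standard_normal((16, 45)) * 0.01
        out = edgewise_tests(z, 8, self.labels(n_rois), n_perm=99, seed=1)
        assert out == []

    def test_nbs_recovers_planted_component(self):
        # a connected 6-edge path among regions 0..6 carries the group effect
        n_rois, n, n_a = 20, 30, 15
        iu, ju = self.edge_cols(n_rois)
        planted = [k for k in range(iu.size)
                   if (iu[k], ju[k]) in {(0, 1), (1, 2), (2, 3), (3, 4),
                                         (4, 5), (5, 6)}]
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            z = 0.3 * r.standard_normal((n, iu.size))
            z[n_a:, planted] += 0.55
            out = edgewise_tests(z, n_a, self.labels(n_rois), primary_p=0.005,
                                 correction="nbs", n_perm=199, seed=seed)
            found = {(f.region_i, f.region_j) for f in out}
            want = {(f"r{iu[k]}", f"r{ju[k]}") for k in planted}
            hits += len(found & want) >= 5
        assert hits >= 16

    def test_bonferroni_mode_extreme_edge(self, rng):
        n_rois = 8
        iu, ju = self.edge_cols(n_rois)
        z = 0.1 * rng.standard_normal((40, iu.size))
        z[20:, 3] += 2.0  # one enormous effect
        out = edgewise_tests(z, 20, self.labels(n_rois),
                             correction="bonferroni", n_perm=99, seed=4)
        assert any((f.region_i, f.region_j) == (f"r{iu[3]}", f"r{ju[3]}")
                   for f in out)
        assert all(f.p < 0.05 for f in out)

    def test_directions_signed_per_edge(self, rng):
        n_rois = 8
        iu, ju = self.edge_cols(n_rois)
        z = 0.1 * rng.standard_normal((40, iu.size))
        z[20:, 0] += 2.0
        z[20:, 5] -= 2.0
        out = edgewise_tests(z, 20, self.labels(n_rois),
                             correction="bonferroni", n_perm=99, seed=4)
        byedge = {(f.region_i, f.region_j): f.direction for f in out}
        assert byedge[(f"r{iu[0]}", f"r{ju[0]}")] == "increased"
        assert byedge[(f"r{iu[5]}", f"r{ju[5]}")] == "decreased"


class TestAdjustedCorrelation:
    def test_exact_negative_relationship(self, rng):
        n = 20
        behavior = rng.standard_normal(n)
        metric = -2.0 * behavior
        q, _ = np.linalg.qr(np.column_stack(
            [np.ones(n), behavior, rng.standard_normal((n, 2))]))
        covs = q[:, 2:4]  # orthogonal to both variables
        r, p = covariate_adjusted_correlation(metric, behavior, covs)
        assert r == pytest.approx(-1.0, abs=1e-10)

    def test_matches_two_stage_least_squares_oracle(self, rng):
        n = 25
        covs = rng.standard_normal((n, 2))
        y1 = rng.standard_normal(n) + 0.5 * covs[:, 0]
        y2 = rng.standard_normal(n) - 0.3 * covs[:, 1]
        design = np.column_stack([np.ones(n), covs])
        r1 = oracles.ols_residuals_normal_equations(y1, design)
        r2 = oracles.ols_residuals_normal_equations(y2, design)
        expected = np.corrcoef(r1, r2)[0, 1]
        r, _ = covariate_adjusted_correlation(y1, y2, covs)
        assert r == pytest.approx(expected, abs=1e-10)

    def test_null_rejection_rate(self):
        hits = 0
        reps = 500
        for seed in range(reps):
            r = np.random.default_rng(seed)
            n = 30
            covs = r.standard_normal((n, 2))
            y1, y2 = r.standard_normal(n), r.standard_normal(n)
            _, p = covariate_adjusted_correlation(y1, y2, covs)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_rank_deficient_covariates_error(self, rng):
        n = 15
        c = rng.standard_normal((n, 1))
        covs = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="rank"):
            covariate_adjusted_correlation(rng.standard_normal(n),
                                           rng.standard_normal(n), covs)

    def test_too_few_observations_error(self, rng):
        with pytest.raises(ValueError, match="observations"):
            covariate_adjusted_correlation(np.ones(4), np.ones(4),
                                           rng.standard_normal((4, 2)))
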
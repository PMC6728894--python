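"""Synthetic-cohort generator: covariance structure, sampling, determinism."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fcgraph import (
    CohortSpec,
    build_group_covariance,
    simulate_cohort,
    simulate_subject,
)
from fcgraph.synthdata import module_partition


def spec(**kw):
    base = dict(n_group_a=2, n_group_b=2, n_rois=20, n_timepoints=50,
                n_modules=4, within_module_corr=0.3, between_module_corr=0.05,
                seed=7)
    base.update(kw)
    return CohortSpec(**base)


class TestCohortSpec:
    def test_rejects_between_at_least_within(self):
        with pytest.raises(ValueError, match="modular"):
            spec(within_module_corr=0.2, between_module_corr=0.2)

    def test_rejects_bad_deficit(self):
        with pytest.raises(ValueError):
            spec(clustering_deficit=1.0)

    @given(st.integers(2, 200), st.integers(1, 20))
    def test_module_partition_covers_all_rois(self, n_rois, n_modules):
        if n_modules > n_rois:
            return
        labels = module_partition(n_rois, n_modules)
        assert labels.size == n_rois
        assert set(labels) == set(range(n_modules))
        sizes = np.bincount(labels)
        # near-equal: all but the last module have the floor size
        assert np.all(sizes[:-1] == n_rois // n_modules)


class TestGroupCovariance:
    def test_group_b_without_deficit_equals_group_a(self):
        s = spec(clustering_deficit=0.0)
        a = build_group_covariance(s, "A")
        b = build_group_covariance(s, "B", duration=None)
        np.testing.assert_array_equal(a, b)

    def test_single_module_is_equicorrelation(self):
        s = spec(n_modules=1, within_module_corr=0.3)
        c = build_group_covariance(s, "A")
        off = ~np.eye(20, dtype=bool)
        assert np.all(c[off] == 0.3)
        assert np.all(np.diag(c) == 1.0)

    def test_deficit_scales_within_module_entries(self):
        # element-wise oracle: within 0.3 scaled by (1 - 0.2) -> 0.24
        s = spec(clustering_deficit=0.2, within_module_corr=0.3)
        c = build_group_covariance(s, "B")
        labels = module_partition(20, 4)
        expected = np.where(labels[:, None] == labels[None, :], 0.24, 0.05)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_duration_attenuates_further_and_floors_at_between(self):
        s = spec(clustering_deficit=0.2, duration_effect=0.05)
        c4 = build_group_covariance(s, "B", duration=4.0)
        labels = module_partition(20, 4)
        within = labels[:, None] == labels[None, :]
        np.fill_diagonal(within, False)
        assert np.allclose(c4[within], 0.3 * 0.8 * (1 - 0.05 * 4.0))
        c_huge = build_group_covariance(s, "B", duration=1000.0)
        assert np.allclose(c_huge[within], 0.05)  # floored at between

    @given(st.floats(0.1, 0.6), st.floats(0.0, 0.09), st.integers(1, 6))
    def test_covariance_is_psd_and_symmetric(self, within, between, n_modules):
        s = spec(within_module_corr=within, between_module_corr=between,
                 n_modules=n_modules)
        c = build_group_covariance(s, "A")
        assert np.allclose(c, c.T)
        assert np.linalg.eigvalsh(c).min() >= -1e-10


class TestSimulateSubject:
    def test_identity_covariance_gives_near_zero_correlations(self):
        x = simulate_subject(np.eye(20), 10000, noise_sd=0.0, seed=3)
        r = np.corrcoef(x, rowvar=False)
        off = ~np.eye(20, dtype=bool)
        assert np.max(np.abs(r[off])) < 0.05  # ~1/sqrt(T) sampling bound

    def test_same_seed_is_bit_identical(self):
        a = simulate_subject(np.eye(5), 100, 0.5, seed=11)
        b = simulate_subject(np.eye(5), 100, 0.5, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_block_correlation_matches_attenuation_closed_form(self):
        # standardized signal + noise: realized corr = cov / (1 + noise_sd^2)
        s = spec(n_rois=10, n_modules=2, within_module_corr=0.6,
                 between_module_corr=0.05)
        cov = build_group_covariance(s, "A")
        noise_sd = 0.5
        x = simulate_subject(cov, 5000, noise_sd, seed=5)
        r = np.corrcoef(x, rowvar=False)
        within = module_partition(10, 2)[:, None] == module_partition(10, 2)[None, :]
        np.fill_diagonal(within, False)
        target = 0.6 / (1 + noise_sd**2)
        assert abs(r[within].mean() - target) < 0.05

    def test_output_is_column_standardized(self, rng):
        x = simulate_subject(np.eye(6), 200, 0.3, seed=9)
        np.testing.assert_allclose(x.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(x.std(axis=0), 1, atol=1e-12)

    def test_too_few_timepoints_is_error(self):
        with pytest.raises(ValueError, match="time points"):
            simulate_subject(np.eye(4), 2, 0.1, seed=1)


class TestSimulateCohort:
    def test_counts_and_labels(self):
        records, cov = simulate_cohort(spec(n_group_a=3, n_group_b=2))
        assert len(records) == 5
        assert sum(r.group == "A" for r in records) == 3
        assert (cov["group"] == "A").sum() == 3
        for r in records:
            assert r.timeseries.values.shape == (50, 20)
            assert np.all(np.isfinite(r.timeseries.values))

    def test_durations_only_for_group_b(self):
        _, cov = simulate_cohort(spec())
        assert cov.loc[cov.group == "A", "duration_years"].isna().all()
        b = cov.loc[cov.group == "B", "duration_years"]
        assert (b > 0).all()

    def test_identical_seed_identical_cohort(self):
        r1, c1 = simulate_cohort(spec(seed=123))
        r2, c2 = simulate_cohort(spec(seed=123))
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.timeseries.values, b.timeseries.values)
        assert c1.equals(c2)

    def test_different_seed_differs(self):
        r1, _ = simulate_cohort(spec(seed=1))
        r2, _ = simulate_cohort(spec(seed=2))
        assert not np.array_equal(r1[0].timeseries.values,
                                  r2[0].timeseries.values)

    def test_covariates_round_trip_tsv(self, tmp_path):
        from fcgraph.io import read_covariates, write_covariates

        _, cov = simulate_cohort(spec())
        p = write_covariates(cov, tmp_path / "covariates.tsv")
        back = read_covariates(p)
        for col in ("age_years", "education_years", "duration_years"):
            np.testing.assert_array_equal(cov[col].to_numpy(), back[col].to_numpy())

    def test_deficit_lowers_within_module_correlation(self):
        # Monte-Carlo ordering over 20 seeds
        labels = module_partition(20, 4)
        within = labels[:, None] == labels[None, :]
        np.fill_diagonal(within, False)

        def mean_within(deficit, seed):
            recs, _ = simulate_cohort(
                spec(n_group_a=0, n_group_b=3, clustering_deficit=deficit,
                     n_timepoints=170, seed=seed))
            rs = [np.corrcoef(r.timeseries.values, rowvar=False)[within].mean()
                  for r in recs]
            return np.mean(rs)

        diffs = [mean_within(0.0, s) - mean_within(0.3, s) for s in range(20)]
        assert all(d > 0 for d in diffs)

    def test_downstream_cp_nonincreasing_in_deficit(self):
        # sign of fitted slope of group-B Cp at cost 0.15 over a deficit grid
        from fcgraph import clustering_coefficient, pearson_fc, threshold_at_cost

        grid = [0.0, 0.2, 0.4]
        slopes = []
        for seed in range(10):
            cps = []
            for deficit in grid:
                recs, _ = simulate_cohort(
                    spec(n_group_a=0, n_group_b=2, n_rois=30, n_modules=3,
                         n_timepoints=170, clustering_deficit=deficit,
                         seed=100 + seed))
                vals = [clustering_coefficient(
                    threshold_at_cost(pearson_fc(r.timeseries), 0.15).adjacency
                )[1] for r in recs]
                cps.append(np.mean(vals))
            slopes.append(np.polyfit(grid, cps, 1)[0])
        assert np.mean(slopes) < 0
        assert sum(s < 0 for s in slopes) >= 8

    def test_generator_networks_are_small_world(self):
        # group-A synthetic data at cost 0.15: gamma > 1 and sigma > 1
        from fcgraph import (
            build_ensemble, global_metrics, pearson_fc,
            small_world_indices, threshold_at_cost,
        )

        recs, _ = simulate_cohort(
            spec(n_group_a=3, n_group_b=0, n_rois=60, n_modules=4,
                 n_timepoints=170, seed=31))
        for r in recs:
            net = threshold_at_cost(pearson_fc(r.timeseries), 0.15)
            gm = global_metrics(net)
            idx = small_world_indices(gm, build_ensemble(net, n=10, seed=5))
            assert idx.gamma > 1 and idx.sigma > 1
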
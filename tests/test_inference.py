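"""Brain-behavior statistics: correlations, Steiger comparison,
permutation schemes, LOOCV, paired tests, and the orchestrator."""

import numpy as np
import pytest

from pattlearn import (
    DegenerateInputError,
    RunConfig,
    SimulationConfig,
    ValidationError,
    compare_dependent_correlations,
    correlate,
    loocv_predict,
    n_between_assignments,
    n_within_assignments,
    paired_t_test,
    permutation_test_between,
    permutation_test_within,
    run_full_analysis,
    simulate_dataset,
)


class TestCorrelate:
    def test_perfect_linear_relationship(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        r, _ = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_null_calibration(self, rng):
        rej = sum(
            correlate(rng.standard_normal(24), rng.standard_normal(24))[1] < 0.05
            for _ in range(1000)
        )
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rej / 1000 - 0.05) < half_width


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        res = compare_dependent_correlations(-0.4, -0.4, 0.3, 24, tails=2)
        assert res.z_stat == 0.0
        assert res.p == pytest.approx(1.0)

    def test_sign_follows_fisher_difference(self):
        res = compare_dependent_correlations(-0.533, -0.106, 0.3, 24)
        assert res.z_stat < 0
        res2 = compare_dependent_correlations(0.533, 0.106, 0.3, 24)
        assert res2.z_stat > 0

    def test_monotone_in_shared_correlation(self):
        # stronger dependence between the two predictors sharpens the test
        # the admissible (positive semidefinite) range for r_kh given these
        # two correlations ends just below 0.9
        zs = [
            abs(compare_dependent_correlations(-0.533, -0.106, rkh, 24).z_stat)
            for rkh in np.linspace(0.0, 0.85, 10)
        ]
        assert np.all(np.diff(zs) > 0)

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValidationError, match="positive semidefinite"):
            compare_dependent_correlations(0.9, -0.9, 0.9, 24)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValidationError):
            compare_dependent_correlations(1.0, 0.5, 0.3, 24)

    def test_null_calibration_trivariate_normal(self, rng):
        # equal population correlations => nominal rejection rate
        C = np.array([[1, 0.3, 0.3], [0.3, 1, 0.3], [0.3, 0.3, 1]])
        L = np.linalg.cholesky(C)
        rej = 0
        reps = 1000
        for _ in range(reps):
            X = rng.standard_normal((24, 3)) @ L.T
            r = np.corrcoef(X, rowvar=False)
            res = compare_dependent_correlations(r[0, 1], r[0, 2], r[1, 2], 24, 2)
            rej += res.p < 0.05
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < half_width


class TestPermutationSpaces:
    def test_counts(self):
        assert n_within_assignments(24) == 2**24 == 16_777_216
        assert n_between_assignments(8) == 40_320


class TestBetweenPermutation:
    def test_identical_vectors_give_minimal_p(self, rng):
        x = rng.standard_normal(24)
        res = permutation_test_between(x, x, n_perm=2000, seed=0)
        assert res.r_obs == pytest.approx(1.0)
        # observed r = 1 beats essentially every permutation
        assert res.p_one <= 3.0 / 2001

    def test_determinism(self, rng):
        x, y = rng.standard_normal((2, 24))
        a = permutation_test_between(x, y, n_perm=500, seed=3)
        b = permutation_test_between(x, y, n_perm=500, seed=3)
        assert np.array_equal(a.null_dist, b.null_dist)
        assert a.p_one == b.p_one and a.p_two == b.p_two

    def test_exhaustive_matches_monte_carlo(self, rng):
        x, y = rng.standard_normal((2, 8))
        ex = permutation_test_between(x, y, exhaustive=True)
        mc = permutation_test_between(x, y, n_perm=5000, seed=1)
        assert ex.n_perm == 40_320
        for p_ex, p_mc in [(ex.p_one, mc.p_one), (ex.p_two, mc.p_two)]:
            se = np.sqrt(p_ex * (1 - p_ex) / 5000)
            assert abs(p_mc - p_ex) < 3 * se + 1e-3

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateInputError):
            permutation_test_between(np.ones(10), np.arange(10.0))


class TestWithinPermutation:
    def test_identical_conditions_make_swaps_noops(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        res = permutation_test_within(x, x.copy(), y, n_perm=200, seed=0,
                                      exhaustive=False)
        assert np.allclose(res.null_dist, res.r_obs)
        assert res.p_one == pytest.approx(1.0)

    def test_exhaustive_enumerates_full_space(self, rng):
        tr, ct, y = rng.standard_normal((3, 8))
        res = permutation_test_within(tr, ct, y, exhaustive=True)
        assert res.n_perm == 256

    def test_exhaustive_matches_monte_carlo(self, rng):
        tr, ct, y = rng.standard_normal((3, 8))
        ex = permutation_test_within(tr, ct, y, exhaustive=True)
        mc = permutation_test_within(tr, ct, y, n_perm=5000, seed=2,
                                     exhaustive=False)
        for p_ex, p_mc in [(ex.p_one, mc.p_one), (ex.p_two, mc.p_two)]:
            se = np.sqrt(p_ex * (1 - p_ex) / 5000)
            assert abs(p_mc - p_ex) < 3 * se + 1e-3

    def test_determinism(self, rng):
        tr, ct, y = rng.standard_normal((3, 24))
        a = permutation_test_within(tr, ct, y, n_perm=400, seed=9)
        b = permutation_test_within(tr, ct, y, n_perm=400, seed=9)
        assert np.array_equal(a.null_dist, b.null_dist)


class TestLOOCV:
    def test_noiseless_linear_gives_zero_error(self, rng):
        x = rng.standard_normal(12)
        y = 2.0 * x + 500.0
        res = loocv_predict(x, y)
        assert np.all(np.abs(res.rel_error) < 1e-10)
        assert res.max_abs_error < 1e-10

    def test_four_subject_fold_matches_hand_regression(self):
        # hold out subject 1: OLS on (2,3,4)->(12,14,17) has slope 2.5,
        # intercept 41/6; prediction at x=1 is 9.3333, rel error -0.0667
        res = loocv_predict([1.0, 2.0, 3.0, 4.0], [10.0, 12.0, 14.0, 17.0])
        assert res.predicted[0] == pytest.approx(28.0 / 3.0, abs=1e-9)
        assert res.rel_error[0] == pytest.approx((28.0 / 3.0 - 10.0) / 10.0, abs=1e-9)

    def test_error_shrinks_with_noise(self):
        maxerrs = []
        for noise in (120.0, 40.0, 1.0):
            rng = np.random.default_rng(17)
            x = rng.standard_normal(24)
            y = 900.0 - 100.0 * x + rng.normal(0, noise, 24)
            maxerrs.append(loocv_predict(x, y).max_abs_error)
        assert maxerrs[0] > maxerrs[1] > maxerrs[2]

    def test_zero_observed_outcome_rejected(self):
        with pytest.raises(ValidationError):
            loocv_predict([1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 2.0, 3.0])

    def test_constant_training_fold_rejected(self):
        with pytest.raises(DegenerateInputError, match="sub"):
            loocv_predict([1.0, 1.0, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0])


class TestPairedT:
    def test_identical_groups(self):
        x = np.array([0.2, 0.5, 0.7, 0.9])
        t, df, p = paired_t_test(x, x.copy())
        assert t == 0.0 and p == pytest.approx(1.0) and df == 3

    def test_hand_computed_t(self):
        # differences [1, 2, 3]: mean 2, sd 1, t = 2*sqrt(3)
        t, df, p = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-12)
        assert df == 2

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_null_calibration(self, rng):
        rej = 0
        reps = 1000
        for _ in range(reps):
            f, s = rng.standard_normal((2, 24))
            rej += paired_t_test(f, s)[2] < 0.05
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < half_width


class TestRunFullAnalysis:
    def test_report_schema_complete_on_small_fixture(self, small_dataset):
        _, patterns, behavior, _ = small_dataset
        report = run_full_analysis(
            patterns, behavior, RunConfig(n_perm=200, seed=1)
        )
        data = report.to_dict()
        assert {"meta", "cells", "learning_rate", "median_split",
                "flagged_rois"} <= set(data)
        assert len(data["cells"]) == 2 * 2  # roi x task
        required = {
            "roi", "task", "n", "r_trained", "p_trained", "r_control",
            "p_control", "r_between_conditions", "dependent_z", "dependent_p",
            "between_perm", "within_perm", "loocv", "significant",
            "p_trained_bonferroni",
        }
        for cell in data["cells"]:
            assert required <= set(cell)
        assert len(data["median_split"]) == 2 * 2

    def test_deterministic_given_seed(self, small_dataset):
        _, patterns, behavior, _ = small_dataset
        cfg = RunConfig(n_perm=150, seed=11)
        r1 = run_full_analysis(patterns, behavior, cfg).to_dict()
        r2 = run_full_analysis(patterns, behavior, cfg).to_dict()
        assert r1 == r2

    def test_mismatched_subjects_rejected(self, small_dataset):
        _, patterns, behavior, _ = small_dataset
        bad = behavior.data.copy()
        bad["subject"] = bad["subject"].str.replace("sub", "participant")
        from pattlearn import BehaviorTable

        with pytest.raises(ValidationError, match="subject ids"):
            run_full_analysis(
                patterns,
                BehaviorTable(bad, behavior.item_rt),
                RunConfig(n_perm=100),
            )

    def test_planted_effect_recovered_and_median_split_direction(self):
        cfg = SimulationConfig(
            seed=31, coupling_slope=-600.0,
            coupled_rois=("left_pars_opercularis", "left_fusiform"),
        )
        patterns, behavior, _ = simulate_dataset(cfg)
        report = run_full_analysis(
            patterns, behavior, RunConfig(n_perm=1000, seed=5)
        )
        assert set(report.flagged_rois) == {"left_pars_opercularis", "left_fusiform"}
        # planted fast items carry higher similarity: positive paired t
        for row in report.median_split:
            assert row["t"] > 0

    def test_null_data_rarely_flag_rois(self):
        flagged = 0
        for i in range(30):
            cfg = SimulationConfig(
                seed=9000 + i, coupling_slope=0.0, coupled_rois=(),
                include_item_groups=False, n_voxels=40,
            )
            patterns, behavior, _ = simulate_dataset(cfg)
            report = run_full_analysis(
                patterns, behavior, RunConfig(n_perm=300, seed=i)
            )
            flagged += len(report.flagged_rois)
        # 120 roi-level opportunities at a joint rate well below alpha
        assert flagged <= 10
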
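"""Learning curves: aggregation, power-law fitting, exclusions, median split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pattlearn import (
    BehaviorTable,
    LearningFit,
    ValidationError,
    daily_mean_rt,
    filter_fits,
    fit_power_curve,
    median_split_items,
    post_training_outcome,
)


def make_behavior(rt_by_task: dict, n_days: int = 12) -> BehaviorTable:
    """Tiny behavior table; rt_by_task maps task -> per-day RT list."""
    rows = []
    for task, rts in rt_by_task.items():
        for day, rt in zip(range(1, n_days + 1), rts):
            rows.append(("s1", day, task, float(rt), 0.9))
    return BehaviorTable(pd.DataFrame(
        rows, columns=["subject", "day", "task", "rt", "accuracy"]
    ))


class TestDailyMeanRT:
    def test_mean_of_two_tasks(self):
        bt = make_behavior({"word_naming": [800] * 12, "picture_naming": [1000] * 12})
        daily = daily_mean_rt(bt)
        assert np.allclose(daily["rt"], 900.0)

    def test_constant_across_everything(self):
        bt = make_behavior({"word_naming": [700] * 12, "picture_naming": [700] * 12})
        assert np.allclose(daily_mean_rt(bt)["rt"], 700.0)

    def test_toy_table_matches_hand_means(self):
        word = np.linspace(2000, 900, 12)
        pic = np.linspace(2200, 1100, 12)
        bt = make_behavior({"word_naming": word, "picture_naming": pic})
        daily = daily_mean_rt(bt).sort_values("day")
        assert np.allclose(daily["rt"].to_numpy(), (word + pic) / 2)

    def test_missing_task_day_cell_is_an_error(self):
        bt = make_behavior({"word_naming": [800] * 12, "picture_naming": [900] * 12})
        data = bt.data[~((bt.data["task"] == "picture_naming") & (bt.data["day"] == 7))]
        with pytest.raises(ValidationError, match="day 7"):
            daily_mean_rt(BehaviorTable(data))


class TestPostTrainingOutcome:
    def test_constant_plateau(self):
        bt = make_behavior({"word_naming": [900] * 12})
        assert post_training_outcome(bt, "word_naming").iloc[0] == pytest.approx(900.0)

    def test_arithmetic_mean_of_descending_plateau(self):
        rts = [2000, 1500, 1200, 1000, 850, 840, 830, 820, 810, 800, 790, 780]
        bt = make_behavior({"word_naming": rts})
        assert post_training_outcome(bt, "word_naming").iloc[0] == pytest.approx(815.0)

    def test_invariant_to_early_days(self):
        base = [2000, 1500, 1200, 1000] + [900] * 8
        scrambled = [1234, 4321, 999, 1111] + [900] * 8
        a = post_training_outcome(make_behavior({"word_naming": base}), "word_naming")
        b = post_training_outcome(
            make_behavior({"word_naming": scrambled}), "word_naming"
        )
        assert a.iloc[0] == b.iloc[0]

    def test_fewer_than_twelve_days_is_an_error(self):
        bt = make_behavior({"word_naming": [900] * 8}, n_days=8)
        with pytest.raises(ValidationError):
            post_training_outcome(bt, "word_naming")


class TestFitPowerCurve:
    def test_noiseless_recovery(self):
        days = np.arange(1, 13)
        fit = fit_power_curve(days, 2000.0 * days ** (-0.3))
        assert fit.converged
        assert fit.a == pytest.approx(2000.0, rel=1e-6)
        assert fit.b == pytest.approx(0.3, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_degenerates_gracefully(self):
        fit = fit_power_curve(np.arange(1, 13), np.full(12, 1000.0))
        assert abs(fit.b) < 1e-6
        assert np.isnan(fit.r2)
        assert fit.message  # the degenerate case is flagged

    def test_r2_never_exceeds_one(self, rng):
        days = np.arange(1, 13)
        for _ in range(20):
            y = 1800.0 * days ** (-0.25) + rng.normal(0, 50, 12)
            fit = fit_power_curve(days, np.maximum(y, 100.0))
            assert fit.r2 <= 1.0 + 1e-12

    def test_noisy_recovery_of_learning_rate(self, rng):
        # moderate-noise simulation study: b is recovered to ~0.05
        days = np.arange(1, 13)
        errs = []
        for _ in range(200):
            y = 1800.0 * days ** (-0.25) + rng.normal(0, 30, 12)
            fit = fit_power_curve(days, y)
            errs.append(abs(fit.b - 0.25))
        assert np.median(errs) < 0.05

    def test_inverts_noiseless_simulator(self):
        from pattlearn import SimulationConfig, simulate_behavior, simulate_patterns

        cfg = SimulationConfig(
            n_subjects=5, n_voxels=10, coupling_slope=0.0, rt_noise_sd=0.0, seed=6,
        )
        _, truth = simulate_patterns(cfg)
        daily = daily_mean_rt(simulate_behavior(cfg, truth))
        for si, subject in enumerate(truth.subjects):
            grp = daily[daily["subject"] == subject].sort_values("day")
            fit = fit_power_curve(grp["day"].to_numpy(), grp["rt"].to_numpy())
            assert fit.a == pytest.approx(truth.a[si], rel=1e-6)
            assert fit.b == pytest.approx(truth.b[si], rel=1e-6)

    @pytest.mark.parametrize("bad", [[0.0] * 12, [-5.0] * 12])
    def test_nonpositive_rts_rejected(self, bad):
        with pytest.raises(ValidationError):
            fit_power_curve(np.arange(1, 13), np.array(bad))

    def test_too_few_days_rejected(self):
        with pytest.raises(ValidationError):
            fit_power_curve(np.array([1, 2]), np.array([100.0, 90.0]))


class TestFilterFits:
    @staticmethod
    def fit(r2, converged=True):
        return LearningFit(2000.0, 0.3, r2, converged, 12)

    def test_threshold_rule(self):
        fits = {"a": self.fit(0.9), "b": self.fit(0.65), "c": self.fit(0.71)}
        kept, excluded = filter_fits(fits, 0.7)
        assert set(kept) == {"a", "c"}
        assert set(excluded) == {"b"}

    def test_zero_threshold_keeps_all_defined(self):
        fits = {"a": self.fit(0.1), "b": self.fit(float("nan"))}
        kept, excluded = filter_fits(fits, 0.0)
        assert set(kept) == {"a"}
        assert set(excluded) == {"b"}

    def test_nonconverged_always_excluded(self):
        kept, excluded = filter_fits({"a": self.fit(0.95, converged=False)}, 0.7)
        assert not kept and set(excluded) == {"a"}

    def test_three_of_twentyfour_below_threshold(self, rng):
        r2s = np.concatenate([rng.uniform(0.75, 0.95, 21), [0.5, 0.6, 0.69]])
        fits = {f"s{i}": self.fit(float(r2)) for i, r2 in enumerate(r2s)}
        kept, excluded = filter_fits(fits, 0.7)
        assert len(kept) == 21 and len(excluded) == 3


class TestMedianSplit:
    def test_even_count(self):
        fast, slow = median_split_items(pd.Series([2.0, 4.0, 6.0, 8.0],
                                                  index=["i1", "i2", "i3", "i4"]))
        assert fast == ["i1", "i2"] and slow == ["i3", "i4"]

    def test_thirty_distinct_items_split_fifteen_fifteen(self, rng):
        rts = pd.Series(rng.permutation(30) + 500.0,
                        index=[f"item{i:02d}" for i in range(30)])
        fast, slow = median_split_items(rts)
        assert len(fast) == len(slow) == 15
        assert max(rts[fast]) < min(rts[slow])

    def test_all_ties_split_by_stable_order(self):
        rts = pd.Series([5.0] * 4, index=["d", "c", "b", "a"])
        fast, slow = median_split_items(rts)
        assert fast == ["a", "b"] and slow == ["c", "d"]

    @given(st.lists(st.floats(100, 5000), min_size=2, max_size=31))
    def test_partition_property(self, values):
        rts = pd.Series(values, index=[f"i{k:03d}" for k in range(len(values))])
        fast, slow = median_split_items(rts)
        assert sorted(fast + slow) == sorted(rts.index)
        assert abs(len(fast) - len(slow)) <= 1
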
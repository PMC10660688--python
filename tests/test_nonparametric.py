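import numpy as np
import pandas as pd
import pytest

from rarliver.nonparametric import (circular_distance_hours,
                                    circular_median_hours, circular_sd_hours,
                                    flag_shift_workers, hourly_series,
                                    interdaily_stability,
                                    intradaily_variability, l5_midpoint)


def hourly_frame(values_by_day):
    """Build an hourly frame from a list of 24-value daily vectors."""
    rows = []
    for d, vals in enumerate(values_by_day, start=1):
        for h, v in enumerate(vals):
            rows.append({"day_index": d, "hour": h, "activity": v})
    return pd.DataFrame(rows)


def bins_frame(profile_by_day):
    rows = []
    for d, vals in enumerate(profile_by_day, start=1):
        for b, v in enumerate(vals):
            rows.append({"participant_id": 1, "day_index": d, "bin_5min": b,
                         "activity": v})
    return pd.DataFrame(rows)


class TestInterdailyStability:
    def test_perfect_repetition(self):
        day = np.sin(np.arange(24) / 24 * 2 * np.pi) + 2
        assert interdaily_stability(hourly_frame([day] * 5)) == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            out = interdaily_stability(hourly_frame([np.ones(24)] * 4))
        assert np.isnan(out)

    def test_white_noise_expectation(self):
        rng = np.random.default_rng(0)
        vals = [interdaily_stability(
            hourly_frame(list(rng.normal(size=(7, 24))))) for _ in range(300)]
        assert abs(np.mean(vals) - 1 / 7) < 0.02

    def test_scale_and_day_origin_invariance(self):
        rng = np.random.default_rng(1)
        days = list(rng.gamma(2, 10, size=(6, 24)))
        base = interdaily_stability(hourly_frame(days))
        scaled = interdaily_stability(
            hourly_frame([5.0 * np.asarray(d) for d in days]))
        reordered = interdaily_stability(hourly_frame(days[3:] + days[:3]))
        assert scaled == pytest.approx(base)
        assert reordered == pytest.approx(base)

    def test_within_day_shuffle_changes_is(self):
        rng = np.random.default_rng(2)
        day = np.linspace(0, 100, 24)
        days = [day + rng.normal(0, 1, 24) for _ in range(5)]
        base = interdaily_stability(hourly_frame(days))
        shuffled = [rng.permutation(d) for d in days]
        assert interdaily_stability(hourly_frame(shuffled)) != pytest.approx(
            base, rel=1e-3)


class TestIntradailyVariability:
    def test_alternating_series(self):
        day = np.tile([0.0, 1.0], 12)
        assert intradaily_variability(hourly_frame([day] * 2)) == pytest.approx(4.0)

    def test_white_noise_limit(self):
        rng = np.random.default_rng(3)
        vals = [intradaily_variability(
            hourly_frame(list(rng.normal(size=(7, 24))))) for _ in range(300)]
        assert abs(np.mean(vals) - 2.0) < 0.1

    def test_smooth_sinusoid_low(self):
        day = np.sin(np.arange(24) / 24 * 2 * np.pi)
        assert intradaily_variability(hourly_frame([day] * 4)) < 0.5

    def test_no_difference_across_gaps(self):
        # a huge level shift hidden behind a missing hour must not inflate IV
        day1 = np.concatenate([np.zeros(23), [np.nan]])
        day2 = np.full(24, 100.0)
        iv = intradaily_variability(
            hourly_frame([day1 + np.random.default_rng(4).normal(0, 1, 24),
                          day2 + np.random.default_rng(5).normal(0, 1, 24)]))
        # all surviving successive differences are within-level noise
        assert iv < 1.0

    def test_constant_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = intradaily_variability(hourly_frame([np.ones(24)] * 4))
        assert np.isnan(out)


class TestL5Midpoint:
    def test_simple_trough(self):
        profile = np.ones(288) * 50
        profile[:60] = 0.0  # [0:00, 5:00)
        mid, act = l5_midpoint(bins_frame([profile]))
        assert mid == pytest.approx(2.5)
        assert act == pytest.approx(0.0)

    def test_wraparound_trough(self):
        profile = np.ones(288) * 50
        profile[264:] = 0.0   # 22:00-24:00
        profile[:36] = 0.0    # 00:00-03:00
        mid, _ = l5_midpoint(bins_frame([profile]))
        assert mid == pytest.approx(0.5)

    def test_simulated_rhythm_midpoint_opposite_acrophase(self):
        # smooth curve (moderate beta) so the trough is single and well-defined
        from rarliver.actigraphy import aggregate_5min, classify_valid_days
        from rarliver.synthetic import RhythmTruth, simulate_actigraphy

        truth = RhythmTruth.with_nadir_sleep(
            minimum=10, amplitude=100, acrophase=14.0, alpha=0.0, beta=2.0,
            noise_sd=2.0, n_days=7)
        epochs = simulate_actigraphy(truth, 1, seed=5)
        bins = aggregate_5min(epochs, classify_valid_days(epochs))
        mid, _ = l5_midpoint(bins)
        assert circular_distance_hours(mid, 2.0) < 0.5

    def test_mostly_missing_profile(self):
        profile = np.full(288, np.nan)
        profile[:100] = 1.0
        mid, act = l5_midpoint(bins_frame([profile]))
        assert np.isnan(mid) and np.isnan(act)

    def test_circular_shift_equivariance(self):
        rng = np.random.default_rng(6)
        profile = rng.gamma(2, 10, 288)
        base, _ = l5_midpoint(bins_frame([profile]))
        shift_bins = 36  # 3 h
        shifted, _ = l5_midpoint(bins_frame([np.roll(profile, shift_bins)]))
        assert circular_distance_hours(shifted, (base + 3.0) % 24) < 1e-9


class TestShiftWorkerFlag:
    def test_outlier_flagged(self):
        mids = [2.4, 2.5, 2.6, 2.5, 2.45, 2.55, 2.5, 2.4, 2.6, 2.5, 14.5]
        flags = flag_shift_workers(mids)
        assert flags[-1] and flags[:-1].sum() == 0

    def test_identical_cohort_flags_nobody(self):
        assert not flag_shift_workers([3.0] * 12).any()

    def test_small_cohort_refused(self):
        with pytest.raises(ValueError, match="at least 10"):
            flag_shift_workers([1.0] * 9)

    def test_mixture_recovery(self):
        rng = np.random.default_rng(9)
        n = 2000
        night = rng.random(n) < 0.05
        mids = np.where(night, (14.5 + rng.normal(0, 0.5, n)) % 24,
                        (2.5 + rng.normal(0, 0.8, n)) % 24)
        flagged = flag_shift_workers(mids).mean()
        assert abs(flagged - 0.05) < 0.02

    def test_circular_stats_wrap(self):
        # cluster straddling midnight: naive SD would be huge
        hours = np.array([23.5, 23.8, 0.2, 0.5, 23.9, 0.1])
        assert circular_sd_hours(hours) < 1.0
        med = circular_median_hours(hours)
        assert circular_distance_hours(med, 0.0) < 0.6
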
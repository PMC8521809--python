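"""Windowing, imputation, normalization and subject-split behaviour."""

import numpy as np
import pandas as pd
import pytest

from sedrl.features import FEATURE_NAMES, MAP_INDEX, N_FEATURES
from sedrl.preprocessing import (
    PatientTrajectory,
    RawObservation,
    compute_training_means,
    fill_missing,
    fit_apply_normalizer,
    preprocess_cohort,
    read_observations_csv,
    split_cohort,
    window_hourly,
)
from sedrl.synthetic import generate_cohort

HR = "heart_rate"


def obs(time, variable, value, sid="s1"):
    return RawObservation(subject_id=sid, time=time, variable=variable, value=value)


class TestWindowHourly:
    def test_mean_of_recordings_within_hour(self):
        traj = window_hourly([obs(3.1, HR, 80), obs(3.9, HR, 90), obs(0.5, "sas", 4)])
        assert traj.features[3, FEATURE_NAMES.index(HR)] == 85.0

    def test_single_observation_yields_one_window(self):
        traj = window_hourly([obs(0.5, HR, 80)])
        assert traj.n_windows == 1

    def test_grouping_by_floor_time(self):
        traj = window_hourly(
            [obs(1.2, "map", 70), obs(1.8, "map", 90), obs(2.1, "map", 100)]
        )
        assert traj.features[1, MAP_INDEX] == 80.0
        assert traj.features[2, MAP_INDEX] == 100.0
        assert np.isnan(traj.features[0, MAP_INDEX])

    def test_missing_doses_are_zero_missing_features_nan(self):
        traj = window_hourly([obs(0.5, HR, 80)])
        assert traj.doses[0, 0] == 0.0 and traj.doses[0, 1] == 0.0
        assert np.isnan(traj.features[0, MAP_INDEX])

    def test_rejects_empty_and_negative_times(self):
        with pytest.raises(ValueError):
            window_hourly([])
        with pytest.raises(ValueError):
            window_hourly([obs(-0.1, HR, 80)])

    def test_matches_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            times = rng.uniform(0, 10, size=60)
            values = rng.normal(80, 10, size=60)
            variables = rng.choice([HR, "map", "resp_rate"], size=60)
            records = [obs(t, v, x) for t, v, x in zip(times, variables, values)]
            traj = window_hourly(records)
            # oracle: group by floor(time) per variable, then mean
            for var in (HR, "map", "resp_rate"):
                col = FEATURE_NAMES.index(var)
                for h in range(traj.n_windows):
                    sel = [x for t, v, x in zip(times, variables, values)
                           if v == var and int(t) == h]
                    if sel:
                        assert traj.features[h, col] == pytest.approx(np.mean(sel))
                    else:
                        assert np.isnan(traj.features[h, col])


def make_traj(hr_values, sas=None, sid="s1"):
    t = len(hr_values)
    features = np.full((t, N_FEATURES), 50.0)
    features[:, FEATURE_NAMES.index(HR)] = hr_values
    sas_arr = np.full(t, 4.0) if sas is None else np.asarray(sas, dtype=float)
    return PatientTrajectory(
        subject_id=sid, features=features, sas=sas_arr, doses=np.zeros((t, 2))
    )


class TestFillMissing:
    means = np.full(N_FEATURES, 85.0)

    def test_hold_forward(self):
        traj = make_traj([80.0, np.nan, np.nan, 90.0])
        filled = fill_missing(traj, self.means)
        hr = filled.features[:, FEATURE_NAMES.index(HR)]
        assert list(hr) == [80.0, 80.0, 80.0, 90.0]

    def test_leading_gap_takes_training_mean(self):
        traj = make_traj([np.nan, 90.0])
        filled = fill_missing(traj, self.means)
        assert filled.features[0, FEATURE_NAMES.index(HR)] == 85.0

    def test_fully_observed_unchanged(self):
        traj = make_traj([80.0, 90.0])
        filled = fill_missing(traj, self.means)
        np.testing.assert_array_equal(filled.features, traj.features)

    def test_removes_windows_with_sas_missing_and_reindexes(self):
        traj = make_traj([80.0, 81.0, 82.0], sas=[4.0, np.nan, 3.0])
        filled = fill_missing(traj, self.means)
        assert filled.n_windows == 2
        hr = filled.features[:, FEATURE_NAMES.index(HR)]
        assert list(hr) == [80.0, 82.0]

    def test_removes_windows_with_all_features_missing(self):
        features = np.full((3, N_FEATURES), 60.0)
        features[1, :] = np.nan
        traj = PatientTrajectory("s1", features, np.full(3, 4.0), np.zeros((3, 2)))
        filled = fill_missing(traj, self.means)
        assert filled.n_windows == 2

    def test_rejects_incomplete_training_means(self):
        bad = self.means.copy()
        bad[2] = np.nan
        with pytest.raises(ValueError):
            fill_missing(make_traj([80.0]), bad)

    def test_no_missing_after_fill_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = rng.integers(3, 15)
            features = rng.normal(70, 10, (t, N_FEATURES))
            mask = rng.uniform(size=features.shape) < 0.3
            features[mask] = np.nan
            traj = PatientTrajectory("s", features, np.full(t, 4.0), np.zeros((t, 2)))
            filled = fill_missing(traj, np.full(N_FEATURES, 70.0))
            assert not np.any(np.isnan(filled.features))


class TestNormalizer:
    def test_population_convention_example(self):
        train = [make_traj([80.0, 90.0])]
        filled = [fill_missing(t, np.full(N_FEATURES, 85.0)) for t in train]
        stats, normed = fit_apply_normalizer(filled, filled)
        col = FEATURE_NAMES.index(HR)
        assert stats.mean[col] == 85.0
        assert stats.std[col] == 5.0  # population, not sample (7.071)
        np.testing.assert_allclose(normed[0].features[:, col], [-1.0, 1.0])

    def test_validation_subject_uses_training_stats(self):
        train = [fill_missing(make_traj([80.0, 90.0]), np.full(N_FEATURES, 85.0))]
        val = [fill_missing(make_traj([85.0, 85.0], sid="v"), np.full(N_FEATURES, 85.0))]
        stats, normed = fit_apply_normalizer(train, train + val)
        col = FEATURE_NAMES.index(HR)
        np.testing.assert_allclose(normed[1].features[:, col], [0.0, 0.0])

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 50)
        values = (values - values.mean()) / values.std()
        traj = make_traj(values)
        filled = [fill_missing(traj, np.full(N_FEATURES, 0.0))]
        stats, _ = fit_apply_normalizer(filled, filled)
        col = FEATURE_NAMES.index(HR)
        assert abs(stats.mean[col]) < 1e-12 and abs(stats.std[col] - 1) < 1e-12

    def test_zero_variance_feature_warns_and_scales_by_one(self):
        train = [fill_missing(make_traj([80.0, 80.0]), np.full(N_FEATURES, 80.0))]
        with pytest.warns(UserWarning):
            stats, normed = fit_apply_normalizer(train, train)
        col = FEATURE_NAMES.index(HR)
        assert stats.std[col] == 1.0

    def test_raw_map_retained_unscaled(self):
        train = [fill_missing(make_traj([80.0, 90.0]), np.full(N_FEATURES, 85.0))]
        _, normed = fit_apply_normalizer(train, train)
        np.testing.assert_array_equal(normed[0].map_mmHg, [50.0, 50.0])

    def test_train_split_normalized_to_zero_mean_unit_variance(self):
        obs_df, _ = generate_cohort(20, 12, seed=3)
        cohort = preprocess_cohort(obs_df, seed=4)
        train = cohort.subset(cohort.split.train_ids)
        stacked = np.concatenate([t.features for t in train])
        for i in range(N_FEATURES):
            if i == FEATURE_NAMES.index("gender"):
                continue
            assert abs(stacked[:, i].mean()) < 1e-9
            assert abs(stacked[:, i].var() - 1.0) < 1e-9


class TestSplitCohort:
    def test_exact_proportions(self):
        split = split_cohort(range(10), seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (6, 2, 2)

    def test_cohort_scale_sizes(self):
        split = split_cohort(range(1757), seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (
            1055,
            351,
            351,
        )

    def test_deterministic_given_seed(self):
        assert split_cohort(range(50), seed=9) == split_cohort(range(50), seed=9)

    def test_disjoint_and_exhaustive_for_any_n_and_seed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 400))
            seed = int(rng.integers(0, 1000))
            split = split_cohort(range(n), seed=seed)
            union = set(split.train_ids) | set(split.val_ids) | set(split.test_ids)
            total = len(split.train_ids) + len(split.val_ids) + len(split.test_ids)
            assert union == set(range(n)) and total == n

    def test_rejects_tiny_cohorts(self):
        with pytest.raises(ValueError):
            split_cohort(range(4), seed=0)


class TestCohortIO:
    def test_wide_format_autodetected(self, tmp_path):
        wide = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "time_h": [0.5, 1.5],
                "heart_rate": [80.0, 90.0],
                "sas": [4, 4],
            }
        )
        path = tmp_path / "wide.csv"
        wide.to_csv(path, index=False)
        long = read_observations_csv(path)
        assert set(long.columns) == {"subject_id", "time_h", "variable", "value"}
        assert len(long) == 4

    def test_end_to_end_preprocess_from_generated_cohort(self):
        obs_df, _ = generate_cohort(12, 10, seed=5)
        cohort = preprocess_cohort(obs_df, seed=6)
        assert len(cohort.trajectories) == 12
        for traj in cohort.trajectories.values():
            assert not np.any(np.isnan(traj.features))
            assert traj.map_mmHg is not None and np.all(traj.map_mmHg > 0)

    def test_training_means_ignore_missing(self):
        traj = make_traj([80.0, np.nan])
        means = compute_training_means([traj])
        assert means[FEATURE_NAMES.index(HR)] == 80.0
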
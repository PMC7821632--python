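"""Response preparation, classifier mapping, validation schemes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdvoice.clinical import UPDRSAssessment
from pdvoice.mapping import (
    CALIBRATION_COLUMN,
    cross_validate,
    discretize,
    fit_predict,
    interpolate_weekly,
    mae,
    spearman_report,
    tracking_validate,
)


def synthetic_design(n=300, n_features=8, n_classes=6, noise=0.3, seed=0):
    """Feature table where the response is a noisy linear readout."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    latent = X[:, 0] + 0.5 * X[:, 1]
    y = np.clip(np.digitize(latent, np.quantile(latent, np.linspace(0, 1, n_classes + 1)[1:-1]))
                + rng.normal(0, noise, n).round().astype(int), 0, n_classes - 1)
    data = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    data["motor_updrs"] = y.astype(float) * 4 + 10
    return data


class TestInterpolation:
    def test_linear_midpoint_and_flat_segment(self):
        traj = interpolate_weekly([
            UPDRSAssessment(0, 20, 27),
            UPDRSAssessment(13, 26, 33),
            UPDRSAssessment(26, 26, 33),
        ])
        assert np.interp(6.5, traj.weeks, traj.motor_weekly) == pytest.approx(23.0)
        assert np.all(traj.motor_weekly[13:] == 26.0)
        assert traj.at_week(13, "motor") == 26.0   # exact at measured weeks

    def test_constant_assessments_give_constant_trajectory(self):
        traj = interpolate_weekly([UPDRSAssessment(w, 15, 20) for w in (0, 13, 26)])
        assert np.all(traj.motor_weekly == 15.0)

    def test_duplicate_weeks_rejected(self):
        with pytest.raises(ValueError):
            interpolate_weekly([UPDRSAssessment(0, 10, 12)] * 2)


class TestDiscretize:
    @pytest.mark.parametrize("value,expected", [(22.4, 22), (22.5, 23), (0.0, 0)])
    def test_rounding(self, value, expected):
        assert discretize(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize(120.0, scale="motor")


class TestMAE:
    def test_perfect_prediction(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_value(self):
        assert mae([3, 2], [1, 2]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1, 2], [1, 2, 3])

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 100, 1000)
        a = rng.uniform(0, 100, 1000)
        bf = sum(abs(x - y) for x, y in zip(p, a)) / 1000
        assert mae(p, a) == pytest.approx(bf, rel=1e-12)


class TestFitPredict:
    def test_memorizes_separable_training_data(self):
        data = synthetic_design(noise=0.0, seed=1)
        X = data.drop(columns=["motor_updrs"])
        y = discretize(data["motor_updrs"].to_numpy())
        pred = fit_predict(X, y, X, seed=0, params={"n_estimators": 100})
        assert mae(pred, y) < 0.2

    def test_single_class_training(self):
        X = pd.DataFrame({"f0": np.random.default_rng(0).normal(size=50)})
        y = np.full(50, 7)
        pred = fit_predict(X, y, X.iloc[:10], seed=0, params={"n_estimators": 20})
        assert np.all(pred == 7)

    def test_identifier_columns_rejected(self):
        X = pd.DataFrame({"f0": [1.0, 2.0], "subject_id": ["a", "b"]})
        with pytest.raises(ValueError):
            fit_predict(X, np.array([1, 2]), X, seed=0)

    def test_unknown_feature_subset_rejected(self):
        X = pd.DataFrame({"f0": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_predict(X, np.array([1, 2, 1]), X, feature_subset=["nope"], seed=0)

    def test_continuous_response_rejected(self):
        X = pd.DataFrame({"f0": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_predict(X, np.array([1.5, 2.5, 3.5]), X, seed=0)


class TestCrossValidate:
    def test_split_sizes_match_90_10_convention(self):
        rng = np.random.default_rng(2)
        for n, train, test in ((4010, 3609, 401), (1865, 1679, 186)):
            data = pd.DataFrame({
                "f0": rng.normal(size=n),
                "motor_updrs": rng.uniform(10, 30, n),
            })
            rep = cross_validate(data, "motor", n_repeats=1, learner="dummy", seed=0)
            assert (rep.n_train, rep.n_test) == (train, test)

    def test_folds_partition_the_data(self):
        """Every row appears in exactly one test fold per repeat."""
        n, n_folds = 103, 10
        rng = np.random.default_rng(np.random.SeedSequence([4 & 0x7FFFFFFF, 0xCF]))
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        flat = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(flat, np.arange(n))

    def test_informative_features_beat_dummy(self):
        data = synthetic_design(seed=3)
        rf = cross_validate(data, "motor", n_repeats=3, seed=1, params={"n_estimators": 100})
        dummy = cross_validate(data, "motor", n_repeats=3, seed=1, learner="dummy")
        assert rf.mae_mean < dummy.mae_mean

    def test_noise_features_do_not_beat_dummy(self):
        """Null data: the forest shows no advantage over the dummy baseline."""
        rng = np.random.default_rng(5)
        data = pd.DataFrame(rng.normal(size=(200, 5)), columns=[f"f{i}" for i in range(5)])
        data["motor_updrs"] = rng.uniform(10, 20, 200)
        rf = cross_validate(data, "motor", n_repeats=10, seed=2, params={"n_estimators": 50})
        dummy = cross_validate(data, "motor", n_repeats=10, seed=2, learner="dummy")
        assert rf.mae_mean >= 0.95 * dummy.mae_mean   # not better than baseline

    def test_report_invariants(self):
        data = synthetic_design(seed=6)
        rep = cross_validate(data, "motor", n_repeats=5, seed=0, params={"n_estimators": 50})
        assert rep.per_repeat_mae.size == 5
        assert rep.ci95[0] <= rep.mae_mean <= rep.ci95[1]
        assert np.all(rep.per_repeat_mae >= 0)

    def test_too_many_folds_rejected(self):
        data = synthetic_design(n=5)
        with pytest.raises(ValueError):
            cross_validate(data, "motor", n_folds=10, n_repeats=1)


def tracking_cohort(n_subjects=6, n_weeks=12, constant=True, seed=0):
    """Toy tracking table: per-subject constant (or drifting) UPDRS."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        level = 10 + 3 * s
        for w in range(n_weeks):
            y = level if constant else level + 0.5 * w
            for slot in (1, 2):
                rows.append({
                    "subject_id": f"S{s}",
                    "week": w,
                    "f0": rng.normal(),
                    "f1": rng.normal(),
                    "total_updrs": float(y),
                })
    return pd.DataFrame(rows)


class TestTrackingValidate:
    def test_constant_trajectories_give_near_zero_mae(self):
        """With per-subject constant UPDRS, the calibration column alone
        suffices; the learner considers all features at each split so the
        perfectly predictive column is always found."""
        data = tracking_cohort(constant=True)
        rep = tracking_validate(data, "total", seed=1,
                                params={"n_estimators": 100, "max_features": None})
        assert rep.mae_mean == pytest.approx(0.0, abs=0.25)

    def test_left_out_test_weeks_never_in_training(self):
        """Partition property: calibration and test weeks are disjoint."""
        data = tracking_cohort()
        weeks = np.sort(data["week"].unique())
        calib = set(weeks[:4])
        test = set(weeks[4:])
        assert calib.isdisjoint(test)

    def test_insufficient_weeks_skipped(self):
        data = tracking_cohort(n_subjects=4, n_weeks=12)
        short = tracking_cohort(n_subjects=1, n_weeks=3, seed=9)
        short["subject_id"] = "SHORT"
        rep = tracking_validate(pd.concat([data, short]), "total", seed=0,
                                params={"n_estimators": 50})
        assert rep.per_repeat_mae.size == 4   # short subject skipped

    def test_two_subjects_required(self):
        data = tracking_cohort(n_subjects=1)
        with pytest.raises(ValueError):
            tracking_validate(data, "total")


class TestSpearmanReport:
    def test_perfect_and_anti_correlation(self):
        y = np.arange(50, dtype=float)
        X = pd.DataFrame({"pos": y.copy(), "neg": -y, "flat": np.ones(50)})
        rep = spearman_report(X, y)
        assert rep.loc["pos", "rho"] == pytest.approx(1.0)
        assert rep.loc["neg", "rho"] == pytest.approx(-1.0)
        assert rep.loc["flat", "flag"] == "constant_or_missing"

    def test_null_feature_rho_small(self):
        """Independent noise: |rho| < 0.15 in at least 95% of simulations."""
        rng = np.random.default_rng(8)
        y = rng.normal(size=500)
        hits = 0
        for _ in range(100):
            x = pd.DataFrame({"noise": rng.normal(size=500)})
            rho = spearman_report(x, y).loc["noise", "rho"]
            hits += abs(rho) < 0.15
        assert hits >= 95

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            spearman_report(pd.DataFrame({"a": [1.0, 2.0]}), np.ones(2))
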
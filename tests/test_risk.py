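"""Risk model: LOCF featurization, training-set windows, thresholds, t_d."""

import numpy as np
import pytest

from shocktraj import (FEATURE_NAMES, RiskModelConfig, build_training_set,
                       compute_risk_trajectory, label_cohort, locf_featurize,
                       select_threshold, train_risk_model)
from shocktraj.exceptions import ConfigError, InputError, TrainingSetError
from shocktraj.label import StateTimeline
from shocktraj.records import HOUR
from shocktraj.risk import RiskModel, RiskTrajectory, detect_t_d, locf_matrix

from conftest import make_record

H = HOUR
LACT = FEATURE_NAMES.index("lactate")


class TestLocf:
    def test_latest_value_at_or_before_query(self):
        rec = make_record(obs=[(1 * H, "lactate", 2.3), (5 * H, "lactate", 4.0)])
        assert locf_featurize(rec, 4 * H)[LACT] == 2.3
        assert locf_featurize(rec, 5 * H)[LACT] == 4.0  # "at or before"

    def test_unobserved_feature_is_nan(self):
        rec = make_record(obs=[(1 * H, "lactate", 2.3)])
        vec = locf_featurize(rec, 0.5 * H)
        assert np.isnan(vec[LACT])
        assert np.isnan(vec[FEATURE_NAMES.index("heart_rate")])

    def test_matrix_agrees_with_pointwise(self):
        rec = make_record(obs=[(1 * H, "lactate", 2.3), (2 * H, "map", 70.0),
                               (5 * H, "lactate", 4.0)])
        times = np.array([0.5 * H, 1 * H, 3 * H, 6 * H])
        mat = locf_matrix(rec, times)
        for i, t in enumerate(times):
            np.testing.assert_array_equal(mat[i], locf_featurize(rec, t))


class TestTrainingSet:
    def tl(self, pid, sepsis=None, shock=None):
        return StateTimeline(pid, sepsis, None, shock, None, False)

    def test_shock_only_cohort_rejected(self):
        rec = make_record(patient_id="s", obs=[
            (7.0 * H, "lactate", 3.0), (8.5 * H, "lactate", 3.5)])
        with pytest.raises(TrainingSetError):
            build_training_set([rec], {"s": self.tl("s", sepsis=1 * H,
                                                    shock=10 * H)})

    def test_window_rule_and_labels(self):
        shock_rec = make_record(patient_id="s", obs=[
            (7.0 * H, "lactate", 3.0), (8.5 * H, "lactate", 3.5),
            (8.9 * H, "heart_rate", 120.0), (9.5 * H, "map", 50.0)])
        neg_rec = make_record(patient_id="n", obs=[
            (2 * H, "lactate", 1.0), (3 * H, "heart_rate", 90.0)])
        X, y, pids = build_training_set(
            [shock_rec, neg_rec],
            {"s": self.tl("s", sepsis=1 * H, shock=10 * H),
             "n": self.tl("n", sepsis=1.5 * H)})
        assert (y[pids == "s"] == 1).all()
        assert len(y[pids == "s"]) == 2  # updates at 8.5 h and 8.9 h
        assert (y[pids == "n"] == 0).all() and len(y[pids == "n"]) == 2

    def test_error_when_a_class_is_missing(self):
        rec = make_record(patient_id="n", obs=[(2 * H, "lactate", 1.0)])
        with pytest.raises(TrainingSetError):
            build_training_set([rec], {"n": self.tl("n", sepsis=1 * H)})


class TestModel:
    def _toy_set(self, n=600, seed=0, shift=3.0):
        rng = np.random.default_rng(seed)
        X = np.full((n, len(FEATURE_NAMES)), np.nan)
        X[:, LACT] = rng.normal(1.5, 0.4, n)
        X[:, 0] = rng.normal(88, 6, n)
        y = np.zeros(n, dtype=int)
        y[n // 2:] = 1
        X[n // 2:, LACT] += shift
        X[n // 2:, 0] += 20
        return X, y

    def test_single_class_rejected(self):
        X, y = self._toy_set()
        with pytest.raises(TrainingSetError):
            train_risk_model(X, np.zeros_like(y))

    def test_duplicated_rows_predict_identically(self):
        X, y = self._toy_set()
        model = train_risk_model(X, y, RiskModelConfig(seed=1))
        pred = model.predict(np.vstack([X[0], X[0]]))
        assert pred[0] == pred[1]

    def test_training_is_deterministic_given_seed(self):
        X, y = self._toy_set()
        a = train_risk_model(X, y, RiskModelConfig(seed=3)).predict(X)
        b = train_risk_model(X, y, RiskModelConfig(seed=3)).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_model_round_trips_through_save_load(self, tmp_path):
        X, y = self._toy_set()
        model = train_risk_model(X, y, RiskModelConfig(seed=1))
        model.save(tmp_path / "m.json")
        loaded = RiskModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(loaded.predict(X), model.predict(X), rtol=1e-6)
        assert loaded.threshold == model.threshold


class TestThreshold:
    def test_separable_scores_any_rule(self):
        scores = np.r_[np.full(50, 0.1), np.full(50, 0.9)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        for rule in ("quantile", "target_specificity", "youden"):
            thr = select_threshold(scores, labels, rule)
            assert 0.1 < thr <= 0.9

    def test_full_specificity_clears_all_negatives(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        thr = select_threshold(scores, labels, "target_specificity",
                               target_specificity=1.0)
        assert (scores[labels == 0] < thr).all()

    def test_youden_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        scores = np.r_[rng.normal(0.3, 0.1, 300), rng.normal(0.6, 0.1, 300)]
        labels = np.r_[np.zeros(300), np.ones(300)]
        thr = select_threshold(scores, labels, "youden")
        # brute force over every cut-point
        def j(c):
            return np.mean(scores[labels == 1] >= c) + np.mean(
                scores[labels == 0] < c) - 1
        best = max(np.unique(scores), key=j)
        assert j(thr) == pytest.approx(j(best))

    def test_unknown_rule_rejected(self):
        with pytest.raises(ConfigError):
            select_threshold(np.array([0.5]), np.array([1]), "magic")


class TestTrajectory:
    def _step_model(self):
        """Model trained so risk tracks lactate level."""
        rng = np.random.default_rng(2)
        X = np.full((800, len(FEATURE_NAMES)), np.nan)
        X[:, LACT] = np.r_[rng.normal(1.0, 0.2, 400), rng.normal(5.0, 0.2, 400)]
        y = np.r_[np.zeros(400), np.ones(400)]
        return train_risk_model(X, y, RiskModelConfig(seed=2, min_child_weight=10.0))

    def test_first_crossing_defines_t_d_and_ewt(self):
        model = self._step_model()
        rec = make_record(obs=[(0.0, "lactate", 1.0), (1 * H, "lactate", 1.1),
                               (2 * H, "lactate", 5.0)])
        traj = compute_risk_trajectory(model, rec, shock_onset=10 * H)
        assert traj.t_d == 2 * H
        assert traj.ewt == 8 * H and traj.ewt_hours == 8.0
        assert len(traj.grid_times) == 13  # t_d .. t_d + 12 h hourly

    def test_no_crossing_means_no_t_d(self):
        model = self._step_model()
        rec = make_record(obs=[(0.0, "lactate", 1.0), (5 * H, "lactate", 1.2)])
        traj = compute_risk_trajectory(model, rec, shock_onset=10 * H)
        assert traj.t_d is None and traj.ewt is None
        assert traj.grid_times.size == 0

    def test_raising_threshold_never_advances_t_d(self):
        model = self._step_model()
        rec = make_record(obs=[(i * H, "lactate", v) for i, v in
                               enumerate([1.0, 1.4, 2.4, 3.5, 5.0])])
        t_lo = detect_t_d(model, rec, threshold=0.2)
        t_hi = detect_t_d(model, rec, threshold=0.8)
        assert t_lo is not None and t_hi is not None and t_hi >= t_lo

    def test_duplicate_observations_leave_trajectory_unchanged(self):
        model = self._step_model()
        obs = [(0.0, "lactate", 1.0), (2 * H, "lactate", 5.0)]
        rec = make_record(obs=obs)
        rec_dup = make_record(obs=obs + [(2 * H, "lactate", 5.0)])
        a = compute_risk_trajectory(model, rec)
        b = compute_risk_trajectory(model, rec_dup)
        assert a.t_d == b.t_d
        np.testing.assert_array_equal(a.risk, b.risk)
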
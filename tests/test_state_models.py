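"""Tracking models: CV structure, baselines, evaluation, leakage guards."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from speechstate.state_models import (
    ModelConfig,
    baseline_predictions,
    classify_diagnosis,
    evaluate,
    fit_predict_personalized,
    fit_predict_population,
    PredictionSet,
)
from conftest import make_windowed_frame

FAST = ModelConfig(cost_grid=(0.1, 1.0), epsilon_grid=(0.1,), inner_folds=3)


class TestPopulationModel:
    def test_default_grid_has_12_combinations(self):
        cfg = ModelConfig()
        combos = list(itertools.product(cfg.cost_grid, cfg.epsilon_grid))
        assert len(combos) == 12

    def test_loso_fold_structure(self):
        frame = make_windowed_frame(5, 8, seed=1)
        pset = fit_predict_population(frame, FAST)
        # every participant predicted exactly once per window, none missing
        counts = pset.records.groupby("participant_id").size()
        assert len(counts) == 5 and (counts == 8).all()

    def test_needs_three_participants(self):
        frame = make_windowed_frame(2, 8)
        with pytest.raises(ValueError):
            fit_predict_population(frame, FAST)

    def test_shared_loadings_learnable(self):
        frame = make_windowed_frame(8, 12, loading_mode="shared", seed=0)
        pset = fit_predict_population(frame, FAST)
        ev = evaluate(pset, baseline_predictions(frame, "zero_correlation"))
        assert ev.mean_rho >= 0.4

    def test_missing_target_column_error(self):
        frame = make_windowed_frame(4, 6)
        with pytest.raises(ValueError):
            fit_predict_population(frame, FAST, target="nonexistent")

    def test_training_targets_carry_the_signal(self):
        """Shuffling training ratings must destroy test-fold performance."""
        frame = make_windowed_frame(6, 10, loading_mode="shared", seed=3)
        rng = np.random.default_rng(0)
        shuffled = frame.copy()
        shuffled["rating"] = rng.permutation(shuffled["rating"].to_numpy())
        pset = fit_predict_population(shuffled, FAST)
        # predictions were made from models fitted to noise: agreement with
        # the (shuffled) targets stays near chance
        ev = evaluate(pset, baseline_predictions(shuffled, "zero_correlation"))
        assert abs(ev.mean_rho) < 0.35


class TestPersonalizedModel:
    def test_below_threshold_skipped(self):
        frame = make_windowed_frame(3, 8, seed=2)
        n_calls = {pid: 34 for pid in frame["participant_id"].unique()}
        pset = fit_predict_personalized(
            frame, FAST, n_calls_by_participant=n_calls
        )
        assert pset.records.empty

    def test_heterogeneous_beats_population(self):
        frame = make_windowed_frame(6, 12, loading_mode="heterogeneous", seed=0)
        n_calls = {pid: 48 for pid in frame["participant_id"].unique()}
        pers = fit_predict_personalized(frame, FAST, n_calls_by_participant=n_calls)
        pop = fit_predict_population(frame, FAST)
        ev_pers = evaluate(pers)
        ev_pop = evaluate(pop)
        assert ev_pers.mean_rho > ev_pop.mean_rho + 0.15

    def test_forecast_not_better_than_concurrent(self):
        frame = make_windowed_frame(5, 14, loading_mode="shared", seed=7)
        n_calls = {pid: 56 for pid in frame["participant_id"].unique()}
        conc = evaluate(
            fit_predict_personalized(frame, FAST, lag=0, n_calls_by_participant=n_calls)
        )
        fore = evaluate(
            fit_predict_personalized(frame, FAST, lag=1, n_calls_by_participant=n_calls)
        )
        assert fore.mean_rho <= conc.mean_rho + 0.1


class TestLeakageGuards:
    def test_preprocessing_fitted_on_training_fold_only(self):
        """Imputation/scaling statistics must come from the training fold:
        corrupting one test row cannot move another test row's prediction."""
        from speechstate.state_models import _nested_fit_predict

        rng = np.random.default_rng(5)
        X_train = rng.normal(size=(30, 8))
        y_train = X_train[:, 0] * 2 + 5 + rng.normal(0, 0.1, 30)
        X_test = rng.normal(size=(4, 8))
        clean = _nested_fit_predict(
            X_train, y_train, X_test, FAST, None, np.random.default_rng(0)
        )
        poisoned = X_test.copy()
        poisoned[3, :] = 1e6  # extreme outlier in the test fold
        poisoned[2, 0] = np.nan  # missing cell imputed with training median
        dirty = _nested_fit_predict(
            X_train, y_train, poisoned, FAST, None, np.random.default_rng(0)
        )
        np.testing.assert_allclose(clean[:2], dirty[:2], atol=1e-9)

    def test_missing_test_cell_uses_training_median(self):
        from speechstate.state_models import _nested_fit_predict

        rng = np.random.default_rng(8)
        X_train = rng.normal(size=(30, 4))
        y_train = X_train[:, 1] + 5
        X_test = X_train[:1].copy()
        X_test[0, 0] = np.nan
        filled = X_train[:1].copy()
        filled[0, 0] = np.median(X_train[:, 0])
        a = _nested_fit_predict(
            X_train, y_train, X_test, FAST, None, np.random.default_rng(0)
        )
        b = _nested_fit_predict(
            X_train, y_train, filled, FAST, None, np.random.default_rng(0)
        )
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestBaselines:
    def test_loo_mean_hand_oracle(self):
        frame = pd.DataFrame(
            {
                "participant_id": ["A"] * 3,
                "window_index": [0, 1, 2],
                "rating": [2.0, 4.0, 6.0],
            }
        )
        pset = baseline_predictions(frame, "individual_loo_mean")
        assert pset.records["predicted"].tolist() == [5.0, 4.0, 3.0]

    def test_constant_ratings(self):
        frame = pd.DataFrame(
            {
                "participant_id": ["A"] * 3,
                "window_index": [0, 1, 2],
                "rating": [5.0, 5.0, 5.0],
            }
        )
        pset = baseline_predictions(frame, "individual_loo_mean")
        assert pset.records["predicted"].tolist() == [5.0, 5.0, 5.0]

    def test_zero_correlation_empty(self):
        frame = make_windowed_frame(3, 4)
        pset = baseline_predictions(frame, "zero_correlation")
        assert pset.records.empty and pset.mode == "baseline_zero"

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            baseline_predictions(make_windowed_frame(3, 4), "bogus")


class TestEvaluate:
    def _pset(self, records, mode="population_concurrent"):
        return PredictionSet(mode=mode, records=pd.DataFrame(records))

    def test_perfect_predictions(self):
        records = [
            {"participant_id": "A", "window_index": i, "actual": float(i), "predicted": float(i)}
            for i in range(5)
        ]
        ev = evaluate(self._pset(records))
        assert ev.mean_rho == pytest.approx(1.0)

    def test_identical_sets_no_improvement(self):
        records = [
            {"participant_id": p, "window_index": i, "actual": float(i), "predicted": float(i * 2)}
            for p in "ABC"
            for i in range(4)
        ]
        ev = evaluate(self._pset(records), self._pset(records, mode="baseline_individual_mean"))
        assert ev.p_vs_baseline == pytest.approx(1.0)

    def test_permuted_predictions_near_zero(self):
        rng = np.random.default_rng(3)
        records = []
        for p in range(10):
            actual = np.arange(12, dtype=float)
            predicted = rng.permutation(actual)
            for i in range(12):
                records.append(
                    {
                        "participant_id": f"P{p}",
                        "window_index": i,
                        "actual": actual[i],
                        "predicted": predicted[i],
                    }
                )
        zero = PredictionSet(
            mode="baseline_zero",
            records=pd.DataFrame(
                columns=["participant_id", "window_index", "actual", "predicted"]
            ),
        )
        ev = evaluate(self._pset(records), zero)
        assert abs(ev.mean_rho) < 0.15
        assert ev.p_vs_baseline > 0.05

    def test_constant_participant_excluded_and_counted(self):
        records = [
            {"participant_id": "A", "window_index": i, "actual": 5.0, "predicted": float(i)}
            for i in range(4)
        ] + [
            {"participant_id": "B", "window_index": i, "actual": float(i), "predicted": float(i)}
            for i in range(4)
        ]
        ev = evaluate(self._pset(records))
        assert ev.n_participants == 1 and ev.n_undefined == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            evaluate(self._pset([]))


class TestDiagnosisClassification:
    def _frame(self, labels, separation=5.0, n_calls=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        class_means = {c: i * separation for i, c in enumerate(sorted(set(labels.values())))}
        for pid, cls in labels.items():
            pid_offset = rng.normal(0, 1.0, size=6)  # individual variation
            for t in range(n_calls):
                rec = {
                    "participant_id": pid,
                    "call_time": pd.Timestamp("2024-01-01") + pd.Timedelta(days=t),
                    "provider_rating": 5,
                }
                for j in range(6):
                    rec[f"q1__f{j}"] = (
                        class_means[cls] + pid_offset[j] + rng.normal(0, 0.3)
                    )
                rows.append(rec)
        return pd.DataFrame(rows)

    def test_separable_two_class(self):
        labels = {f"P{i}": ("a" if i < 4 else "b") for i in range(8)}
        frame = self._frame(labels)
        _, uar, _ = classify_diagnosis(frame, labels, FAST, n_permutations=20)
        assert uar == pytest.approx(1.0)

    def test_random_labels_chance_level(self):
        rng = np.random.default_rng(1)
        labels = {f"P{i}": f"c{rng.integers(4)}" for i in range(20)}
        frame = self._frame(labels, separation=0.0, seed=2)
        _, uar, p = classify_diagnosis(frame, labels, FAST, n_permutations=50)
        assert abs(uar - 0.25) <= 0.15
        assert p > 0.05

    def test_single_class_error(self):
        labels = {f"P{i}": "a" for i in range(4)}
        with pytest.raises(ValueError):
            classify_diagnosis(self._frame(labels), labels, FAST)

    def test_small_class_error(self):
        labels = {"P0": "a", "P1": "a", "P2": "b"}
        with pytest.raises(ValueError):
            classify_diagnosis(self._frame(labels), labels, FAST)
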
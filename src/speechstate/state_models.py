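"""Population and personalized clinical-state tracking models.

The tracker fits L2-regularized linear support-vector regression
(liblinear) on windowed speech features with two-layer cross-validation:
an outer leave-one-subject-out loop (population model) or
leave-one-window-out loop (personalized model), and an inner grid search
over cost and epsilon that minimizes mean absolute error. Median
imputation and z-standardization are fitted on each training fold only.

Exposed statsmodels-style: build a :class:`ClinicalStateTracker` from a
feature table, call ``fit()``, inspect the returned
:class:`TrackingResults` (predictions, per-participant correlations,
significance vs baseline, ``summary()``).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC, LinearSVR

from speechstate.feature_assembly import (
    CallFeatureRow,
    impute_for_model,
    rows_to_frame,
    windowed_frame,
)
from speechstate.state_statistics import spearman

logger = logging.getLogger(__name__)

MODES = (
    "population_concurrent",
    "population_forecast",
    "personalized_concurrent",
    "personalized_forecast",
    "baseline_zero",
    "baseline_individual_mean",
    "diagnosis_classification",
)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and CV design for the tracking models.

    cost_grid / epsilon_grid follow the liblinear SVR convention
    (C and the epsilon-insensitive tube width p); window_size is the
    non-overlapping moving-average length in calls;
    min_samples_personalized is the minimum number of calls a participant
    needs before qualifying for an individually-trained model.
    """

    cost_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    epsilon_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    inner_folds: int = 5
    window_size: int = 4
    min_samples_personalized: int = 35
    forecasting_lag: int = 1
    seed: int = 0
    rating_range: tuple[float, float] = (1.0, 10.0)
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.epsilon_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class PredictionSet:
    """Aligned predicted-vs-actual series produced under one CV mode."""

    mode: str
    records: pd.DataFrame  # participant_id, window_index, actual, predicted

    def per_participant(self) -> dict[str, pd.DataFrame]:
        return {
            str(pid): sub for pid, sub in self.records.groupby("participant_id")
        }


@dataclass
class EvaluationResult:
    """Per-participant Spearman agreement and significance vs a baseline."""

    mode: str
    mean_rho: float
    per_participant_rho: dict[str, float]
    p_vs_baseline: float
    n_participants: int
    n_samples: int
    baseline_mode: str | None = None
    n_undefined: int = 0


# ---------------------------------------------------------------------------
# fold machinery


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def _fit_svr(
    X: np.ndarray, y: np.ndarray, cost: float, epsilon: float, config: ModelConfig
) -> LinearSVR:
    # liblinear primal L2-regularized SVR (-s 11): deterministic and fast
    model = LinearSVR(
        C=cost,
        epsilon=epsilon,
        loss="squared_epsilon_insensitive",
        dual=False,
        max_iter=config.max_iter,
        random_state=config.seed,
        tol=1e-4,
    )
    model.fit(X, y)
    return model


def _inner_folds(
    n: int, groups: np.ndarray | None, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Index folds for the inner grid search.

    Population model: folds respect participant grouping so the inner
    validation participant never appears in the inner training split.
    Personalized model: sequential (unshuffled) blocks of windows.
    """
    idx = np.arange(n)
    if groups is not None:
        uniq = np.unique(groups)
        k = min(k, uniq.size)
        if k < 2:
            return []
        perm = rng.permutation(uniq)
        blocks = np.array_split(perm, k)
        folds = []
        for block in blocks:
            val = idx[np.isin(groups, block)]
            train = idx[~np.isin(groups, block)]
            if val.size and train.size:
                folds.append((train, val))
        return folds
    k = min(k, n)
    if k < 2:
        return []
    folds = []
    for block in np.array_split(idx, k):
        train = np.setdiff1d(idx, block)
        if block.size and train.size:
            folds.append((train, block))
    return folds


def _nested_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ModelConfig,
    groups: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grid-searched SVR prediction with train-fold-only preprocessing."""
    folds = _inner_folds(len(y_train), groups, config.inner_folds, rng)
    best = (1.0, 0.1)
    if folds:
        best_loss = math.inf
        for cost, epsilon in itertools.product(config.cost_grid, config.epsilon_grid):
            losses = []
            for tr, val in folds:
                Xtr, med = impute_for_model(X_train[tr])
                mean, std = _standardize_fit(Xtr)
                Xtr = (Xtr - mean) / std
                Xval, _ = impute_for_model(X_train[val], medians=med)
                Xval = (Xval - mean) / std
                model = _fit_svr(Xtr, y_train[tr], cost, epsilon, config)
                pred = model.predict(Xval)
                losses.append(float(np.mean(np.abs(pred - y_train[val]))))
            loss = float(np.mean(losses))
            if loss < best_loss - 1e-12:
                best_loss = loss
                best = (cost, epsilon)
    Xtr, med = impute_for_model(X_train)
    mean, std = _standardize_fit(Xtr)
    Xtr = (Xtr - mean) / std
    Xte, _ = impute_for_model(X_test, medians=med)
    Xte = (Xte - mean) / std
    model = _fit_svr(Xtr, y_train, best[0], best[1], config)
    lo, hi = config.rating_range
    return np.clip(model.predict(Xte), lo, hi)


def _lagged_pairs(
    X: np.ndarray, y: np.ndarray, window_index: np.ndarray, lag: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Feature window t paired with the rating of window t+lag."""
    if lag == 0:
        return X, y, window_index
    if lag >= len(y):
        return X[:0], y[:0], window_index[:0]
    return X[:-lag], y[lag:], window_index[lag:]


def _split_windowed(
    wframe: pd.DataFrame, feature_names: list[str], target: str
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    if target not in wframe.columns:
        raise ValueError(f"target column {target!r} absent from windowed table")
    out = {}
    for pid, sub in wframe.groupby("participant_id", sort=True):
        sub = sub.sort_values("window_index")
        out[str(pid)] = (
            sub[feature_names].to_numpy(dtype=np.float64),
            sub[target].to_numpy(dtype=np.float64),
            sub["window_index"].to_numpy(),
        )
    return out


def _feature_names(wframe: pd.DataFrame, target: str) -> list[str]:
    meta = {"participant_id", "window_index", "rating", "n_calls", target}
    return [c for c in wframe.columns if c not in meta]


def fit_predict_population(
    wframe: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    target: str = "rating",
    lag: int = 0,
) -> PredictionSet:
    """Leave-one-subject-out population model over windowed features.

    For each participant the SVR is trained on all other participants'
    (feature window, rating) pairs — lagged by ``lag`` windows for
    forecasting — with the inner grid search grouped by participant.
    """
    names = _feature_names(wframe, target)
    per_pid = _split_windowed(wframe, names, target)
    pids = [p for p, (X, y, _) in per_pid.items() if len(y) > lag]
    if len(pids) < 3:
        raise ValueError("population model needs at least 3 participants with windows")
    rng = np.random.default_rng(config.seed)
    records = []
    for test_pid in pids:
        X_tr_parts, y_tr_parts, group_parts = [], [], []
        for pid in pids:
            if pid == test_pid:
                continue
            Xl, yl, _ = _lagged_pairs(*per_pid[pid], lag)
            keep = np.isfinite(yl)
            X_tr_parts.append(Xl[keep])
            y_tr_parts.append(yl[keep])
            group_parts.append(np.full(int(keep.sum()), pid, dtype=object))
        X_train = np.vstack(X_tr_parts)
        y_train = np.concatenate(y_tr_parts)
        groups = np.concatenate(group_parts)
        Xt, yt, wt = _lagged_pairs(*per_pid[test_pid], lag)
        keep = np.isfinite(yt)
        Xt, yt, wt = Xt[keep], yt[keep], wt[keep]
        if not len(yt):
            continue
        pred = _nested_fit_predict(X_train, y_train, Xt, config, groups, rng)
        for w, a, p in zip(wt, yt, pred):
            records.append(
                {
                    "participant_id": test_pid,
                    "window_index": int(w),
                    "actual": float(a),
                    "predicted": float(p),
                }
            )
    mode = "population_concurrent" if lag == 0 else "population_forecast"
    return PredictionSet(mode=mode, records=pd.DataFrame(records))


def fit_predict_personalized(
    wframe: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    target: str = "rating",
    lag: int = 0,
    n_calls_by_participant: dict[str, int] | None = None,
) -> PredictionSet:
    """Leave-one-window-out individually-trained models.

    Participants qualify with at least ``min_samples_personalized`` calls
    (checked against ``n_calls_by_participant`` when given, else against
    windows x window_size). Each window is predicted by a model trained on
    the participant's remaining windows only, with a sequential inner
    grid search.
    """
    names = _feature_names(wframe, target)
    per_pid = _split_windowed(wframe, names, target)
    rng = np.random.default_rng(config.seed)
    records = []
    for pid, (X, y, widx) in per_pid.items():
        n_calls = (
            n_calls_by_participant.get(pid, 0)
            if n_calls_by_participant is not None
            else len(y) * config.window_size
        )
        if n_calls < config.min_samples_personalized:
            logger.info(
                "participant %s below the %d-call personalized threshold; skipped",
                pid,
                config.min_samples_personalized,
            )
            continue
        Xl, yl, wl = _lagged_pairs(X, y, widx, lag)
        keep = np.isfinite(yl)
        Xl, yl, wl = Xl[keep], yl[keep], wl[keep]
        if len(yl) < 3:
            continue
        for i in range(len(yl)):
            train = np.arange(len(yl)) != i
            pred = _nested_fit_predict(
                Xl[train], yl[train], Xl[i : i + 1], config, None, rng
            )
            records.append(
                {
                    "participant_id": pid,
                    "window_index": int(wl[i]),
                    "actual": float(yl[i]),
                    "predicted": float(pred[0]),
                }
            )
    mode = "personalized_concurrent" if lag == 0 else "personalized_forecast"
    return PredictionSet(mode=mode, records=pd.DataFrame(records))


def baseline_predictions(wframe: pd.DataFrame, mode: str) -> PredictionSet:
    """Reference predictions the models are tested against.

    ``zero_correlation`` (population reference): no predictions — the
    baseline correlation is fixed at 0. ``individual_loo_mean``: each
    window is predicted by the mean rating of the participant's other
    windows.
    """
    if mode == "zero_correlation":
        return PredictionSet(
            mode="baseline_zero",
            records=pd.DataFrame(
                columns=["participant_id", "window_index", "actual", "predicted"]
            ),
        )
    if mode != "individual_loo_mean":
        raise ValueError(f"unknown baseline mode {mode!r}")
    records = []
    for pid, sub in wframe.groupby("participant_id", sort=True):
        sub = sub.sort_values("window_index")
        y = sub["rating"].to_numpy(dtype=np.float64)
        widx = sub["window_index"].to_numpy()
        keep = np.isfinite(y)
        y, widx = y[keep], widx[keep]
        if len(y) < 2:
            continue
        total = y.sum()
        for i in range(len(y)):
            records.append(
                {
                    "participant_id": str(pid),
                    "window_index": int(widx[i]),
                    "actual": float(y[i]),
                    "predicted": float((total - y[i]) / (len(y) - 1)),
                }
            )
    return PredictionSet(mode="baseline_individual_mean", records=pd.DataFrame(records))


def evaluate(
    predictions: PredictionSet,
    baseline: PredictionSet | None = None,
    alternative: str = "two-sided",
    min_windows: int = 3,
) -> EvaluationResult:
    """Per-participant Spearman agreement, averaged, tested vs baseline.

    Participants contribute when they have at least ``min_windows`` test
    windows and a defined rank correlation; undefined participants are
    excluded and counted. Against ``baseline_zero`` the test is a
    one-sample t-test of the per-participant rho values against 0;
    otherwise a paired t-test on the per-participant rho differences.
    Two identical series of rho values give p = 1.0 (no improvement).
    """
    if predictions.records.empty:
        raise ValueError("prediction set is empty")
    rhos: dict[str, float] = {}
    n_undefined = 0
    for pid, sub in predictions.records.groupby("participant_id"):
        if len(sub) < min_windows:
            n_undefined += 1
            continue
        rho, _ = spearman(sub["actual"], sub["predicted"])
        if np.isfinite(rho):
            rhos[str(pid)] = rho
        else:
            n_undefined += 1
    if not rhos:
        raise ValueError("no participant with enough test windows for evaluation")
    values = np.array(list(rhos.values()))

    p_vs_baseline = math.nan
    baseline_mode = None
    if baseline is not None:
        baseline_mode = baseline.mode
        if baseline.mode == "baseline_zero" or baseline.records.empty:
            diffs = values
        else:
            base_eval_rhos = {}
            for pid, sub in baseline.records.groupby("participant_id"):
                rho, _ = spearman(sub["actual"], sub["predicted"])
                if np.isfinite(rho):
                    base_eval_rhos[str(pid)] = rho
            shared = sorted(set(rhos) & set(base_eval_rhos))
            diffs = np.array([rhos[p] - base_eval_rhos[p] for p in shared])
        if diffs.size >= 2 and np.ptp(diffs) > 0:
            t, p = stats.ttest_1samp(diffs, 0.0)
            if alternative == "greater":
                p = p / 2.0 if t > 0 else 1.0 - p / 2.0
            p_vs_baseline = float(p)
        elif diffs.size and np.allclose(diffs, 0.0):
            p_vs_baseline = 1.0
    return EvaluationResult(
        mode=predictions.mode,
        mean_rho=float(values.mean()),
        per_participant_rho=rhos,
        p_vs_baseline=p_vs_baseline,
        n_participants=len(rhos),
        n_samples=len(predictions.records),
        baseline_mode=baseline_mode,
        n_undefined=n_undefined,
    )


def classify_diagnosis(
    rows_frame: pd.DataFrame,
    labels: dict[str, str],
    config: ModelConfig = ModelConfig(),
    n_permutations: int = 200,
) -> tuple[dict[str, float], float, float]:
    """Leave-one-subject-out diagnosis classification from mean features.

    One feature vector per participant (mean over that participant's
    calls), linear support-vector classification, unweighted average
    recall (mean of per-class recalls), and a label-permutation p-value.
    """
    meta = {"participant_id", "call_time", "provider_rating"}
    feature_names = [c for c in rows_frame.columns if c not in meta]
    pids, vectors, y = [], [], []
    for pid, sub in rows_frame.groupby("participant_id", sort=True):
        if str(pid) not in labels:
            continue
        with np.errstate(invalid="ignore"):
            vec = np.nanmean(sub[feature_names].to_numpy(dtype=np.float64), axis=0)
        pids.append(str(pid))
        vectors.append(vec)
        y.append(labels[str(pid)])
    X = np.vstack(vectors)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("diagnosis classification needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError(
            f"every class needs >= 2 participants; got {dict(zip(classes, counts))}"
        )

    def _loso_uar(y_arr: np.ndarray) -> tuple[dict[str, float], float]:
        preds = np.empty(len(y_arr), dtype=object)
        for i in range(len(y_arr)):
            train = np.arange(len(y_arr)) != i
            if np.unique(y_arr[train]).size < 2:
                preds[i] = y_arr[train][0]
                continue
            Xtr, med = impute_for_model(X[train])
            mean, std = _standardize_fit(Xtr)
            Xtr = (Xtr - mean) / std
            Xte, _ = impute_for_model(X[i : i + 1], medians=med)
            Xte = (Xte - mean) / std
            clf = LinearSVC(
                C=1.0, max_iter=config.max_iter, random_state=config.seed
            )
            clf.fit(Xtr, y_arr[train])
            preds[i] = clf.predict(Xte)[0]
        recalls = {}
        for cls in classes:
            mask = y_arr == cls
            recalls[str(cls)] = float((preds[mask] == cls).mean())
        return recalls, float(np.mean(list(recalls.values())))

    recalls, uar = _loso_uar(y)
    rng = np.random.default_rng(config.seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        _, uar_p = _loso_uar(perm)
        if uar_p >= uar:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)
    return recalls, uar, float(p_value)


# ---------------------------------------------------------------------------
# model-object surface


@dataclass
class TrackingResults:
    """Fitted tracking results: predictions, baselines, evaluations."""

    config: ModelConfig
    evaluations: dict[str, EvaluationResult]
    prediction_sets: dict[str, PredictionSet]

    def summary(self) -> str:
        lines = [
            "Clinical state tracking (windowed linear SVR, nested CV)",
            f"window size: {self.config.window_size} calls; "
            f"grid C={list(self.config.cost_grid)}, "
            f"eps={list(self.config.epsilon_grid)}",
            "-" * 72,
            f"{'mode':<26}{'mean rho':>10}{'p vs base':>12}"
            f"{'n part':>8}{'n samp':>8}",
        ]
        for mode, ev in self.evaluations.items():
            p = "" if math.isnan(ev.p_vs_baseline) else f"{ev.p_vs_baseline:.3g}"
            lines.append(
                f"{mode:<26}{ev.mean_rho:>10.3f}{p:>12}"
                f"{ev.n_participants:>8d}{ev.n_samples:>8d}"
            )
        return "\n".join(lines)

    def predictions_frame(self) -> pd.DataFrame:
        frames = []
        for mode, pset in self.prediction_sets.items():
            if pset.records.empty:
                continue
            sub = pset.records.copy()
            sub.insert(0, "mode", mode)
            frames.append(sub)
        if not frames:
            return pd.DataFrame(
                columns=["mode", "participant_id", "window_index", "actual", "predicted"]
            )
        return pd.concat(frames, ignore_index=True)


class ClinicalStateTracker:
    """Speech-feature model of provider-rated clinical state.

    Built from per-call feature rows; ``fit()`` windows the features,
    runs the requested cross-validated models plus their baselines, and
    returns a :class:`TrackingResults`.
    """

    def __init__(
        self,
        rows: Sequence[CallFeatureRow],
        config: ModelConfig = ModelConfig(),
    ):
        if not rows:
            raise ValueError("no feature rows")
        self.rows = list(rows)
        self.config = config
        self.frame = rows_to_frame(self.rows)
        self.n_calls_by_participant = (
            self.frame.groupby("participant_id").size().to_dict()
        )
        self.wframe = windowed_frame(self.rows, w=config.window_size)

    @classmethod
    def from_feature_table(
        cls, frame: pd.DataFrame, config: ModelConfig = ModelConfig()
    ) -> "ClinicalStateTracker":
        from speechstate.feature_assembly import FeatureManifest, default_manifest

        manifest = default_manifest()
        rows = []
        names = manifest.call_feature_names()
        for _, rec in frame.iterrows():
            rating = rec["provider_rating"]
            rows.append(
                CallFeatureRow(
                    participant_id=str(rec["participant_id"]),
                    call_time=pd.Timestamp(rec["call_time"]),
                    provider_rating=None if pd.isna(rating) else int(rating),
                    values=rec[names].to_numpy(dtype=np.float64),
                    manifest=manifest,
                )
            )
        return cls(rows, config=config)

    def fit(
        self,
        modes: Sequence[str] = (
            "population_concurrent",
            "population_forecast",
            "personalized_concurrent",
            "personalized_forecast",
        ),
    ) -> TrackingResults:
        cfg = self.config
        lag = cfg.forecasting_lag
        prediction_sets: dict[str, PredictionSet] = {}
        evaluations: dict[str, EvaluationResult] = {}
        zero = baseline_predictions(self.wframe, "zero_correlation")
        loo_mean = baseline_predictions(self.wframe, "individual_loo_mean")
        prediction_sets[zero.mode] = zero
        prediction_sets[loo_mean.mode] = loo_mean
        for mode in modes:
            if mode == "population_concurrent":
                pset = fit_predict_population(self.wframe, cfg, lag=0)
                base = zero
            elif mode == "population_forecast":
                pset = fit_predict_population(self.wframe, cfg, lag=lag)
                base = zero
            elif mode == "personalized_concurrent":
                pset = fit_predict_personalized(
                    self.wframe,
                    cfg,
                    lag=0,
                    n_calls_by_participant=self.n_calls_by_participant,
                )
                base = loo_mean
            elif mode == "personalized_forecast":
                pset = fit_predict_personalized(
                    self.wframe,
                    cfg,
                    lag=lag,
                    n_calls_by_participant=self.n_calls_by_participant,
                )
                base = loo_mean
            else:
                raise ValueError(f"unknown mode {mode!r}")
            prediction_sets[mode] = pset
            if not pset.records.empty:
                try:
                    evaluations[mode] = evaluate(pset, base)
                except ValueError as exc:
                    logger.info("mode %s not evaluable: %s", mode, exc)
        return TrackingResults(
            config=cfg, evaluations=evaluations, prediction_sets=prediction_sets
        )


@dataclass
class ClassificationResults:
    """Diagnosis-classification outcome with permutation significance."""

    per_class_recall: dict[str, float]
    uar: float
    permutation_p: float
    n_participants: int

    def summary(self) -> str:
        lines = [
            "Diagnosis classification (LOSO linear SVC on mean features)",
            f"unweighted average recall: {self.uar:.3f} "
            f"(permutation p = {self.permutation_p:.3g}, "
            f"n = {self.n_participants})",
        ]
        for cls, rec in self.per_class_recall.items():
            lines.append(f"  recall[{cls}] = {rec:.3f}")
        return "\n".join(lines)


class DiagnosisClassifier:
    """Participant-level diagnostic-group classifier from mean speech features."""

    def __init__(
        self,
        rows: Sequence[CallFeatureRow],
        labels: dict[str, str],
        config: ModelConfig = ModelConfig(),
    ):
        self.frame = rows_to_frame(list(rows))
        self.labels = labels
        self.config = config

    @classmethod
    def from_feature_table(
        cls,
        frame: pd.DataFrame,
        labels: dict[str, str],
        config: ModelConfig = ModelConfig(),
    ) -> "DiagnosisClassifier":
        obj = cls.__new__(cls)
        obj.frame = frame
        obj.labels = labels
        obj.config = config
        return obj

    def fit(self, n_permutations: int = 200) -> ClassificationResults:
        recalls, uar, p = classify_diagnosis(
            self.frame, self.labels, self.config, n_permutations=n_permutations
        )
        return ClassificationResults(
            per_class_recall=recalls,
            uar=uar,
            permutation_p=p,
            n_participants=len(
                set(self.frame["participant_id"]) & set(self.labels)
            ),
        )
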
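"""Score-reconstruction models under subject-aware cross-validation.

Four architectures — {statistical catalogue, random-kernel} features x
{ridge, gradient-boosted trees} predictors — fit either a regression of the
continuous SARA gait score on [0, 4] or one of the 15 binary class-pair
problems over {HC, 0, 1, 2, 3, 4}.  Evaluation uses a modified leave-one-out
cross-validation: one fold per video, with *all* other videos of the test
video's subject removed from training, so no subject-specific information
leaks.  A hybrid ordinal scheme turns continuous regression outputs into
discrete grades by delegating the final decision to the binary classifier of
the two flanking grades, with a decision threshold that moves with the
regressor's distance from the class boundary.

The predictors are sklearn-style estimators (:class:`TunedRegressor`,
:class:`TunedClassifier`) whose ``fit`` performs the inner, subject-grouped
hyperparameter search: a log-spaced alpha grid for ridge, random search over
(learning rate, max depth, n_estimators) for the gradient-boosted trees.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold, KFold

from .errors import (
    ConfigurationError,
    DegenerateFoldError,
    InsufficientDataError,
    InvalidArgumentError,
    SchemaError,
)
from .features import CatalogueFeaturizer, RocketFeaturizer
from .kinematics import CATEGORIES, category_combinations, extract_all
from .pose_io import GRADES, PoseSequence

logger = logging.getLogger(__name__)

SCORE_RANGE: tuple[float, float] = (0.0, 4.0)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """One architecture: feature family x predictor x task."""

    feature_set: str = "catalogue"  # "catalogue" | "kernel"
    predictor: str = "gbt"  # "gbt" | "ridge"
    task: str | tuple[str, str] = "regression"  # or ("binary", a, b) / tuple pair
    include_hc: bool = False  # regression-with-HC variant
    n_tuning_trials: int = 30
    inner_folds: int = 5
    ridge_alphas: np.ndarray = field(
        default_factory=lambda: np.logspace(-3, 3, 13))
    gbt_lr_range: tuple[float, float] = (0.01, 0.3)
    gbt_depth_range: tuple[int, int] = (2, 8)
    gbt_estimator_range: tuple[int, int] = (50, 500)
    n_kernels: int = 10_000
    crop_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in ("catalogue", "kernel"):
            raise InvalidArgumentError(f"unknown feature set {self.feature_set!r}")
        if self.predictor not in ("gbt", "ridge"):
            raise InvalidArgumentError(f"unknown predictor {self.predictor!r}")
        if self.n_tuning_trials < 1:
            raise InvalidArgumentError("n_tuning_trials must be >= 1")
        if isinstance(self.task, (tuple, list)) and self.task[0] != "binary":
            # allow ("binary", a, b) or plain (a, b)
            self.task = ("binary", *self.task)
        if isinstance(self.task, (tuple, list)):
            _, a, b = self.task
            if a not in GRADES or b not in GRADES or a == b:
                raise InvalidArgumentError(
                    f"binary task classes must be distinct members of {GRADES}")

    @property
    def is_regression(self) -> bool:
        return self.task == "regression"


@dataclass(frozen=True)
class FoldPlan:
    """One cross-validation fold: a test video and its admissible training set."""

    test_video: str
    train_videos: tuple[str, ...]


def make_loocv_folds(video_ids, subject_ids) -> list[FoldPlan]:
    """Modified leave-one-out folds: one per video, subject-disjoint.

    Every video is the test video of exactly one fold; all videos sharing
    the test video's subject are excluded from that fold's training set.
    """
    video_ids = list(video_ids)
    subject_ids = list(subject_ids)
    if len(video_ids) != len(subject_ids):
        raise InvalidArgumentError("video_ids and subject_ids length mismatch")
    if len(set(subject_ids)) < 2:
        raise InsufficientDataError("need at least 2 subjects for cross-validation")
    subj_of = dict(zip(video_ids, subject_ids))
    folds = []
    for vid in video_ids:
        train = tuple(v for v in video_ids if subj_of[v] != subj_of[vid])
        folds.append(FoldPlan(test_video=vid, train_videos=train))
    return folds


def check_fold_plan(folds: list[FoldPlan], subject_of: dict[str, str]) -> None:
    """Assert the leakage invariant; raises on any subject overlap."""
    tested = [f.test_video for f in folds]
    if len(set(tested)) != len(tested):
        raise InvalidArgumentError("a video is tested more than once")
    for f in folds:
        test_subj = subject_of[f.test_video]
        leaked = [v for v in f.train_videos if subject_of[v] == test_subj]
        if leaked:
            raise InvalidArgumentError(
                f"fold {f.test_video}: training set shares subject "
                f"{test_subj} via {leaked}")


# ---------------------------------------------------------------------------
# Tuned predictors
# ---------------------------------------------------------------------------


def _inner_splits(n: int, groups, n_folds: int, seed: int):
    groups = np.asarray(groups) if groups is not None else None
    if groups is not None and len(np.unique(groups)) >= 2:
        k = min(n_folds, len(np.unique(groups)))
        return list(GroupKFold(n_splits=k).split(np.zeros(n), groups=groups))
    k = min(n_folds, n)
    if k < 2:
        return []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


class _TunedBase(BaseEstimator):
    """Shared inner-search machinery for the ridge / gbt predictors."""

    def __init__(self, predictor="gbt", n_tuning_trials=30, inner_folds=5,
                 ridge_alphas=None, gbt_lr_range=(0.01, 0.3),
                 gbt_depth_range=(2, 8), gbt_estimator_range=(50, 500),
                 seed=0):
        self.predictor = predictor
        self.n_tuning_trials = n_tuning_trials
        self.inner_folds = inner_folds
        self.ridge_alphas = ridge_alphas
        self.gbt_lr_range = gbt_lr_range
        self.gbt_depth_range = gbt_depth_range
        self.gbt_estimator_range = gbt_estimator_range
        self.seed = seed

    # subclasses define: _make_ridge(alpha), _make_gbt(params), _loss(y, est, X)

    def _candidates(self) -> list[dict]:
        if self.predictor == "ridge":
            alphas = (np.logspace(-3, 3, 13) if self.ridge_alphas is None
                      else np.asarray(self.ridge_alphas))
            return [{"alpha": float(a)} for a in alphas]
        rng = np.random.default_rng(self.seed)
        lo, hi = self.gbt_lr_range
        cands = []
        for _ in range(self.n_tuning_trials):
            cands.append({
                "learning_rate": float(10 ** rng.uniform(math.log10(lo),
                                                         math.log10(hi))),
                "max_depth": int(rng.integers(self.gbt_depth_range[0],
                                              self.gbt_depth_range[1] + 1)),
                "n_estimators": int(rng.integers(self.gbt_estimator_range[0],
                                                 self.gbt_estimator_range[1] + 1)),
            })
        return cands

    def _make(self, params: dict):
        if self.predictor == "ridge":
            return self._make_ridge(params["alpha"])
        return self._make_gbt(params)

    def _search(self, X: np.ndarray, y: np.ndarray, groups) -> dict:
        splits = _inner_splits(len(y), groups, self.inner_folds, self.seed)
        candidates = self._candidates()
        if not splits:
            return candidates[0]
        best_params, best_loss = None, np.inf
        for params in candidates:
            losses = []
            for tr, va in splits:
                if not self._fold_ok(y[tr]):
                    continue
                est = self._make(params)
                est.fit(X[tr], y[tr])
                losses.append(self._loss(y[va], est, X[va]))
            loss = float(np.mean(losses)) if losses else np.inf
            if loss < best_loss - 1e-12:
                best_loss, best_params = loss, params
        return best_params if best_params is not None else candidates[0]

    def _fit_common(self, X, y, groups):
        Xm, names = _as_matrix(X)
        y = np.asarray(y)
        if len(y) < 2:
            raise InsufficientDataError("need at least 2 training samples")
        self.feature_names_in_ = names
        self.best_params_ = self._search(Xm, y, groups)
        self.model_ = self._make(self.best_params_)
        self.model_.fit(Xm, y)
        return self

    def _validate_X(self, X) -> np.ndarray:
        Xm, names = _as_matrix(X)
        if names != self.feature_names_in_:
            if set(names) == set(self.feature_names_in_):
                return X[self.feature_names_in_].to_numpy(dtype=float)
            raise SchemaError("feature names do not match the training schema")
        return Xm

    @staticmethod
    def _fold_ok(y) -> bool:
        return True


class TunedRegressor(_TunedBase, RegressorMixin):
    """Ridge or gradient-boosted regressor with subject-grouped inner tuning.

    ``fit(X, y, groups=...)`` selects hyperparameters by inner-fold RMSE and
    refits on the full training set; deterministic under ``seed``.
    """

    def _make_ridge(self, alpha):
        return Ridge(alpha=alpha)

    def _make_gbt(self, params):
        return xgb.XGBRegressor(random_state=self.seed, n_jobs=1,
                                verbosity=0, tree_method="hist", **params)

    def _loss(self, y_true, est, Xv):
        pred = est.predict(Xv)
        return float(np.sqrt(np.mean((np.asarray(y_true) - pred) ** 2)))

    def fit(self, X, y, groups=None):
        return self._fit_common(X, y, groups)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model_.predict(self._validate_X(X)), dtype=float)

    def predict_clamped(self, X) -> np.ndarray:
        """Predictions clamped to the score range for downstream ordinal use."""
        return np.clip(self.predict(X), *SCORE_RANGE)


class TunedClassifier(_TunedBase, ClassifierMixin):
    """Ridge or gradient-boosted binary classifier with inner tuning.

    Inner selection maximizes macro-F1.  ``predict_proba`` comes from the
    underlying model when available (gbt); the ridge classifier maps its
    decision function through a logistic link.
    """

    def _make_ridge(self, alpha):
        return RidgeClassifier(alpha=alpha)

    def _make_gbt(self, params):
        return xgb.XGBClassifier(random_state=self.seed, n_jobs=1,
                                 verbosity=0, tree_method="hist",
                                 eval_metric="logloss", **params)

    def _loss(self, y_true, est, Xv):
        pred = est.predict(Xv)
        return 1.0 - f1_score(y_true, pred, average="macro", zero_division=0)

    @staticmethod
    def _fold_ok(y) -> bool:
        return len(np.unique(y)) >= 2

    def fit(self, X, y, groups=None):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateFoldError(
                "training fold contains a single class; fold must be skipped")
        self.classes_ = classes
        self._y_index = {c: i for i, c in enumerate(classes)}
        y_enc = np.array([self._y_index[v] for v in y])
        self._fit_common(X, y_enc, groups)
        return self

    def predict(self, X) -> np.ndarray:
        idx = np.asarray(self.model_.predict(self._validate_X(X)), dtype=int)
        return self.classes_[idx]

    def predict_proba(self, X) -> np.ndarray:
        Xm = self._validate_X(X)
        if hasattr(self.model_, "predict_proba"):
            return np.asarray(self.model_.predict_proba(Xm))
        d = np.asarray(self.model_.decision_function(Xm), dtype=float)
        if d.ndim == 1:
            p1 = 1.0 / (1.0 + np.exp(-d))
            return np.column_stack([1.0 - p1, p1])
        e = np.exp(d - d.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def prob_of(self, X, cls) -> np.ndarray:
        """Probability of a specific class label."""
        proba = self.predict_proba(X)
        return proba[:, int(np.flatnonzero(self.classes_ == cls)[0])]


def make_predictor(config: ModelConfig):
    """The estimator matching a config's predictor/task."""
    cls = TunedRegressor if config.is_regression else TunedClassifier
    return cls(predictor=config.predictor,
               n_tuning_trials=config.n_tuning_trials,
               inner_folds=config.inner_folds,
               ridge_alphas=config.ridge_alphas,
               gbt_lr_range=config.gbt_lr_range,
               gbt_depth_range=config.gbt_depth_range,
               gbt_estimator_range=config.gbt_estimator_range,
               seed=config.seed)


def tune_and_fit(X, y, config: ModelConfig, groups=None):
    """Functional wrapper: build the configured predictor and fit it."""
    return make_predictor(config).fit(X, y, groups=groups)


# ---------------------------------------------------------------------------
# Hybrid ordinal post-processing
# ---------------------------------------------------------------------------


def boundary_threshold(fractional_part: float) -> float:
    """Default threshold policy τ = 1 − f.

    The closer the regression output sits to the *lower* grade boundary
    (small f), the higher the classifier probability required to promote the
    prediction to the upper grade.
    """
    return 1.0 - fractional_part


@dataclass(frozen=True)
class OrdinalPrediction:
    """Outcome of the hybrid ordinal decision for one sample."""

    raw: float
    pair: tuple[int, int] | None
    upper_probability: float | None
    threshold: float | None
    final_class: int


def hybrid_ordinal_predict(p: float, pair_classifiers: dict, features,
                           threshold_policy=boundary_threshold
                           ) -> OrdinalPrediction:
    """Discretize a regression output via the flanking-pair classifier.

    ``p`` is clamped to [0, 4]; with k = floor(p) and fractional part
    f = p − k, the (k, k+1) classifier's upper-class probability q is
    compared against τ = threshold_policy(f); the final grade is k+1 if
    q ≥ τ, else k.  Integer p short-circuits to grade p without invoking
    any classifier.  ``pair_classifiers`` maps (k, k+1) to a fitted
    binary classifier whose labels are the two grades.
    """
    p = float(np.clip(p, *SCORE_RANGE))
    if p == int(p):
        return OrdinalPrediction(raw=p, pair=None, upper_probability=None,
                                 threshold=None, final_class=int(p))
    k = min(int(math.floor(p)), 3)
    f = p - k
    pair = (k, k + 1)
    clf = pair_classifiers.get(pair)
    if clf is None:
        raise ConfigurationError(f"no classifier for adjacent pair {pair}")
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    q = float(clf.prob_of(features, k + 1)[0]) if hasattr(clf, "prob_of") \
        else float(clf.predict_proba(features)[0, 1])
    tau = float(threshold_policy(f))
    final = k + 1 if q >= tau else k
    return OrdinalPrediction(raw=p, pair=pair, upper_probability=q,
                             threshold=tau, final_class=final)


def fit_pair_classifiers(X, y, config: ModelConfig, groups=None) -> dict:
    """Fit the four adjacent-grade classifiers (k, k+1), k = 0..3.

    ``y`` holds integer grades 0..4.  Pairs missing a class in the training
    data are skipped with a log line.
    """
    y = np.asarray(y)
    classifiers = {}
    for k in range(4):
        mask = (y == k) | (y == k + 1)
        if len(np.unique(y[mask])) < 2:
            logger.warning("pair (%d, %d): single class in training data; "
                           "skipped", k, k + 1)
            continue
        cfg_clf = ModelConfig(
            feature_set=config.feature_set, predictor=config.predictor,
            task=("binary", str(k), str(k + 1)),
            n_tuning_trials=config.n_tuning_trials,
            inner_folds=config.inner_folds,
            ridge_alphas=config.ridge_alphas,
            gbt_lr_range=config.gbt_lr_range,
            gbt_depth_range=config.gbt_depth_range,
            gbt_estimator_range=config.gbt_estimator_range,
            seed=config.seed)
        clf = make_predictor(cfg_clf)
        g = np.asarray(groups)[mask] if groups is not None else None
        Xm = X[mask] if not isinstance(X, pd.DataFrame) else X.loc[mask]
        clf.fit(Xm, y[mask], groups=g)
        classifiers[(k, k + 1)] = clf
    return classifiers


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------


def binary_tasks() -> list[tuple[str, str]]:
    """The 15 unordered class pairs over {HC, 0, 1, 2, 3, 4}."""
    return list(itertools.combinations(GRADES, 2))


@dataclass
class ExperimentResult:
    """Out-of-fold predictions and per-combination scores of one experiment."""

    config: ModelConfig
    predictions: pd.DataFrame  # video_id, subject_id, y_true, one column per combo
    combo_scores: dict[tuple[str, ...], float]
    best_combo: tuple[str, ...]
    attributions: pd.DataFrame | None = None  # per-sample TreeSHAP, best combo

    @property
    def best_predictions(self) -> pd.DataFrame:
        out = self.predictions[["video_id", "subject_id", "y_true"]].copy()
        out["y_pred"] = self.predictions["+".join(self.best_combo)]
        return out


def featurize_cohort(sequences: list[PoseSequence], config: ModelConfig
                     ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-category feature tables for a cohort (rows follow ``sequences``).

    Returns (tables keyed by category, provenance of all features).  Kernel
    features share one kernel sample across categories (same seed), so
    per-category tables concatenate consistently.
    """
    channel_sets = [extract_all(seq) for seq in sequences]
    tables = {}
    provenances = []
    for cat in CATEGORIES:
        sets = [cs[cat] for cs in channel_sets]
        if config.feature_set == "catalogue":
            feat = CatalogueFeaturizer()
        else:
            feat = RocketFeaturizer(n_kernels=config.n_kernels,
                                    crop_length=config.crop_length,
                                    seed=config.seed)
        tables[cat] = feat.fit(sets).transform(sets)
        provenances.append(feat.provenance_)
    return tables, pd.concat(provenances)


def _combo_table(tables: dict[str, pd.DataFrame],
                 combo: tuple[str, ...]) -> pd.DataFrame:
    return pd.concat([tables[cat] for cat in combo], axis=1)


def _select_task(sequences: list[PoseSequence], config: ModelConfig):
    """Row mask and target vector for the configured task."""
    labels = np.array([s.label for s in sequences])
    if config.is_regression:
        mask = np.ones(len(sequences), bool) if config.include_hc \
            else labels != "HC"
        y = np.array([s.numeric_grade() for s in sequences])[mask]
    else:
        _, a, b = config.task
        mask = (labels == a) | (labels == b)
        y = labels[mask]
    return mask, y


def run_experiment(sequences: list[PoseSequence], config: ModelConfig,
                   combos: list[tuple[str, ...]] | None = None,
                   collect_attributions: bool = False,
                   feature_tables: dict[str, pd.DataFrame] | None = None,
                   ) -> ExperimentResult:
    """Out-of-fold evaluation over channel-category combinations.

    For every combination (all 15 by default), runs the modified LOOCV and
    records each video's out-of-fold prediction; the best combination is the
    one maximizing out-of-fold R² (regression) or macro-F1 (classification).
    With ``collect_attributions`` and a gbt predictor, per-test-sample
    TreeSHAP contributions are collected across folds for the best
    combination.
    """
    if combos is None:
        combos = category_combinations()
    if feature_tables is None:
        feature_tables, _ = featurize_cohort(sequences, config)

    mask, y = _select_task(sequences, config)
    idx = np.flatnonzero(mask)
    if len(idx) < 4:
        raise InsufficientDataError("too few videos for this task")
    video_ids = [sequences[i].visit_id or f"v{i}" for i in idx]
    subject_ids = [sequences[i].subject_id for i in idx]
    folds = make_loocv_folds(video_ids, subject_ids)
    check_fold_plan(folds, dict(zip(video_ids, subject_ids)))
    row_of = {v: r for r, v in enumerate(video_ids)}

    pred_df = pd.DataFrame({"video_id": video_ids, "subject_id": subject_ids,
                            "y_true": y})
    combo_scores: dict[tuple[str, ...], float] = {}
    attr_store: dict[tuple[str, ...], list[pd.DataFrame]] = {}

    for combo in combos:
        X = _combo_table(feature_tables, combo).iloc[idx].reset_index(drop=True)
        preds = np.full(len(idx), np.nan, dtype=object)
        attrs = []
        for fold in folds:
            tr = [row_of[v] for v in fold.train_videos]
            te = row_of[fold.test_video]
            est = make_predictor(config)
            try:
                est.fit(X.iloc[tr], y[tr],
                        groups=np.asarray(subject_ids)[tr])
            except DegenerateFoldError:
                logger.warning("fold %s: degenerate training fold skipped",
                               fold.test_video)
                continue
            X_te = X.iloc[[te]]
            if config.is_regression:
                preds[te] = float(est.predict(X_te)[0])
            else:
                preds[te] = est.predict(X_te)[0]
            if collect_attributions and config.predictor == "gbt":
                attrs.append(tree_shap_contributions(est, X_te))
        pred_df["+".join(combo)] = preds
        combo_scores[combo] = _combo_score(y, preds, config)
        if attrs:
            attr_store[combo] = attrs

    best_combo = max(combo_scores, key=lambda c: combo_scores[c])
    attributions = (pd.concat(attr_store[best_combo], ignore_index=True)
                    if best_combo in attr_store else None)
    logger.info("best combination %s (score %.4f)", "+".join(best_combo),
                combo_scores[best_combo])
    return ExperimentResult(config=config, predictions=pred_df,
                            combo_scores=combo_scores, best_combo=best_combo,
                            attributions=attributions)


def _combo_score(y, preds, config: ModelConfig) -> float:
    ok = np.array([p is not None and not (isinstance(p, float) and np.isnan(p))
                   for p in preds])
    if ok.sum() < 2:
        return -np.inf
    if config.is_regression:
        yt = np.asarray(y, float)[ok]
        yp = np.asarray(list(preds[ok]), float)
        ss_tot = np.sum((yt - yt.mean()) ** 2)
        if ss_tot == 0:
            return -np.inf
        return float(1.0 - np.sum((yt - yp) ** 2) / ss_tot)
    return float(f1_score(np.asarray(y)[ok], np.asarray(list(preds[ok])),
                          average="macro", zero_division=0))


def tree_shap_contributions(est, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TreeSHAP feature contributions of a fitted gbt predictor.

    Uses the booster's exact tree-path attribution; the bias column is
    dropped so rows carry only per-feature contributions.
    """
    model = est.model_ if isinstance(est, _TunedBase) else est
    booster = model.get_booster()
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    contrib = booster.predict(xgb.DMatrix(Xm),
                              pred_contribs=True).astype(np.float64)
    if contrib.ndim == 3:  # multiclass: sum of |contrib| over classes
        contrib = np.abs(contrib).sum(axis=1)
    names = (list(X.columns) if isinstance(X, pd.DataFrame)
             else est.feature_names_in_)
    return pd.DataFrame(contrib[:, :-1], columns=names)
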
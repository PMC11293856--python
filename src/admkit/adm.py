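"""Association distribution models (ADMs).

An ADM relates one pairwise association to the physico-chemical context of
the samples. Two variants exist:

* **cADM** — a multi-class classifier of the pair's per-sample co-occurrence
  state (co-presence / co-absence / exclusion), scored by balanced accuracy
  under stratified cross-validation;
* **rADM** — a regressor of the pair's per-sample local contribution alpha,
  scored by cross-validated R^2.

Both are trained on a small set of environmental predictors (by default
temperature, salinity, nitrate, silicate). Permutation feature importance
(PFI) quantifies each predictor's contribution as the drop in score when its
column is shuffled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import balanced_accuracy_score, r2_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .association import AlphaMatrix
from .compositional import AbundanceTable

__all__ = [
    "EnvTable",
    "CooccurrenceStates",
    "AdmModel",
    "FeatureImportance",
    "STATE_COPRESENCE",
    "STATE_COABSENCE",
    "STATE_EXCLUSION",
    "discretize_states",
    "fit_cadm",
    "fit_radm",
    "compare_learners",
    "permutation_feature_importance",
]

STATE_COPRESENCE = "copresence"
STATE_COABSENCE = "coabsence"
STATE_EXCLUSION = "exclusion"

DEFAULT_FEATURES = ["temperature", "salinity", "nitrate", "silicate"]

#: Pinned learner defaults so runs are reproducible across library versions.
LEARNER_DEFAULTS = {
    "random_forest": {"n_estimators": 500},
    "gradient_boosting": {"n_estimators": 100},
    "svm": {"kernel": "rbf"},
}


@dataclass
class EnvTable:
    """Per-sample environmental predictors (n samples x p features)."""

    sample_ids: list[str]
    features: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[0] != len(self.sample_ids):
            raise ValueError("features rows must match sample_ids")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("features columns must match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("environmental features contain missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, index=self.sample_ids, columns=self.feature_names)

    def subset(self, sample_ids: Sequence[str]) -> "EnvTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return EnvTable(list(sample_ids), self.features[idx], list(self.feature_names))


@dataclass
class CooccurrenceStates:
    """Three-state co-occurrence labels of one pair across samples."""

    pair: tuple[str, str]
    states: np.ndarray  # array of state strings
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        valid = {STATE_COPRESENCE, STATE_COABSENCE, STATE_EXCLUSION}
        bad = set(self.states) - valid
        if bad:
            raise ValueError(f"invalid states: {sorted(bad)}")
        if self.states.shape[0] != len(self.sample_ids):
            raise ValueError("states and sample_ids length mismatch")


@dataclass
class AdmModel:
    """A fitted cADM or rADM with its provenance.

    ``training_ranges`` holds per-feature (q2.5, q97.5) of the training
    features; projections refuse to extrapolate beyond them.
    """

    pair: tuple[str, str]
    variant: str  # "cadm" | "radm"
    learner: str
    predictors: list[str]
    estimator: BaseEstimator
    performance: dict
    training_ranges: dict[str, tuple[float, float]]
    seed: int
    n_train: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(features, dtype=float))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if not hasattr(self.estimator, "predict_proba"):
            raise AttributeError(f"learner {self.learner!r} provides no probabilities")
        return self.estimator.predict_proba(np.asarray(features, dtype=float))


@dataclass
class FeatureImportance:
    """Permutation importances: score drop per shuffled predictor."""

    pair: tuple[str, str]
    importances: dict[str, float]
    n_repeats: int
    seed: int

    def ranked(self) -> list[str]:
        return sorted(self.importances, key=lambda f: -self.importances[f])


def discretize_states(table: AbundanceTable, pair: tuple[str, str]) -> CooccurrenceStates:
    """Per-sample co-occurrence state of a pair from raw presence/absence."""
    for t in pair:
        if t not in table.taxon_ids:
            raise KeyError(f"unknown taxon {t!r}")
    a = table.values[:, table.taxon_ids.index(pair[0])] > 0
    b = table.values[:, table.taxon_ids.index(pair[1])] > 0
    states = np.where(
        a & b, STATE_COPRESENCE, np.where(~a & ~b, STATE_COABSENCE, STATE_EXCLUSION)
    ).astype(object)
    return CooccurrenceStates(pair=tuple(pair), states=states, sample_ids=list(table.sample_ids))


def _make_estimator(learner, variant: str, seed: int, **overrides) -> tuple[str, BaseEstimator]:
    """Resolve a learner name (or pass through an estimator instance).

    Hyperparameter overrides a learner does not accept (e.g. n_estimators
    for the SVM) are silently dropped so one override set can serve a mixed
    learner comparison.
    """
    if isinstance(learner, BaseEstimator):
        return type(learner).__name__, clone(learner)

    def build(cls, **fixed):
        params = dict(LEARNER_DEFAULTS.get(learner, {}))
        params.update(overrides)
        valid = cls().get_params()
        params = {k: v for k, v in params.items() if k in valid}
        return cls(**fixed, **params)

    if learner == "random_forest":
        cls = RandomForestClassifier if variant == "cadm" else RandomForestRegressor
        return learner, build(cls, random_state=seed)
    if learner == "gradient_boosting":
        cls = GradientBoostingClassifier if variant == "cadm" else GradientBoostingRegressor
        return learner, build(cls, random_state=seed)
    if learner == "svm":
        if variant == "cadm":
            return learner, build(SVC, random_state=seed, probability=False)
        return learner, build(SVR)
    if learner == "memorize":
        # exact-interpolation stub (1-nearest-neighbour); used to validate
        # the rho* projection scaling by round-trip
        if variant == "cadm":
            raise ValueError("memorize learner is regression-only")
        return learner, KNeighborsRegressor(n_neighbors=1)
    raise ValueError(f"unknown learner {learner!r}")


def _training_ranges(env: EnvTable, q_lo: float = 2.5, q_hi: float = 97.5) -> dict:
    lo = np.percentile(env.features, q_lo, axis=0)
    hi = np.percentile(env.features, q_hi, axis=0)
    return {f: (float(a), float(b)) for f, a, b in zip(env.feature_names, lo, hi)}


def fit_cadm(
    states: CooccurrenceStates,
    env: EnvTable,
    learner="random_forest",
    seed: int = 0,
    cv_folds: int = 5,
    **learner_params,
) -> AdmModel:
    """Fit a co-occurrence state classifier for one pair.

    Performance is the mean balanced accuracy over stratified
    ``cv_folds``-fold cross-validation; the returned estimator is refit on
    all samples.
    """
    if list(states.sample_ids) != list(env.sample_ids):
        env = env.subset(states.sample_ids)
    y = np.asarray(states.states, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(
            f"degenerate labels: only state {classes[0]!r} present, cannot fit a classifier"
        )
    name, est = _make_estimator(learner, "cadm", seed, **learner_params)
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("smallest class has < 2 members; cannot cross-validate")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(est, env.features, y, cv=cv, scoring="balanced_accuracy")
    est.fit(env.features, y)
    return AdmModel(
        pair=states.pair,
        variant="cadm",
        learner=name,
        predictors=list(env.feature_names),
        estimator=est,
        performance={"metric_name": "balanced_accuracy", "cv_value": float(scores.mean())},
        training_ranges=_training_ranges(env),
        seed=seed,
        n_train=len(y),
    )


def fit_radm(
    alpha: AlphaMatrix,
    env: EnvTable,
    learner="random_forest",
    seed: int = 0,
    cv_folds: int = 5,
    **learner_params,
) -> AdmModel:
    """Fit a regressor of per-sample alpha for one pair (CV R^2 performance)."""
    if list(alpha.sample_ids) != list(env.sample_ids):
        env = env.subset(alpha.sample_ids)
    y = np.asarray(alpha.alpha, dtype=float)
    if y.shape[0] < cv_folds:
        raise ValueError(f"need at least cv_folds={cv_folds} samples")
    name, est = _make_estimator(learner, "radm", seed, **learner_params)
    if np.ptp(y) == 0:
        warnings.warn(
            "constant alpha vector: R^2 undefined, model predicts the constant",
            RuntimeWarning,
            stacklevel=2,
        )
        cv_value = float("nan")
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(est, env.features, y, cv=cv, scoring="r2")
        cv_value = float(scores.mean())
    est.fit(env.features, y)
    return AdmModel(
        pair=alpha.pair,
        variant="radm",
        learner=name,
        predictors=list(env.feature_names),
        estimator=est,
        performance={"metric_name": "r2", "cv_value": cv_value},
        training_ranges=_training_ranges(env),
        seed=seed,
        n_train=len(y),
    )


def compare_learners(
    target,
    env: EnvTable,
    learners: Sequence = ("random_forest", "gradient_boosting", "svm"),
    seed: int = 0,
    cv_folds: int = 5,
    **learner_params,
) -> list[AdmModel]:
    """Fit one model per learner and rank them by CV performance.

    ``target`` is either :class:`CooccurrenceStates` (cADM) or
    :class:`AlphaMatrix` (rADM). Ties are broken by learner name.
    """
    if len(learners) < 1:
        raise ValueError("need at least one learner")
    fitter = fit_cadm if isinstance(target, CooccurrenceStates) else fit_radm
    models = [fitter(target, env, lr, seed=seed, cv_folds=cv_folds, **learner_params) for lr in learners]
    return sorted(models, key=lambda m: (-m.performance["cv_value"], m.learner))


def _score(model: AdmModel, features: np.ndarray, target: np.ndarray) -> float:
    pred = model.estimator.predict(features)
    if model.variant == "cadm":
        return float(balanced_accuracy_score(target, pred))
    return float(r2_score(target, pred))


def permutation_feature_importance(
    model: AdmModel,
    env: EnvTable,
    target,
    n_repeats: int = 10,
    seed: int = 0,
) -> FeatureImportance:
    """Permutation feature importance (PFI).

    Importance of a predictor = mean, over ``n_repeats`` seeded shuffles of
    its column, of (baseline score - score on the shuffled copy). Useless
    features score near zero and may go slightly negative.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if isinstance(target, CooccurrenceStates):
        y = np.asarray(target.states, dtype=object)
    elif isinstance(target, AlphaMatrix):
        y = np.asarray(target.alpha, dtype=float)
    else:
        y = np.asarray(target)
    X = np.asarray(env.features, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("target not aligned to env samples")
    rng = np.random.default_rng(seed)
    baseline = _score(model, X, y)
    importances: dict[str, float] = {}
    for f_idx, fname in enumerate(env.feature_names):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, f_idx] = rng.permutation(Xp[:, f_idx])
            drops[r] = baseline - _score(model, Xp, y)
        importances[fname] = float(drops.mean())
    return FeatureImportance(
        pair=model.pair, importances=importances, n_repeats=n_repeats, seed=seed
    )
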
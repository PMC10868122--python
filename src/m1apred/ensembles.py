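"""The nine ensemble classifiers: one blending stack, four bagging and
four boosting models, with their published hyperparameters frozen as the
default registry.

Families
--------
* **blending** — four heterogeneous base learners (a small feed-forward
  neural network, 3-nearest-neighbours, an RBF support-vector classifier
  and a randomized decision tree) whose held-out scores train a
  gradient-boosted meta-classifier.  The base learners are fit on an inner
  80% of the training partition and scored on the remaining 20% to build
  the meta-training table, then refit on the full partition for
  prediction; this holdout prevents the meta-learner from learning the
  base models' training error.
* **bagging** — random forest, extremely-randomized trees, a single
  randomized decision tree, and bootstrap aggregation of decision trees
  with out-of-bag scoring.
* **boosting** — gradient boosting, histogram-based gradient boosting,
  adaptive boosting, and extreme gradient boosting (XGBoost).

Features are standardized (zero mean, unit variance per column) with the
scaler fit on the training partition only.  Prediction thresholds scores
at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

BUNDLE_FORMAT_VERSION = 1

#: Registry of the nine published configurations, keyed by short name.
MODEL_REGISTRY: dict[str, dict[str, Any]] = {
    "blending": {
        "family": "blending",
        "hyperparameters": {
            "ann": {"hidden_layer_sizes": (5, 2), "activation": "relu", "solver": "lbfgs",
                    "learning_rate": "adaptive", "alpha": 1e-4, "random_state": 1},
            "knn": {"n_neighbors": 3},
            "svm": {"C": 10.0, "gamma": 1e-4, "kernel": "rbf", "coef0": 0.0, "probability": True},
            "dt": {"splitter": "random", "max_depth": 80, "min_samples_leaf": 4},
            "meta": {"n_estimators": 100, "criterion": "squared_error"},
            "holdout_fraction": 0.2,
        },
    },
    "bagging/random_forest": {
        "family": "bagging",
        "hyperparameters": {"n_estimators": 200, "max_depth": 50, "max_features": "sqrt",
                            "min_samples_split": 10, "min_samples_leaf": 5},
    },
    "bagging/extra_trees": {
        "family": "bagging",
        "hyperparameters": {"n_estimators": 100, "max_depth": 40, "max_features": "sqrt",
                            "bootstrap": True},
    },
    "bagging/decision_tree": {
        "family": "bagging",
        "hyperparameters": {"splitter": "random", "max_depth": 80, "min_samples_leaf": 4,
                            "min_weight_fraction_leaf": 0.1},
    },
    "bagging/bagging_classifier": {
        "family": "bagging",
        "hyperparameters": {"n_estimators": 100, "oob_score": True},
    },
    "boosting/gradient_boost": {
        "family": "boosting",
        "hyperparameters": {"learning_rate": 0.1, "n_estimators": 100, "criterion": "squared_error"},
    },
    "boosting/hist_gradient_boost": {
        "family": "boosting",
        "hyperparameters": {"max_iter": 200, "max_depth": 40, "warm_start": True},
    },
    "boosting/adaboost": {
        "family": "boosting",
        "hyperparameters": {"n_estimators": 50},
    },
    "boosting/xgboost": {
        "family": "boosting",
        "hyperparameters": {"n_estimators": 100, "max_depth": 40},
    },
}

MODEL_NAMES = tuple(MODEL_REGISTRY)


class ConfigurationError(ValueError):
    pass


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Name + family + hyperparameters of one classifier configuration."""

    name: str
    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_registry(cls, name: str, seed: int = 0, **overrides) -> "ModelSpec":
        if name not in MODEL_REGISTRY:
            raise ConfigurationError(f"unknown model {name!r}; choose from {list(MODEL_REGISTRY)}")
        entry = MODEL_REGISTRY[name]
        hp = {**entry["hyperparameters"], **overrides}
        return cls(name=name, family=entry["family"], hyperparameters=hp, seed=seed)


def _check_counts(hp: dict) -> None:
    for key in ("n_estimators", "max_iter", "n_neighbors", "max_depth"):
        val = hp.get(key)
        if val is not None and (not isinstance(val, (int, np.integer)) or val <= 0):
            raise ConfigurationError(f"{key} must be a positive integer, got {val!r}")


class BlendingClassifier:
    """Stacked generalization with an internal holdout for the meta-learner.

    Base learners are fit on an inner (1 - holdout_fraction) share of the
    training data; their class-1 scores on the held-out share form the
    meta-learner's training table.  After the meta-learner is fit, the base
    learners are refit on the full training partition.
    """

    def __init__(self, hyperparameters: dict, seed: int = 0):
        self.hp = hyperparameters
        self.seed = seed

    def _make_bases(self):
        hp = self.hp
        return [
            ("ann", MLPClassifier(max_iter=2000, **hp["ann"])),
            ("knn", KNeighborsClassifier(**hp["knn"])),
            ("svm", SVC(random_state=self.seed, **hp["svm"])),
            ("dt", DecisionTreeClassifier(random_state=self.seed, **hp["dt"])),
        ]

    def fit(self, X, y):
        from sklearn.model_selection import train_test_split

        X, y = np.asarray(X), np.asarray(y)
        frac = self.hp.get("holdout_fraction", 0.2)
        X_in, X_hold, y_in, y_hold = train_test_split(
            X, y, test_size=frac, random_state=self.seed, stratify=y)
        bases = self._make_bases()
        for _, est in bases:
            est.fit(X_in, y_in)
        meta_X = np.column_stack([est.predict_proba(X_hold)[:, 1] for _, est in bases])
        self.meta_ = GradientBoostingClassifier(random_state=self.seed, **self.hp["meta"])
        self.meta_.fit(meta_X, y_hold)
        # refit base learners on the full training partition for prediction
        self.bases_ = self._make_bases()
        for _, est in self.bases_:
            est.fit(X, y)
        return self

    def predict_proba(self, X):
        meta_X = np.column_stack([est.predict_proba(X)[:, 1] for _, est in self.bases_])
        return self.meta_.predict_proba(meta_X)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class VotingBagEnsemble:
    """Bootstrap aggregation with majority-vote labels and mean-score probabilities.

    Ties on the vote are broken toward the negative class (a sample is
    called positive only when a strict majority of members calls it so).
    """

    def __init__(self, base_estimator, n_estimators: int, seed: int = 0, oob_score: bool = False):
        self.base_estimator = base_estimator
        self.n_estimators = n_estimators
        self.seed = seed
        self.oob_score = oob_score

    def fit(self, X, y):
        X, y = np.asarray(X), np.asarray(y)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self.members_ = []
        oob_votes = np.zeros(n)
        oob_counts = np.zeros(n)
        for m in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)
            est = clone(self.base_estimator)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
            est.fit(X[idx], y[idx])
            self.members_.append(est)
            if self.oob_score:
                mask = np.ones(n, dtype=bool)
                mask[idx] = False
                if mask.any():
                    oob_votes[mask] += est.predict(X[mask])
                    oob_counts[mask] += 1
        if self.oob_score:
            seen = oob_counts > 0
            self.oob_score_ = float(((oob_votes[seen] / oob_counts[seen] > 0.5).astype(int) == y[seen]).mean())
        return self

    def predict_proba(self, X):
        scores = np.mean([est.predict_proba(X)[:, 1] for est in self.members_], axis=0)
        return np.column_stack([1 - scores, scores])

    def predict(self, X):
        votes = np.sum([est.predict(X) for est in self.members_], axis=0)
        return (votes > self.n_estimators / 2).astype(int)


def build_model(spec: ModelSpec):
    """Instantiate the untrained classifier a spec describes."""
    hp = dict(spec.hyperparameters)
    _check_counts(hp)
    if spec.family == "blending":
        for part in ("ann", "knn", "svm", "dt", "meta"):
            if part not in hp:
                raise ConfigurationError(f"blending spec missing {part!r} hyperparameters")
            _check_counts(hp[part])
        return BlendingClassifier(hp, seed=spec.seed)
    if spec.family == "bagging":
        if spec.name.endswith("random_forest"):
            return RandomForestClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("extra_trees"):
            return ExtraTreesClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("decision_tree"):
            return DecisionTreeClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("bagging_classifier"):
            return VotingBagEnsemble(DecisionTreeClassifier(), seed=spec.seed, **hp)
        raise ConfigurationError(f"unknown bagging model {spec.name!r}")
    if spec.family == "boosting":
        if spec.name.endswith("gradient_boost") and "hist" not in spec.name:
            return GradientBoostingClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("hist_gradient_boost"):
            return HistGradientBoostingClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("adaboost"):
            return AdaBoostClassifier(random_state=spec.seed, **hp)
        if spec.name.endswith("xgboost"):
            return XGBClassifier(random_state=spec.seed, eval_metric="logloss", **hp)
        raise ConfigurationError(f"unknown boosting model {spec.name!r}")
    raise ConfigurationError(f"unknown family {spec.family!r}")


@dataclass
class ScalerState:
    """Per-column standardization parameters learned from training data.

    Constant columns pass through unchanged (their deviation is treated
    as 1 to avoid division by zero).
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X) -> "ScalerState":
        sc = StandardScaler().fit(np.asarray(X, dtype=float))
        return cls(mean=sc.mean_.copy(), scale=sc.scale_.copy())

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.mean):
            raise ManifestError(f"expected {len(self.mean)} columns, got {X.shape[1]}")
        return (X - self.mean) / self.scale


def fit_scaler(X) -> ScalerState:
    """Learn standardization parameters on the training partition only."""
    return ScalerState.fit(X)


def apply_scaler(state: ScalerState, X) -> np.ndarray:
    return state.transform(X)


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to apply it consistently."""

    spec: ModelSpec
    scaler: ScalerState
    model: Any
    columns: tuple[str, ...]
    format_version: int = BUNDLE_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise ManifestError(f"{path} is not a model bundle")
        if bundle.format_version != BUNDLE_FORMAT_VERSION:
            raise ManifestError(f"bundle format {bundle.format_version} unsupported")
        return bundle

    def _check_columns(self, columns) -> None:
        if columns is not None and tuple(columns) != self.columns:
            raise ManifestError("feature-column manifest mismatch")


def train(spec: ModelSpec, X, y, columns=None, scale: bool = True) -> ModelBundle:
    """Fit the scaler (train rows only) and the model a spec describes.

    Deterministic given ``spec.seed``.  ``y`` must contain both classes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    scaler = fit_scaler(X) if scale else ScalerState(mean=np.zeros(X.shape[1]), scale=np.ones(X.shape[1]))
    Xs = scaler.transform(X)
    model = build_model(spec)
    model.fit(Xs, y)
    cols = tuple(columns) if columns is not None else tuple(f"f{i}" for i in range(X.shape[1]))
    return ModelBundle(spec=spec, scaler=scaler, model=model, columns=cols)


def predict_scores(bundle: ModelBundle, X, columns=None) -> np.ndarray:
    """Class-1 scores in [0, 1] for each row of X."""
    bundle._check_columns(columns)
    Xs = bundle.scaler.transform(np.asarray(X, dtype=float))
    return np.clip(bundle.model.predict_proba(Xs)[:, 1], 0.0, 1.0)


def predict(bundle: ModelBundle, X, columns=None, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: scores thresholded at 0.5 by default."""
    return (predict_scores(bundle, X, columns) >= threshold).astype(int)
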
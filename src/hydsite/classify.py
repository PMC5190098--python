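"""Random-forest stage: training, vote-fraction scoring, Gini importances.

The forest decides by majority vote over its trees, so the score of a sample
is the fraction of trees voting "site"; the hard call is score >= threshold
(default 0.5).  Feature ranking uses the mean decrease of Gini impurity as
implemented by scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

from .coupling import SequenceCouplingEncoder, WindowLike, _as_window
from .peptides import ValidationError


class SelfConsistencyError(ValueError):
    """Query center residue does not match the residue the model was trained for.

    A model trained on Pro-centered windows must only score Pro-centered
    queries, and likewise for Lys.
    """


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest hyperparameters.

    The defaults (100 trees, sqrt-of-features candidates per split, no class
    weighting) are the common convention; none of these were published for
    the original predictor, so all are exposed.
    """

    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    seed: int = 0
    class_weighting: str | None = None  # None | "balanced"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.class_weighting not in (None, "none", "balanced"):
            raise ValidationError(f"unknown class_weighting {self.class_weighting!r}")

    @property
    def sklearn_class_weight(self):
        return "balanced" if self.class_weighting == "balanced" else None


@dataclass
class TrainedForest:
    """A fitted ensemble plus the configuration that produced it."""

    config: ForestConfig
    estimator: RandomForestClassifier
    feature_count: int


def _validate_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"{X.shape[0]} feature rows but {y.shape[0]} labels"
        )
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 training samples")
    classes = set(np.unique(y).tolist())
    if classes != {0, 1}:
        raise ValidationError(
            f"labels must contain both classes 0 and 1, got {sorted(classes)}"
        )
    return X, y.astype(int)


def train_forest(features, labels, config: ForestConfig | None = None) -> TrainedForest:
    """Train a random forest; deterministic for a fixed ``config.seed``."""
    config = config or ForestConfig()
    X, y = _validate_xy(features, labels)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        class_weight=config.sklearn_class_weight,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return TrainedForest(config=config, estimator=rf, feature_count=X.shape[1])


def predict_scores(model: TrainedForest, features) -> np.ndarray:
    """Fraction of trees voting "site" for each row, in [0, 1]."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.feature_count:
        raise ValidationError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else 'bad'} columns, "
            f"model expects {model.feature_count}"
        )
    votes = np.zeros(X.shape[0])
    for tree in model.estimator.estimators_:
        votes += (tree.predict(X) == 1)
    return votes / len(model.estimator.estimators_)


class FeatureImportanceReport(NamedTuple):
    values: np.ndarray   # nonnegative, sums to 1
    ranking: np.ndarray  # feature indices, most important first


def feature_importances(model: TrainedForest) -> FeatureImportanceReport:
    """Gini importances (normalized to sum 1) with their descending ranking."""
    if not hasattr(model.estimator, "estimators_"):
        raise ValidationError("forest is not trained")
    values = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = values.sum()
    if total == 0:
        warnings.warn("no informative splits; importances are uniform")
        values = np.full_like(values, 1.0 / len(values))
    else:
        values = values / total
    ranking = np.argsort(-values, kind="stable")
    return FeatureImportanceReport(values=values, ranking=ranking)


class SequenceCoupledSiteClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end site classifier: coupling encoder + random forest.

    fit(X, y) takes raw peptide windows (strings or PeptideSample; all
    centered on the same residue) with binary labels, predict_scores(X)
    returns vote fractions, predict(X) hard calls at the decision threshold.
    Scoring windows centered on a different residue than the training
    windows raises :class:`SelfConsistencyError`.

    Parameters
    ----------
    n_trees, max_features, class_weighting, random_state
        Forest hyperparameters (see :class:`ForestConfig`).
    smoothing
        Pseudo-count mode of the coupling encoder.
    threshold
        Vote fraction above which a site is called, default 0.5.
    """

    def __init__(self, n_trees: int = 100, max_features="sqrt",
                 class_weighting: str | None = None, smoothing="none",
                 threshold: float = 0.5, random_state: int = 0):
        self.n_trees = n_trees
        self.max_features = max_features
        self.class_weighting = class_weighting
        self.smoothing = smoothing
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X: Sequence[WindowLike], y) -> "SequenceCoupledSiteClassifier":
        encoder = SequenceCouplingEncoder(smoothing=self.smoothing)
        encoder.fit(X, y)
        features = encoder.transform(X)
        forest = train_forest(
            features, np.asarray(y),
            ForestConfig(n_trees=self.n_trees, max_features=self.max_features,
                         seed=self.random_state, class_weighting=self.class_weighting),
        )
        self.encoder_ = encoder
        self.forest_ = forest
        self.target_ = encoder.target_
        self.xi_ = encoder.xi_
        self.classes_ = np.array([0, 1])
        return self

    def _check_windows(self, X: Sequence[WindowLike]) -> list[str]:
        if not hasattr(self, "forest_"):
            raise ValidationError("classifier is not fitted")
        windows = [_as_window(s) for s in X]
        for w in windows:
            center = w[len(w) // 2] if len(w) % 2 == 1 else None
            if center != self.target_:
                raise SelfConsistencyError(
                    f"query window {w!r} is centered on {center!r}; this model "
                    f"was trained for {self.target_!r}-centered windows"
                )
        return windows

    def predict_scores(self, X: Sequence[WindowLike]) -> np.ndarray:
        windows = self._check_windows(X)
        return predict_scores(self.forest_, self.encoder_.transform(windows))

    def predict_proba(self, X: Sequence[WindowLike]) -> np.ndarray:
        scores = self.predict_scores(X)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X: Sequence[WindowLike]) -> np.ndarray:
        return (self.predict_scores(X) >= self.threshold).astype(int)
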
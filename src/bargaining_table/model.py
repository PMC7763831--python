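"""Behavioral model: P(focal-point solution) from game and player features.

A bootstrap-aggregated ensemble of depth-bounded classification trees maps
the six predictors (see :mod:`bargaining_table.features`) to ``P_FP``, the
probability that a player implements the focal solution on a given board.
The predicted probability is the mean over trees of each tree's leaf
class-1 frequency, which gives a smoother estimate than a hard-vote
fraction and is what the stochastic adaptive agent consumes.

Hyperparameters (number of trees, maximum depth) are selected by k-fold
cross-validated accuracy at a 0.5 classification threshold.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, FeatureSchemaError, NoDataError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "TrainingObservation",
    "EnsembleConfig",
    "TrainedModel",
    "ConfusionMatrix",
    "AblationReport",
    "observations_to_frame",
    "fit_ensemble",
    "predict_pfp",
    "cross_validate",
    "evaluate_confusion",
    "svo_ablation",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingObservation:
    """One labeled instance: features plus the binary focal/not outcome."""

    features: FeatureVector
    y: int

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.y}")


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the bagged-tree ensemble.

    The admissible ranges (1-300 trees, depth 1-50) match the grid the
    model was designed to be searched over.
    """

    n_trees: int = 100
    max_depth: int = 10
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_trees <= 300:
            raise ValueError(f"n_trees must be in 1..300, got {self.n_trees}")
        if not 1 <= self.max_depth <= 50:
            raise ValueError(f"max_depth must be in 1..50, got {self.max_depth}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


@dataclass
class TrainedModel:
    """A fitted ensemble plus the feature manifest it was trained with.

    ``constant`` is set instead of ``estimator`` when the training data
    contained a single class, in which case prediction returns that class's
    probability (0.0 or 1.0) everywhere.
    """

    config: EnsembleConfig
    feature_names: tuple[str, ...]
    estimator: BaggingClassifier | None = None
    constant: float | None = None

    @property
    def includes_svo(self) -> bool:
        return "x6_svo_angle" in self.feature_names


def observations_to_frame(observations: Iterable[TrainingObservation]) -> pd.DataFrame:
    """Flatten observations into the tabular layout used throughout
    (columns x1..x6 and y, one row per (player, board) instance)."""
    rows = [{**obs.features.as_dict(), "y": obs.y} for obs in observations]
    return pd.DataFrame(rows)


def _design_matrix(data: pd.DataFrame, feature_names: Sequence[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in data.columns]
    if missing:
        raise FeatureSchemaError(f"data lacks feature columns {missing}")
    return data.loc[:, list(feature_names)].to_numpy(dtype=float)


def fit_ensemble(
    data: pd.DataFrame | Iterable[TrainingObservation],
    config: EnsembleConfig | None = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> TrainedModel:
    """Fit the bagged-tree ensemble.

    Each of ``config.n_trees`` trees is grown on a bootstrap resample of
    the same size as the training set, with depth capped at
    ``config.max_depth``.  Fitting is deterministic given (data, config).
    """
    config = config or EnsembleConfig()
    if not isinstance(data, pd.DataFrame):
        data = observations_to_frame(data)
    if len(data) == 0:
        raise NoDataError("cannot fit on an empty dataset")
    feature_names = tuple(feature_names)
    X = _design_matrix(data, feature_names)
    y = data["y"].to_numpy(dtype=int)
    classes = np.unique(y)
    if len(classes) == 1:
        return TrainedModel(config=config, feature_names=feature_names, constant=float(classes[0]))
    estimator = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_depth=config.max_depth),
        n_estimators=config.n_trees,
        bootstrap=True,
        max_samples=1.0,
        random_state=config.seed,
    )
    estimator.fit(X, y)
    return TrainedModel(config=config, feature_names=feature_names, estimator=estimator)


def _coerce_features(
    model: TrainedModel, features: FeatureVector | dict | pd.DataFrame
) -> pd.DataFrame:
    if isinstance(features, FeatureVector):
        features = features.as_dict()
    if isinstance(features, dict):
        features = pd.DataFrame([features])
    offered = set(features.columns) - {"y", "player_id", "board_id"}
    if offered != set(model.feature_names):
        raise FeatureSchemaError(
            f"model trained on {sorted(model.feature_names)} but offered {sorted(offered)}"
        )
    return features


def predict_pfp(
    model: TrainedModel, features: FeatureVector | dict | pd.DataFrame
) -> float | np.ndarray:
    """Predict P_FP, the probability of focal-point play.

    Returns a scalar for a single feature vector and an array for a
    DataFrame of instances.  Raises :class:`FeatureSchemaError` when the
    offered features do not match the training manifest (e.g. an SVO-less
    model handed an SVO column).
    """
    scalar = not isinstance(features, pd.DataFrame)
    frame = _coerce_features(model, features)
    if model.constant is not None:
        out = np.full(len(frame), model.constant)
    else:
        X = _design_matrix(frame, model.feature_names)
        proba = model.estimator.predict_proba(X)
        col = list(model.estimator.classes_).index(1)
        out = proba[:, col]
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts with the derived per-class rates.

    ``n01`` counts true-class-0 instances predicted as class 1, etc.
    TPR/FNR are row-conditional (per true class); PPV/FDR are
    column-conditional (per predicted class).
    """

    n00: int
    n01: int
    n10: int
    n11: int

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def accuracy(self) -> float:
        return (self.n00 + self.n11) / self.total

    @property
    def tpr(self) -> tuple[float, float]:
        return self.n00 / (self.n00 + self.n01), self.n11 / (self.n10 + self.n11)

    @property
    def fnr(self) -> tuple[float, float]:
        t0, t1 = self.tpr
        return 1.0 - t0, 1.0 - t1

    @property
    def ppv(self) -> tuple[float, float]:
        return self.n00 / (self.n00 + self.n10), self.n11 / (self.n01 + self.n11)

    @property
    def fdr(self) -> tuple[float, float]:
        p0, p1 = self.ppv
        return 1.0 - p0, 1.0 - p1


def evaluate_confusion(
    model: TrainedModel, data: pd.DataFrame, threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion counts of the model on labeled data at a threshold."""
    if len(data) == 0:
        raise NoDataError("cannot evaluate on an empty dataset")
    keep = [c for c in data.columns if c in model.feature_names or c == "y"]
    p = predict_pfp(model, data[keep].drop(columns="y"))
    pred = (p > threshold).astype(int)
    y = data["y"].to_numpy(dtype=int)
    return ConfusionMatrix(
        n00=int(np.sum((y == 0) & (pred == 0))),
        n01=int(np.sum((y == 0) & (pred == 1))),
        n10=int(np.sum((y == 1) & (pred == 0))),
        n11=int(np.sum((y == 1) & (pred == 1))),
    )


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(order, n_folds)]


def cross_validate(
    data: pd.DataFrame,
    grid: Sequence[EnsembleConfig],
    threshold: float = 0.5,
    feature_names: Sequence[str] = FEATURE_NAMES,
    seed: int = 0,
) -> tuple[EnsembleConfig, pd.DataFrame]:
    """Select hyperparameters by k-fold cross-validated accuracy.

    Folds are a seeded uniform shuffle (no stratification) split into
    near-equal parts; every config in the grid is scored by mean held-out
    accuracy at ``threshold``.  Ties go to fewer trees, then smaller depth.

    Returns the winning config and a per-config accuracy table.
    """
    grid = list(grid)
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    if len(data) == 0:
        raise NoDataError("cannot cross-validate an empty dataset")
    n_folds = grid[0].n_folds
    folds = _fold_indices(len(data), n_folds, np.random.default_rng(seed))
    rows = []
    for config in grid:
        accs = []
        for k, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != k])
            fitted = fit_ensemble(data.iloc[train_idx], config, feature_names)
            cm = evaluate_confusion(fitted, data.iloc[test_idx], threshold)
            accs.append(cm.accuracy)
        rows.append(
            {
                "n_trees": config.n_trees,
                "max_depth": config.max_depth,
                "cv_accuracy": float(np.mean(accs)),
            }
        )
    table = pd.DataFrame(rows)
    # best accuracy, parsimony on ties: fewer trees, then shallower
    order = table.sort_values(
        ["cv_accuracy", "n_trees", "max_depth"], ascending=[False, True, True]
    )
    best = grid[order.index[0]]
    return best, table


@dataclass(frozen=True)
class AblationReport:
    with_svo_config: EnsembleConfig
    with_svo_accuracy: float
    without_svo_config: EnsembleConfig
    without_svo_accuracy: float

    @property
    def accuracy_drop(self) -> float:
        return self.with_svo_accuracy - self.without_svo_accuracy


def svo_ablation(
    data: pd.DataFrame,
    grid: Sequence[EnsembleConfig],
    threshold: float = 0.5,
    seed: int = 0,
) -> AblationReport:
    """Paired cross-validation with and without the SVO feature.

    Both runs share the same fold split, so the accuracy difference
    isolates the contribution of the SVO angle.
    """
    full = tuple(FEATURE_NAMES)
    reduced = tuple(n for n in full if n != "x6_svo_angle")
    best_with, table_with = cross_validate(data, grid, threshold, full, seed)
    best_without, table_without = cross_validate(data, grid, threshold, reduced, seed)
    return AblationReport(
        with_svo_config=best_with,
        with_svo_accuracy=float(table_with["cv_accuracy"].max()),
        without_svo_config=best_without,
        without_svo_accuracy=float(table_without["cv_accuracy"].max()),
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model as a self-describing pickle archive."""
    payload = {
        "config": model.config,
        "feature_names": model.feature_names,
        "estimator": model.estimator,
        "constant": model.constant,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return TrainedModel(**payload)
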
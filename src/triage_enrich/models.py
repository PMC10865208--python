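"""Triage classifiers: k-nearest-neighbour, support-vector machine, multilayer perceptron.

All three models share one train/predict interface so the pipeline can
swap them without code changes. The MLP uses rectified-linear hidden
units, the Adam optimizer and the cross-entropy loss; kNN and SVM take
standard defaults (k=5, RBF kernel). Stratified 4-fold cross-validation
on the training table provides per-fold diagnostics; the returned model
is refit on the full training table. Rows with a missing value in any
feature column are dropped (complete-case) with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import FeatureTable
from .evaluation import confusion, f1_from_confusion

__all__ = ["ModelConfig", "TrainedModel", "drop_incomplete", "train_model", "predict"]

log = logging.getLogger(__name__)

MODEL_NAMES = ("knn", "svm", "mlp")


@dataclass(frozen=True)
class ModelConfig:
    model: str = "svm"
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    mlp_hidden: tuple[int, ...] = (64,)
    mlp_max_epochs: int = 300
    mlp_patience: int = 30
    mlp_learning_rate: float = 0.01
    cv_folds: int = 4
    n_runs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}, got {self.model!r}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class TrainedModel:
    """A fitted predictor plus the bookkeeping needed to apply it safely."""

    estimator: object
    feature_names: list[str]
    condition: str = ""
    run_index: int = 0
    fold_diagnostics: list[dict] = field(default_factory=list)
    classes_: np.ndarray | None = None


def drop_incomplete(table: FeatureTable) -> tuple[FeatureTable, int]:
    """Remove rows with any missing feature value; returns (table, n dropped)."""
    complete = ~table.features.isna().any(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d incomplete rows of %d", n_dropped, len(table))
    return table.subset_rows(complete), n_dropped


def _make_estimator(cfg: ModelConfig, seed: int):
    if cfg.model == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    if cfg.model == "svm":
        return SVC(kernel=cfg.svm_kernel, C=cfg.svm_c, random_state=seed)
    return MLPClassifier(
        hidden_layer_sizes=tuple(cfg.mlp_hidden),
        activation="relu",
        solver="adam",
        max_iter=cfg.mlp_max_epochs,
        early_stopping=True,
        n_iter_no_change=cfg.mlp_patience,
        validation_fraction=0.25,
        learning_rate_init=cfg.mlp_learning_rate,
        random_state=seed,
    )


def train_model(train: FeatureTable, cfg: ModelConfig, run_index: int = 0) -> TrainedModel:
    """Fit one classifier on a (balanced, feature-selected) training table.

    Cross-validation folds are scored (accuracy and macro F1) for
    diagnostics before the final refit on all rows. Reproducible given
    the config seed; successive runs should pass distinct ``run_index``
    values, which offset the seed.
    """
    if not train.feature_names:
        raise ValueError("empty feature list")
    table, _ = drop_incomplete(train)
    X = table.features.to_numpy(dtype=float)
    y = table.labels
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes after complete-case filtering, got {len(classes)}")
    seed = int((cfg.seed + 7919 * run_index) % (2**31 - 1))

    diagnostics = []
    counts = np.bincount(y)
    n_folds = min(cfg.cv_folds, int(counts[counts > 0].min()))
    if n_folds >= 2:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            est = _make_estimator(cfg, seed)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[va])
            cm = confusion(y[va], pred, classes=tuple(sorted(set(y.tolist()))))
            rep = f1_from_confusion(cm)
            diagnostics.append(
                {
                    "fold": fold,
                    "accuracy": float((pred == y[va]).mean()),
                    "macro_f1": rep.macro_f1,
                }
            )

    est = _make_estimator(cfg, seed)
    est.fit(X, y)
    return TrainedModel(
        estimator=est,
        feature_names=table.feature_names,
        condition=table.condition,
        run_index=run_index,
        fold_diagnostics=diagnostics,
        classes_=classes,
    )


def predict(model: TrainedModel, eval_table: FeatureTable) -> np.ndarray:
    """Predict triage classes for the rows of an evaluation table."""
    missing = [c for c in model.feature_names if c not in eval_table.features.columns]
    if missing:
        raise KeyError(f"evaluation table lacks model feature columns: {missing}")
    X = eval_table.features.loc[:, model.feature_names].to_numpy(dtype=float)
    if len(X) == 0:
        return np.array([], dtype=int)
    if np.isnan(X).any():
        raise ValueError("evaluation rows contain missing values; drop incomplete rows first")
    return np.asarray(model.estimator.predict(X), dtype=int)
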
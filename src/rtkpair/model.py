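"""Class-weighted C-SVM training, tuning, and decision-value combination.

The classifier is a C-SVM (libsvm, via scikit-learn's SVC) with per-class
misclassification weights proportional to the opposite class's size, so
the rare interacting class is not swamped by the enumerated negatives.
Decision values (signed distances to the separating surface) are the
model output; thresholding at 0 gives predicted labels.

Two models' decision values can be merged into "combined results": a
weighted average where each model's weight is its AUC minus 0.5, i.e. its
improvement over random ranking.  A model at or below chance gets a small
epsilon weight instead of a zero or negative one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import ClassWeights, class_weights

MODEL_FORMAT_VERSION = 1

#: Epsilon floor for combination weights (chance-level or worse models).
COMBINE_EPS = 1e-6


class ModelError(ValueError):
    pass


class ModelFormatError(ModelError):
    """Serialized model file is corrupted or from an incompatible version."""


def libsvm_grid() -> tuple[list[float], list[float]]:
    """The classic wide libsvm grid: C in 2^-5..2^15, gamma in 2^-15..2^3, step 2^2."""
    return (
        [2.0**e for e in range(-5, 16, 2)],
        [2.0**e for e in range(-15, 4, 2)],
    )


def default_grid() -> tuple[list[float], list[float]]:
    """Coarse default grid keeping repeated-CV protocols at desk scale."""
    return ([0.1, 1.0, 10.0, 100.0], [0.01, 0.1, 1.0])


@dataclass(frozen=True)
class SvmConfig:
    """Kernel, regularization and tuning-grid settings for the pair SVM.

    ``gamma`` may be a positive real or the sentinel ``"scale"``
    (variance-scaled, the library default).  ``class_weights=None`` means
    derive proportional weights from the training labels at fit time.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    class_weights: ClassWeights | None = None
    grid_C: tuple[float, ...] = field(default_factory=lambda: tuple(default_grid()[0]))
    grid_gamma: tuple[float, ...] = field(default_factory=lambda: tuple(default_grid()[1]))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ModelError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.C <= 0:
            raise ModelError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ModelError("gamma must be positive")
        if not self.grid_C:
            raise ModelError("grid_C must be nonempty")
        if self.kernel == "rbf" and not self.grid_gamma:
            raise ModelError("grid_gamma must be nonempty for the rbf kernel")


@dataclass
class TrainedPairModel:
    """A fitted SVM plus the bookkeeping needed to score new pairs.

    ``training_auc`` is the mean inner-CV AUC measured during tuning on
    the training data (None if never tuned); it supplies the weight when
    this model's decisions are combined with another's.
    """

    svc: SVC
    config: SvmConfig
    recipe: str
    n_features: int
    training_auc: float | None = None
    vocab: object | None = None  # DomainVocabulary snapshot for domain-based recipes


def _resolve_class_weights(y: np.ndarray, config: SvmConfig) -> ClassWeights:
    if config.class_weights is not None:
        return config.class_weights
    return class_weights(int((y == 1).sum()), int((y == 0).sum()))


def train(
    X: np.ndarray, y: Sequence[int], config: SvmConfig, recipe: str = "unspecified"
) -> TrainedPairModel:
    """Fit the class-weighted C-SVM at the config's resolved (C, gamma)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != len(y):
        raise ModelError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    if not np.isfinite(X).all():
        raise ModelError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ModelError("training labels must contain both classes")
    cw = _resolve_class_weights(y, config)
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma if config.kernel == "rbf" else "scale",
        class_weight={1: cw.w_pos, 0: cw.w_neg},
        random_state=config.seed,
    )
    svc.fit(X, y)
    return TrainedPairModel(svc=svc, config=config, recipe=recipe, n_features=X.shape[1])


def _grid_points(config: SvmConfig) -> list[tuple[float, float | str]]:
    if config.kernel == "linear":
        return [(c, "scale") for c in sorted(config.grid_C)]
    return [(c, g) for c in sorted(config.grid_C) for g in sorted(config.grid_gamma)]


def inner_cv_auc(
    X: np.ndarray, y: np.ndarray, config: SvmConfig, n_folds: int = 5, seed: int = 0
) -> float:
    """Mean held-out-fold AUC of the config's (C, gamma) under stratified CV."""
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in splitter.split(X, y):
        m = train(X[train_idx], y[train_idx], config)
        scores = m.svc.decision_function(X[test_idx])
        aucs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(aucs))


def tune(
    X: np.ndarray,
    y: Sequence[int],
    config: SvmConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[SvmConfig, float]:
    """Pick (C, gamma) maximizing mean inner-CV AUC over the config's grid.

    Ties break toward smaller C, then smaller gamma.  Returns the resolved
    config and the winning mean AUC.  A single-point grid skips nothing:
    its AUC is still measured (it feeds decision-value combination).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    best: tuple[SvmConfig, float] | None = None
    for c, g in _grid_points(config):
        candidate = replace(config, C=c, gamma=g)
        auc = inner_cv_auc(X, y, candidate, n_folds=n_folds, seed=seed)
        if best is None or auc > best[1] + 1e-12:
            best = (candidate, auc)
    assert best is not None
    return best


def fit_tuned(
    X: np.ndarray,
    y: Sequence[int],
    config: SvmConfig,
    recipe: str = "unspecified",
    n_folds: int = 5,
    seed: int = 0,
) -> TrainedPairModel:
    """Tune on (X, y), refit at the winning point, record the inner-CV AUC."""
    resolved, auc = tune(X, y, config, n_folds=n_folds, seed=seed)
    model = train(X, y, resolved, recipe=recipe)
    model.training_auc = auc
    return model


def decision_values(model: TrainedPairModel, X: np.ndarray) -> np.ndarray:
    """Signed decision values, one per row; >0 means predicted interacting."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ModelError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model ({model.recipe}) expects {model.n_features}"
        )
    return model.svc.decision_function(X)


@dataclass(frozen=True)
class CombinationWeights:
    """Per-model weights a = AUC_A - 0.5 and b = AUC_B - 0.5, floored at eps."""

    a: float
    b: float

    @classmethod
    def from_aucs(cls, auc_a: float, auc_b: float, eps: float = COMBINE_EPS) -> "CombinationWeights":
        for auc in (auc_a, auc_b):
            if not (0.0 <= auc <= 1.0):
                raise ModelError(f"AUC must be in [0, 1], got {auc}")
        return cls(a=max(auc_a - 0.5, eps), b=max(auc_b - 0.5, eps))


def combine_decisions(
    f_a: Sequence[float],
    f_b: Sequence[float],
    auc_a: float,
    auc_b: float,
    eps: float = COMBINE_EPS,
) -> np.ndarray:
    """AUC-weighted average of two models' decision values.

    f_comp = (a*f_A + b*f_B) / (a + b) with a = max(AUC_A - 0.5, eps) and
    b = max(AUC_B - 0.5, eps), so each model counts by how far it beats
    random ranking.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if f_a.shape != f_b.shape:
        raise ModelError(f"decision-value length mismatch: {f_a.shape} vs {f_b.shape}")
    w = CombinationWeights.from_aucs(auc_a, auc_b, eps=eps)
    return (w.a * f_a + w.b * f_b) / (w.a + w.b)


def save_model(model: TrainedPairModel, path: str | Path) -> None:
    """Serialize as a self-describing versioned bundle (joblib)."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "recipe": model.recipe,
            "config": model.config,
            "n_features": model.n_features,
            "training_auc": model.training_auc,
            "vocab": model.vocab,
            "svc": model.svc,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedPairModel:
    """Load a bundle written by :func:`save_model`; round trip preserves scores."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"{path}: not a readable model bundle ({exc})") from None
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path}: missing model-format header")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedPairModel(
        svc=payload["svc"],
        config=payload["config"],
        recipe=payload["recipe"],
        n_features=payload["n_features"],
        training_auc=payload["training_auc"],
        vocab=payload.get("vocab"),
    )
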
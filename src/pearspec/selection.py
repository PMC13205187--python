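"""Characteristic-wavelength selection and the RBF-SVM baseline.

Two selectors are provided: univariate one-way ANOVA F scores and random
forest impurity importances. The classifier is a one-vs-one RBF-SVM whose
pairwise binary machines are delegated to libsvm but whose majority vote and
bandwidth heuristic live in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

DEFAULT_K = 100
DEFAULT_C = 1.0


@dataclass(frozen=True)
class SelectionResult:
    """Top-K wavelength selection with the per-wavelength statistic."""

    method: Literal["US", "RF"]
    K: int
    selected_indices: np.ndarray
    scores: np.ndarray


def f_statistic_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way between-groups F statistic per wavelength.

    F = (between-class mean square) / (within-class mean square), computed
    column-wise over the class partition of the rows.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    groups = [X[y == c] for c in classes]
    for c, g in zip(classes, groups):
        if g.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    n = X.shape[0]
    k = classes.size
    grand = X.mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ms_within > 0, ms_between / np.where(ms_within > 0, ms_within, 1.0),
                     np.where(ms_between > 0, np.inf, 0.0))
    return f


def select_top_k(scores: np.ndarray, K: int = DEFAULT_K,
                 method: Literal["US", "RF"] = "US") -> SelectionResult:
    """Indices of the K largest scores; ties broken by lower index."""
    scores = np.asarray(scores, dtype=np.float64)
    if K > scores.size:
        raise ValueError("K exceeds the number of wavelengths")
    if K < 1:
        raise ValueError("K must be >= 1")
    order = np.argsort(-scores, kind="stable")
    return SelectionResult(method=method, K=K,
                           selected_indices=np.sort(order[:K]), scores=scores)


def rf_importance_scores(X: np.ndarray, y: np.ndarray, n_trees: int = 500,
                         seed: int = 0) -> np.ndarray:
    """Impurity-based random forest importances (non-negative, sum to 1)."""
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(np.asarray(X, dtype=np.float64), np.asarray(y))
    return forest.feature_importances_


def scale_gamma(X: np.ndarray) -> float:
    """The 'scale' bandwidth heuristic: γ = 1 / (n_features · Var(X))."""
    X = np.asarray(X, dtype=np.float64)
    var = X.var()
    if var <= 0:
        raise ValueError("features have zero variance; gamma undefined")
    return 1.0 / (X.shape[1] * var)


@dataclass(frozen=True)
class SvmModel:
    """One-vs-one RBF-SVM: one binary machine per class pair plus the vote."""

    classes: np.ndarray
    pair_models: dict[tuple[int, int], SVC]
    gamma: float
    C: float
    n_features: int


def train_svm(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C,
              bandwidth_mode: str = "variance-scaled", seed: int = 0) -> SvmModel:
    """Train the pairwise binary machines of an OvO RBF-SVM.

    γ follows the variance-scaled heuristic computed once on the full
    training matrix; probability estimates are enabled on each binary
    machine so confidence scores are available downstream.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train")
    if bandwidth_mode != "variance-scaled":
        raise ValueError(f"unknown bandwidth_mode {bandwidth_mode!r}")
    gamma = scale_gamma(X)
    pair_models: dict[tuple[int, int], SVC] = {}
    for a, b in combinations(range(classes.size), 2):
        sel = (y == classes[a]) | (y == classes[b])
        clf = SVC(kernel="rbf", C=C, gamma=gamma, probability=True, random_state=seed)
        with warnings.catch_warnings():
            # probability=True is the published protocol; silence the
            # scikit-learn >=1.9 deprecation nudge toward CalibratedClassifierCV
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X[sel], y[sel])
        pair_models[(a, b)] = clf
    return SvmModel(classes=classes, pair_models=pair_models, gamma=gamma, C=C,
                    n_features=X.shape[1])


def predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    """OvO majority vote over the pairwise machines.

    Each binary machine casts one vote per sample; the class with the most
    votes wins, ties broken in favor of the lower class label.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    if X.shape[0] == 0:
        return np.array([], dtype=model.classes.dtype)
    votes = np.zeros((X.shape[0], model.classes.size), dtype=np.int64)
    for (a, b), clf in model.pair_models.items():
        pred = clf.predict(X)
        votes[:, a] += pred == model.classes[a]
        votes[:, b] += pred == model.classes[b]
    return model.classes[np.argmax(votes, axis=1)]
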
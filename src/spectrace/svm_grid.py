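"""RBF-kernel SVM classification with exhaustive (c, g) grid search.

Penalty c and kernel width g are searched over power-of-2 grids by
7-fold cross-validated accuracy, the standard libSVM protocol for
chemometric classification. Any variable subset is accepted; an empty
subset raises the explicit "cannot build" condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .pls import _stratified_folds

__all__ = ["SVMSearchResult", "CannotBuildError", "default_c_grid", "default_g_grid", "grid_search_svm", "evaluate_svm"]


class CannotBuildError(ValueError):
    """The model cannot be built (e.g. zero input variables)."""


def default_c_grid(step: float = 1.0) -> np.ndarray:
    """Penalty grid 2^-5 .. 2^20."""
    return 2.0 ** np.arange(-5.0, 20.0 + 1e-9, step)


def default_g_grid(step: float = 1.0) -> np.ndarray:
    """Kernel-width grid 2^-15 .. 2^3."""
    return 2.0 ** np.arange(-15.0, 3.0 + 1e-9, step)


@dataclass
class SVMSearchResult:
    best_c: float
    best_g: float
    cv_surface: np.ndarray  # accuracy %, shape len(c_grid) x len(g_grid)
    c_grid: np.ndarray
    g_grid: np.ndarray
    classifier: SVC
    train_accuracy: float  # percent
    classes: np.ndarray


def grid_search_svm(
    X_train: np.ndarray,
    labels: np.ndarray,
    c_grid: np.ndarray | None = None,
    g_grid: np.ndarray | None = None,
    k_folds: int = 7,
    seed: int = 0,
) -> SVMSearchResult:
    """Exhaustive 7-fold-CV grid search; ties break to smallest c, then g.

    The winning (c, g) is refit on the full training set (one-vs-one
    multiclass, libSVM SMO solver). Features are used as-is: spectra
    share absorbance units, so no auto-scaling is applied.
    """
    X_train = np.asarray(X_train, dtype=float)
    labels = np.asarray(labels)
    if X_train.ndim != 2 or X_train.shape[1] == 0:
        raise CannotBuildError("cannot build an SVM on zero variables")
    c_grid = default_c_grid() if c_grid is None else np.sort(np.asarray(c_grid, float))
    g_grid = default_g_grid() if g_grid is None else np.sort(np.asarray(g_grid, float))
    if c_grid.size == 0 or g_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")

    n = X_train.shape[0]
    folds = _stratified_folds(labels, k_folds, seed)
    fold_cache = []
    for heldout in folds:
        mask = np.ones(n, dtype=bool)
        mask[heldout] = False
        if np.unique(labels[mask]).size < 2:
            raise ValueError("a CV fold's training part has a single class")
        fold_cache.append((mask, heldout))

    surface = np.zeros((c_grid.size, g_grid.size))
    for ic, c in enumerate(c_grid):
        for ig, g in enumerate(g_grid):
            correct = 0
            for mask, heldout in fold_cache:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(X_train[mask], labels[mask])
                correct += int(np.sum(clf.predict(X_train[heldout]) == labels[heldout]))
            surface[ic, ig] = 100.0 * correct / n

    best_flat = int(np.argmax(surface))  # row-major: smallest c, then g, wins ties
    ic, ig = divmod(best_flat, g_grid.size)
    best_c, best_g = float(c_grid[ic]), float(g_grid[ig])
    clf = SVC(C=best_c, gamma=best_g, kernel="rbf")
    clf.fit(X_train, labels)
    train_acc = 100.0 * float(np.mean(clf.predict(X_train) == labels))
    return SVMSearchResult(
        best_c=best_c,
        best_g=best_g,
        cv_surface=surface,
        c_grid=c_grid,
        g_grid=g_grid,
        classifier=clf,
        train_accuracy=train_acc,
        classes=np.unique(labels),
    )


def evaluate_svm(
    result: SVMSearchResult, X_test: np.ndarray, labels_test: np.ndarray
) -> tuple[float, np.ndarray]:
    """Test accuracy (%) and confusion matrix (rows: true, cols: predicted).

    Classes unseen in training get confusion rows of their own and count
    as errors.
    """
    X_test = np.asarray(X_test, dtype=float)
    labels_test = np.asarray(labels_test)
    pred = result.classifier.predict(X_test)
    classes = result.classes
    unseen = np.setdiff1d(np.unique(labels_test), classes)
    if unseen.size:
        warnings.warn(f"test set contains classes unseen in training: {unseen.tolist()}")
        classes = np.concatenate([classes, unseen])
    lookup = {c: k for k, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for true, hat in zip(labels_test, pred):
        cm[lookup[true], lookup[hat]] += 1
    accuracy = 100.0 * float(np.trace(cm)) / len(labels_test)
    return accuracy, cm
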
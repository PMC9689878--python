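"""NIPALS PLS2 discriminant analysis with the chemometric metric suite.

Class labels are one-hot encoded and regressed on the (mean-centered)
spectra by NIPALS partial least squares. The module provides the
standard model-quality metrics (R^2, Q^2, RMSEE, RMSECV, RMSEP, class
accuracies), latent-variable selection at the first maximum of the Q^2
curve, VIP variable-importance scores, and the label-permutation
overfitting test with R^2/Q^2 intercept criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSDAModel",
    "CVResult",
    "ModelMetrics",
    "PermutationVerdict",
    "fit_plsda",
    "predict",
    "cross_validate",
    "select_lv_by_q2",
    "vip_scores",
    "compute_metrics",
    "permutation_test",
    "one_hot",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class PLSDAModel:
    classes: np.ndarray  # class labels, sorted; column k of Y <-> classes[k]
    x_mean: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # X-weights, p x A, unit columns
    T: np.ndarray  # X-scores, n x A
    P: np.ndarray  # X-loadings, p x A
    C: np.ndarray  # Y-loadings, K x A

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def rotations(self) -> np.ndarray:
        """Weights rotated to apply to undeflated X: R = W (P^T W)^-1."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def coefficients(self) -> np.ndarray:
        """Accumulated regression coefficients B (p x K) such that
        Y_hat = (X - x_mean) B + y_mean."""
        return self.rotations @ self.C.T

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new spectra onto the latent-variable scores."""
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.rotations


@dataclass
class CVResult:
    q2: float
    rmsecv: float
    press: float
    n_samples: int
    n_classes: int


@dataclass
class ModelMetrics:
    r2: float
    q2: float
    rmsee: float
    rmsecv: float
    rmsep: float
    train_accuracy: float  # percent
    test_accuracy: float  # percent


@dataclass
class PermutationVerdict:
    n_permutations: int
    similarity: np.ndarray  # abscissa per permutation (original point last)
    r2: np.ndarray
    q2: np.ndarray
    r2_intercept: float
    q2_intercept: float
    overfitting: bool = field(init=False)

    def __post_init__(self) -> None:
        # Overfit-free: R2 intercept < 0.4 and Q2 intercept < 0.
        self.overfitting = not (self.r2_intercept < 0.4 and self.q2_intercept < 0.0)


def one_hot(labels: np.ndarray, classes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    if not np.all(Y.sum(axis=1) == 1):
        raise ValueError("labels contain classes outside the training set")
    return Y, classes


def _nipals(Xc: np.ndarray, Yc: np.ndarray, n_components: int):
    """Core NIPALS PLS2 loop on centered matrices."""
    X = Xc.copy()
    Y = Yc.copy()
    n, p = X.shape
    Ws, Ts, Ps, Cs = [], [], [], []
    for _ in range(n_components):
        # Start u from the Y column with the most remaining variance.
        col = int(np.argmax(np.sum(Y**2, axis=0)))
        u = Y[:, col]
        if np.linalg.norm(u) < 1e-14:
            break  # Y residual exhausted
        for _ in range(_NIPALS_MAX_ITER):
            w = X.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                break
            w /= wn
            t = X @ w
            tt = float(t @ t)
            if tt < 1e-28:
                break
            c = Y.T @ t / tt
            cc = float(c @ c)
            if cc < 1e-28:
                break
            u_new = Y @ c / cc
            if np.linalg.norm(u_new - u) < _NIPALS_TOL * max(np.linalg.norm(u_new), 1e-300):
                u = u_new
                break
            u = u_new
        w = X.T @ u
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-28:
            break
        c = Y.T @ t / tt
        pvec = X.T @ t / tt
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, c)
        Ws.append(w)
        Ts.append(t)
        Ps.append(pvec)
        Cs.append(c)
    if not Ws:
        raise ValueError("X has no usable variance (degenerate input)")
    return (np.column_stack(Ws), np.column_stack(Ts), np.column_stack(Ps), np.column_stack(Cs))


def fit_plsda(X: np.ndarray, labels: np.ndarray, n_components: int) -> PLSDAModel:
    X = np.asarray(X, dtype=float)
    Y, classes = one_hot(labels)
    n, p = X.shape
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components must be in [1, min(n-1, p)]")
    # relative check: second-derivative spectra live at ~1e-5 AU/(cm^-1)^2,
    # so an absolute-tolerance test would falsely flag them as constant
    if not np.any(np.ptp(X, axis=0) > 0):
        raise ValueError("X has zero variance in every column")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    W, T, P, C = _nipals(X - x_mean, Y - y_mean, n_components)
    return PLSDAModel(classes=classes, x_mean=x_mean, y_mean=y_mean, W=W, T=T, P=P, C=C)


def predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class labels and the continuous one-hot estimates.

    Decision rule: argmax over the class columns; ties resolve to the
    lowest class index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ValueError("X column count does not match the training data")
    yhat = (X - model.x_mean) @ model.coefficients + model.y_mean
    return model.classes[np.argmax(yhat, axis=1)], yhat


def _stratified_folds(labels: np.ndarray, k_folds: int, seed: int) -> list[np.ndarray]:
    """Deal each class's (shuffled) samples round-robin over k folds."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    start = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, sample in enumerate(idx):
            folds[(start + j) % k_folds].append(int(sample))
        start += idx.size
    return [np.sort(np.asarray(f, dtype=int)) for f in folds if len(f)]


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int,
    k_folds: int = 7,
    seed: int = 0,
) -> CVResult:
    """k-fold CV of the one-hot regression: Q^2 = 1 - PRESS/SSY."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if k_folds > n:
        raise ValueError("k_folds cannot exceed n")
    Y, classes = one_hot(labels)
    folds = _stratified_folds(labels, k_folds, seed)
    press = 0.0
    for heldout in folds:
        mask = np.ones(n, dtype=bool)
        mask[heldout] = False
        train_labels = labels[mask]
        if np.unique(train_labels).size < 2:
            raise ValueError("a CV fold's training part has a single class")
        A = min(n_components, int(mask.sum()) - 1, X.shape[1])
        sub = fit_plsda(X[mask], train_labels, A)
        Ysub, _ = one_hot(train_labels, classes=sub.classes)
        yhat = (X[heldout] - sub.x_mean) @ sub.coefficients + sub.y_mean
        # Align columns in case a class is absent from the training part.
        full = np.zeros((heldout.size, classes.size))
        col = {c: k for k, c in enumerate(classes)}
        for k_sub, c in enumerate(sub.classes):
            full[:, col[c]] = yhat[:, k_sub]
        press += float(np.sum((Y[heldout] - full) ** 2))
    ssy = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    q2 = 1.0 - press / ssy
    rmsecv = float(np.sqrt(press / (n * classes.size)))
    return CVResult(q2=q2, rmsecv=rmsecv, press=press, n_samples=n, n_classes=classes.size)


def select_lv_by_q2(
    X: np.ndarray,
    labels: np.ndarray,
    max_components: int,
    k_folds: int = 7,
    seed: int = 0,
    rule: str = "first_global_max",
) -> tuple[int, np.ndarray]:
    """Latent-variable count at the first maximum of the Q^2(A) curve.

    'first_global_max' (default) returns the smallest A attaining the
    curve's overall maximum; 'first_local_max' stops at the first A
    whose successor does not improve on it.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    q2_curve = np.array(
        [cross_validate(X, labels, A, k_folds=k_folds, seed=seed).q2 for A in range(1, max_components + 1)]
    )
    if rule == "first_global_max":
        chosen = int(np.argmax(q2_curve)) + 1
    elif rule == "first_local_max":
        chosen = len(q2_curve)
        for a in range(len(q2_curve)):
            if a + 1 >= len(q2_curve) or q2_curve[a + 1] <= q2_curve[a]:
                chosen = a + 1
                break
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return chosen, q2_curve


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ), with
    SSY_a = ||t_a||^2 ||c_a||^2 the Y-variance captured by component a
    and w_a the unit-norm X-weights. mean(VIP^2) = 1 by construction.
    """
    p = model.W.shape[0]
    ssy = np.sum(model.T**2, axis=0) * np.sum(model.C**2, axis=0)
    total = float(ssy.sum())
    if total <= 0.0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wnorm2 = model.W**2 / np.sum(model.W**2, axis=0)
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def _r2_rmsee(model: PLSDAModel, X: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    Y, _ = one_hot(labels, classes=model.classes)
    _, yhat = predict(model, X)
    resid = Y - yhat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmsee = float(np.sqrt(ss_res / resid.size))
    return r2, rmsee


def compute_metrics(
    model: PLSDAModel,
    X_train: np.ndarray,
    labels_train: np.ndarray,
    X_test: np.ndarray,
    labels_test: np.ndarray,
    cv: CVResult | None = None,
) -> ModelMetrics:
    if len(labels_test) == 0:
        raise ValueError("test set is empty")
    r2, rmsee = _r2_rmsee(model, X_train, labels_train)
    Y_test, _ = one_hot(labels_test, classes=model.classes)
    pred_test, yhat_test = predict(model, X_test)
    rmsep = float(np.sqrt(np.mean((Y_test - yhat_test) ** 2)))
    pred_train, _ = predict(model, X_train)
    train_acc = 100.0 * float(np.mean(pred_train == np.asarray(labels_train)))
    test_acc = 100.0 * float(np.mean(pred_test == np.asarray(labels_test)))
    return ModelMetrics(
        r2=r2,
        q2=cv.q2 if cv is not None else float("nan"),
        rmsee=rmsee,
        rmsecv=cv.rmsecv if cv is not None else float("nan"),
        rmsep=rmsep,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
    )


def permutation_test(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int,
    n_permutations: int = 200,
    k_folds: int = 7,
    seed: int = 0,
) -> PermutationVerdict:
    """Label-permutation overfitting check.

    Labels are permuted uniformly; the model is refit and cross-validated
    at the same component count for each permutation. R^2 and Q^2 are
    regressed on the similarity between permuted and original labels
    (fraction of labels left in place; the unpermuted model sits at 1),
    and the regression intercepts at similarity 0 are reported. The
    conventional no-overfitting call is R^2-intercept < 0.4 and
    Q^2-intercept < 0.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def _fit_eval(lab: np.ndarray) -> tuple[float, float]:
        model = fit_plsda(X, lab, n_components)
        r2, _ = _r2_rmsee(model, X, lab)
        q2 = cross_validate(X, lab, n_components, k_folds=k_folds, seed=seed).q2
        return r2, q2

    sims, r2s, q2s = [], [], []
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        permuted = labels[perm]
        r2, q2 = _fit_eval(permuted)
        sims.append(float(np.mean(permuted == labels)))
        r2s.append(r2)
        q2s.append(q2)
    r2_orig, q2_orig = _fit_eval(labels)
    sims.append(1.0)
    r2s.append(r2_orig)
    q2s.append(q2_orig)

    sims_arr = np.asarray(sims)
    design = np.column_stack([np.ones_like(sims_arr), sims_arr])
    r2_fit, *_ = np.linalg.lstsq(design, np.asarray(r2s), rcond=None)
    q2_fit, *_ = np.linalg.lstsq(design, np.asarray(q2s), rcond=None)
    return PermutationVerdict(
        n_permutations=n_permutations,
        similarity=sims_arr,
        r2=np.asarray(r2s),
        q2=np.asarray(q2s),
        r2_intercept=float(r2_fit[0]),
        q2_intercept=float(q2_fit[0]),
    )
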
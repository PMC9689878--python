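"""Wavelength selection: VIP thresholding, SPA, and CARS.

Three complementary strategies for picking informative wavenumbers out
of a highly collinear NIR matrix:

* VIP keeps variables whose importance-in-projection exceeds 1.
* SPA (successive projections algorithm) grows chains of minimally
  collinear variables by repeated orthogonal projection and keeps the
  chain/length with the lowest validation RMSE.
* CARS (competitive adaptive reweighted sampling) runs Monte-Carlo
  PLS fits while an exponentially decreasing function (EDF) shrinks the
  retained-variable count, keeping the run with the lowest RMSECV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import cross_validate, fit_plsda, one_hot, predict, select_lv_by_q2
from .sampling import kennard_stone

__all__ = [
    "SelectionResult",
    "EmptySelectionError",
    "ChainExhaustedError",
    "select_vip",
    "spa_chain",
    "spa",
    "edf_ratio",
    "cars",
    "compare_selections",
]


class EmptySelectionError(ValueError):
    """No variable survived selection; downstream models need >= 1."""


class ChainExhaustedError(ValueError):
    """SPA ran out of linearly independent columns before the target length."""


@dataclass
class SelectionResult:
    method: str
    indices: np.ndarray  # sorted unique column indices into the grid
    curve: dict  # diagnostic curve: x -> RMSE/RMSECV (or scores for VIP)
    settings: dict = field(default_factory=dict)
    score: float | None = None  # the winning RMSE/RMSECV where applicable
    grid_points: int | None = None

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)


def select_vip(
    vip: np.ndarray, threshold: float = 1.0, grid_points: int | None = None
) -> SelectionResult:
    """Keep variables with VIP strictly greater than the threshold."""
    vip = np.asarray(vip, dtype=float)
    if not np.all(np.isfinite(vip)):
        raise ValueError("VIP scores must be finite")
    idx = np.flatnonzero(vip > threshold)
    if idx.size == 0:
        raise EmptySelectionError("no variable exceeds the VIP threshold")
    return SelectionResult(
        method="vip",
        indices=idx,
        curve={"vip": vip},
        settings={"threshold": threshold},
        grid_points=grid_points if grid_points is not None else vip.size,
    )


def spa_chain(X: np.ndarray, start_var: int, chain_len: int) -> np.ndarray:
    """Successive-projections chain of column indices.

    Starting from `start_var`, each step projects the remaining columns
    onto the orthogonal complement of the span of the chosen columns and
    picks the one with the largest residual norm (lowest index on ties).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_var < p:
        raise ValueError("start_var out of range")
    if not 1 <= chain_len <= min(n, p):
        raise ValueError("chain_len must be in [1, min(n, p)]")
    R = X.copy()
    chain = [start_var]
    chosen = np.zeros(p, dtype=bool)
    chosen[start_var] = True
    while len(chain) < chain_len:
        last = R[:, chain[-1]].copy()
        nrm2 = float(last @ last)
        if nrm2 < 1e-24:
            raise ChainExhaustedError("projected norms vanished before chain_len")
        R -= np.outer(last, (last @ R) / nrm2)
        norms = np.einsum("ij,ij->j", R, R)
        norms[chosen] = -np.inf
        pick = int(np.argmax(norms))
        if norms[pick] < 1e-24:
            raise ChainExhaustedError("projected norms vanished before chain_len")
        chain.append(pick)
        chosen[pick] = True
    return np.asarray(chain, dtype=int)


def _eval_rmse(
    X_cal: np.ndarray,
    labels_cal: np.ndarray,
    X_val: np.ndarray,
    labels_val: np.ndarray,
    cols: np.ndarray,
    n_components: int,
) -> float:
    A = min(n_components, cols.size, X_cal.shape[0] - 1)
    model = fit_plsda(X_cal[:, cols], labels_cal, A)
    Y_val, _ = one_hot(labels_val, classes=model.classes)
    _, yhat = predict(model, X_val[:, cols])
    return float(np.sqrt(np.mean((Y_val - yhat) ** 2)))


def spa(
    X: np.ndarray,
    labels: np.ndarray,
    max_vars: int,
    inner_split: float = 0.7,
    n_components: int | None = None,
    max_components: int = 10,
    k_folds: int = 7,
    seed: int = 0,
    starts: np.ndarray | None = None,
) -> SelectionResult:
    """SPA wavelength selection scored by validation RMSE.

    Every start variable seeds a projection chain; every prefix of every
    chain is fit as a PLS-DA model on an internal Kennard-Stone
    calibration/validation split and scored by validation RMSE on the
    one-hot targets. The minimum-RMSE (start, length) wins; ties go to
    the smaller subset then the earlier start.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1")
    n_cal = int(np.floor(n * inner_split + 0.5))
    n_cal = max(2, min(n - 1, n_cal))
    cal = kennard_stone(X, n_cal)
    val = np.setdiff1d(np.arange(n), cal)
    X_cal, X_val = X[cal], X[val]
    lab_cal, lab_val = labels[cal], labels[val]
    if np.unique(lab_cal).size < 2 or np.unique(lab_val).size < 1:
        raise ValueError("inner split degenerate for classification")

    if n_components is None:
        max_a = min(max_components, n_cal - 1, p)
        n_components, _ = select_lv_by_q2(X_cal, lab_cal, max_a, k_folds=k_folds, seed=seed)

    max_len = min(max_vars, n_cal - 1, p)
    if starts is None:
        starts = np.arange(p)
    best = None  # (rmse, size, start, subset)
    best_by_size: dict[int, float] = {}
    for start in np.asarray(starts, dtype=int):
        try:
            chain = spa_chain(X_cal, int(start), max_len)
        except ChainExhaustedError:
            continue
        for k in range(1, chain.size + 1):
            cols = np.sort(chain[:k])
            try:
                rmse = _eval_rmse(X_cal, lab_cal, X_val, lab_val, cols, n_components)
            except ValueError as exc:
                raise ValueError(f"evaluation failed for start={start}, size={k}") from exc
            if k not in best_by_size or rmse < best_by_size[k]:
                best_by_size[k] = rmse
            key = (rmse, k, int(start))
            if best is None or key < (best[0], best[1], best[2]):
                best = (rmse, k, int(start), cols)
    if best is None:
        raise ChainExhaustedError("no SPA chain could be built")
    rmse, size, start, cols = best
    return SelectionResult(
        method="spa",
        indices=cols,
        curve={"subset_size": sorted(best_by_size), "rmse": [best_by_size[k] for k in sorted(best_by_size)]},
        settings={
            "max_vars": max_vars,
            "inner_split": inner_split,
            "n_components": n_components,
            "start": start,
        },
        score=rmse,
        grid_points=p,
    )


def edf_ratio(run_i: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing retained-variable fraction.

    r_i = a e^{-k i} with a, k set so r_1 = 1 and r_N = 2/p.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 1 <= run_i <= n_runs:
        raise ValueError("run_i out of range")
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(np.exp(-k * (run_i - 1)))


def cars(
    X: np.ndarray,
    labels: np.ndarray,
    n_runs: int = 50,
    mc_fraction: float = 0.8,
    n_components: int | None = None,
    max_components: int = 10,
    k_folds: int = 7,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per run: a Monte-Carlo subset of calibration samples fits a PLS-DA
    model on the surviving variables; variables are re-drawn (weighted
    by normalized |coefficient|, without replacement) down to the EDF
    count; the surviving set's 7-fold RMSECV is recorded. The run with
    the lowest RMSECV provides the final selection.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    if p < 2:
        raise ValueError("CARS needs at least 2 variables")
    rng = np.random.default_rng(seed)

    if n_components is None:
        max_a = min(max_components, n - 1, p)
        n_components, _ = select_lv_by_q2(X, labels, max_a, k_folds=k_folds, seed=seed)

    pool = np.arange(p)
    pools, rmsecvs = [], []
    n_mc = max(2, int(np.floor(n * mc_fraction + 0.5)))
    for i in range(1, n_runs + 1):
        if pool.size < 2:
            warnings.warn("CARS pool collapsed below 2 variables; truncating runs")
            break
        # Monte-Carlo calibration subset (must keep >= 2 classes).
        for _ in range(50):
            mc = rng.choice(n, size=n_mc, replace=False)
            if np.unique(labels[mc]).size >= 2:
                break
        A = min(n_components, pool.size, n_mc - 1)
        model = fit_plsda(X[mc][:, pool], labels[mc], A)
        weights = np.sum(np.abs(model.coefficients), axis=1)
        weights = np.maximum(weights, 1e-300)
        weights = weights / weights.sum()

        target = int(np.ceil(edf_ratio(i, n_runs, p) * p))
        target = max(2, min(target, pool.size))
        # Adaptive reweighted sampling: weighted draw without replacement.
        keep = rng.choice(pool.size, size=target, replace=False, p=weights)
        pool = np.sort(pool[keep])

        A_cv = min(n_components, pool.size)
        cv = cross_validate(X[:, pool], labels, A_cv, k_folds=k_folds, seed=seed)
        pools.append(pool.copy())
        rmsecvs.append(cv.rmsecv)

    if not rmsecvs:
        raise EmptySelectionError("CARS recorded no runs")
    best = int(np.argmin(rmsecvs))
    return SelectionResult(
        method="cars",
        indices=pools[best],
        curve={
            "run": list(range(1, len(rmsecvs) + 1)),
            "rmsecv": rmsecvs,
            "n_retained": [int(q.size) for q in pools],
        },
        settings={
            "n_runs": n_runs,
            "mc_fraction": mc_fraction,
            "n_components": n_components,
            "seed": seed,
        },
        score=float(rmsecvs[best]),
        grid_points=p,
    )


def compare_selections(results: list[SelectionResult]) -> dict:
    """Pairwise and common-to-all overlap counts of selected-index sets."""
    if len(results) < 2:
        raise ValueError("need at least 2 selections to compare")
    grids = {r.grid_points for r in results}
    if len(grids) != 1:
        raise ValueError("selections come from different grids")
    sets = {r.method: set(r.indices.tolist()) for r in results}
    methods = [r.method for r in results]
    pairwise = {}
    for a in range(len(methods)):
        for b in range(a + 1, len(methods)):
            ma, mb = methods[a], methods[b]
            pairwise[f"{ma}&{mb}"] = len(sets[ma] & sets[mb])
    common = set.intersection(*sets.values())
    union = set.union(*sets.values())
    return {
        "sizes": {m: len(s) for m, s in sets.items()},
        "pairwise": pairwise,
        "common_to_all": sorted(common),
        "n_common": len(common),
        "n_union": len(union),
    }
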
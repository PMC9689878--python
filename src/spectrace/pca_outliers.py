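"""PCA score-space outlier gating with Hotelling's T^2.

The raw spectra are mean-centered and decomposed by SVD; each sample's
Hotelling T^2 over the first A score dimensions is compared against the
F-distribution control limit at the chosen confidence level (95% by
default, A = 2, matching score-plot practice). Samples past the limit
are removed before any modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .dataset import SpectralDataset

__all__ = ["PCAModel", "OutlierVerdict", "fit_pca", "hotelling_t2", "remove_outliers", "gate_outliers"]


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # p x A, orthonormal columns
    scores: np.ndarray  # n x A
    explained_variance: np.ndarray  # per retained component
    explained_variance_ratio: np.ndarray
    n_samples: int


@dataclass
class OutlierVerdict:
    t2: np.ndarray
    limit: float
    flags: np.ndarray
    alpha: float


def fit_pca(dataset: SpectralDataset | np.ndarray, n_components: int) -> PCAModel:
    X = dataset.absorbance if isinstance(dataset, SpectralDataset) else np.asarray(dataset, float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("n_components must be in [1, min(n-1, p)]")
    mean = X.mean(axis=0)
    Xc = X - mean
    # Economy SVD; scores = U * s.
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    A = n_components
    return PCAModel(
        mean=mean,
        loadings=Vt[:A].T.copy(),
        scores=(U[:, :A] * s[:A]).copy(),
        explained_variance=var[:A].copy(),
        explained_variance_ratio=(var[:A] / total).copy(),
        n_samples=n,
    )


def hotelling_t2(model: PCAModel, alpha: float = 0.05) -> OutlierVerdict:
    """T^2_i = sum_a score_ia^2 / var_a against the limit
    A(n-1)/(n-A) * F_{1-alpha}(A, n-A)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = model.n_samples
    A = model.scores.shape[1]
    if n <= A:
        raise ValueError("need more samples than components")
    t2 = np.sum(model.scores**2 / model.explained_variance, axis=1)
    limit = A * (n - 1) / (n - A) * f_dist.ppf(1.0 - alpha, A, n - A)
    return OutlierVerdict(t2=t2, limit=float(limit), flags=t2 > limit, alpha=alpha)


def remove_outliers(dataset: SpectralDataset, verdict: OutlierVerdict) -> SpectralDataset:
    if len(verdict.flags) != dataset.n_samples:
        raise ValueError("verdict does not align with dataset")
    keep = np.flatnonzero(~verdict.flags)
    if keep.size == 0:
        raise ValueError("all samples flagged; refusing to return an empty dataset")
    removed_ids = dataset.sample_ids[verdict.flags].tolist()
    out = dataset.subset(keep)
    out.meta["removed_outlier_ids"] = removed_ids
    return out


def gate_outliers(
    dataset: SpectralDataset, n_components: int = 2, alpha: float = 0.05
) -> tuple[SpectralDataset, OutlierVerdict, PCAModel]:
    """Convenience wrapper: fit PCA, score T^2, drop flagged rows."""
    model = fit_pca(dataset, n_components)
    verdict = hotelling_t2(model, alpha)
    return remove_outliers(dataset, verdict), verdict, model
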
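"""Generalized two-dimensional correlation spectroscopy (synchronous).

Following Noda's discrete formulation, the dynamic spectra of a class
are the deviations of its member spectra from the class mean; the
synchronous map is their covariance-like cross product
Phi(v1, v2) = S(v1)^T S(v2) / (m - 1). Per-sample maps take the single
deviation vector of one sample (a rank-1 outer product with the same
1/(m-1) scaling), so that the per-sample maps of a class sum to the
class map. Spectra are block-average binned to a 64-point grid first so
each map renders directly as a 64 x 64 image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import SpectralDataset, WavenumberGrid

__all__ = [
    "DynamicSpectra",
    "SynchronousMap",
    "dynamic_spectra",
    "synchronous_map",
    "bin_to_grid",
    "sample_sync_image",
    "class_sync_image",
    "render_map",
]


@dataclass
class DynamicSpectra:
    S: np.ndarray  # m x p deviations from the class mean
    class_id: object
    perturbation: str = "deviation-from-class-mean"

    @property
    def m(self) -> int:
        return int(self.S.shape[0])


@dataclass
class SynchronousMap:
    phi: np.ndarray  # p x p, symmetric PSD
    grid: WavenumberGrid
    class_id: object = None
    sample_id: object = None


def dynamic_spectra(dataset: SpectralDataset, class_id) -> DynamicSpectra:
    """Deviations of one class's spectra from that class's mean."""
    idx = dataset.class_indices(class_id)
    if idx.size < 2:
        raise ValueError(f"class {class_id!r} needs >= 2 samples for a perturbation series")
    block = dataset.absorbance[idx]
    return DynamicSpectra(S=block - block.mean(axis=0), class_id=class_id)


def synchronous_map(dyn: DynamicSpectra, grid: WavenumberGrid | None = None) -> SynchronousMap:
    """Phi = S^T S / (m - 1)."""
    if dyn.m < 2:
        raise ValueError("synchronous map undefined for m < 2")
    phi = dyn.S.T @ dyn.S / (dyn.m - 1)
    phi = 0.5 * (phi + phi.T)  # enforce exact symmetry against roundoff
    if grid is None:
        # placeholder index grid when none is supplied
        grid = WavenumberGrid(np.arange(phi.shape[0], dtype=float)[::-1] + 1.0)
    return SynchronousMap(phi=phi, grid=grid, class_id=dyn.class_id)


def _bin_slices(n_points: int, n_bins: int) -> list[slice]:
    """Contiguous balanced partition; bin sizes differ by at most 1."""
    base, extra = divmod(n_points, n_bins)
    slices, start = [], 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        slices.append(slice(start, start + size))
        start += size
    return slices


def bin_to_grid(dataset: SpectralDataset, n_bins: int = 64) -> SpectralDataset:
    """Block-average the spectra onto an n_bins-point grid.

    Bins are contiguous wavenumber blocks of near-equal size (the 1557
    points of the instrument grid split into 64 bins of 24 or 25
    points); the bin wavenumber is the block mean.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > dataset.n_points:
        raise ValueError("n_bins cannot exceed the number of grid points")
    if n_bins == dataset.n_points:
        return dataset
    slices = _bin_slices(dataset.n_points, n_bins)
    v = dataset.grid.values
    binned_v = np.array([v[s].mean() for s in slices])
    # bins differ by at most one point, so the binned axis is uniform
    # only to ~1/bin_size relative; declare that tolerance explicitly
    rtol = 1.5 / max(dataset.n_points // n_bins, 1)
    binned_x = np.column_stack([dataset.absorbance[:, s].mean(axis=1) for s in slices])
    out = SpectralDataset(
        grid=WavenumberGrid(binned_v, spacing_rtol=rtol),
        absorbance=binned_x,
        labels=dataset.labels.copy(),
        sample_ids=dataset.sample_ids.copy(),
        meta=dict(dataset.meta),
    )
    out.meta["binned_from"] = dataset.n_points
    return out


def sample_sync_image(
    dataset: SpectralDataset, sample_index: int, n_bins: int = 64
) -> SynchronousMap:
    """Per-sample synchronous map: the rank-1 outer product of the
    sample's binned deviation from its class mean, scaled by 1/(m-1).

    One map per sample; the maps of a class sum to the class-level map.
    """
    if not 0 <= sample_index < dataset.n_samples:
        raise ValueError("sample_index out of range")
    binned = bin_to_grid(dataset, n_bins)
    label = binned.labels[sample_index]
    idx = binned.class_indices(label)
    if idx.size < 2:
        raise ValueError(f"class {label!r} needs >= 2 samples")
    d = binned.absorbance[sample_index] - binned.absorbance[idx].mean(axis=0)
    phi = np.outer(d, d) / (idx.size - 1)
    return SynchronousMap(
        phi=phi, grid=binned.grid, class_id=label, sample_id=binned.sample_ids[sample_index]
    )


def class_sync_image(dataset: SpectralDataset, class_id, n_bins: int = 64) -> SynchronousMap:
    """Class-level synchronous map on the binned grid."""
    binned = bin_to_grid(dataset, n_bins)
    return synchronous_map(dynamic_spectra(binned, class_id), grid=binned.grid)


def map_to_rgb(sync: SynchronousMap) -> np.ndarray:
    """Min-max normalize Phi and push it through a fixed perceptually
    uniform colormap; all-zero maps render flat at mid-scale."""
    import matplotlib

    phi = sync.phi
    if not np.all(np.isfinite(phi)):
        raise ValueError("map contains non-finite values")
    lo, hi = float(phi.min()), float(phi.max())
    if hi - lo < 1e-300:
        import warnings

        warnings.warn("all-constant map; rendering flat mid-scale image")
        norm = np.full_like(phi, 0.5)
    else:
        norm = (phi - lo) / (hi - lo)
    cmap = matplotlib.colormaps["viridis"]
    return (cmap(norm)[..., :3] * 255.0 + 0.5).astype(np.uint8)


def render_map(sync: SynchronousMap, path: str | Path) -> Path:
    """Write the map as an 8-bit RGB PNG, one pixel per grid bin."""
    from PIL import Image

    rgb = map_to_rgb(sync)
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path
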
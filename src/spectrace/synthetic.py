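"""Synthetic FT-NIR dataset generator with known ground truth.

Emulates the structure of a multi-origin herbal FT-NIR study: ~200 powder
spectra from 10 geographic classes on a 10,000-4000 cm^-1 grid (1557
points), with absorbance peaks at the overtone/combination bands typical
of polysaccharide-rich plant material, per-class intensity effects at
those bands, per-sample multiplicative/additive scatter, additive noise,
and a few gross outliers. Because every effect is planted, downstream
stages (scatter correction, outlier gating, wavelength selection,
classifiers) can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import SpectralDataset, WavenumberGrid, make_wavenumber_grid

__all__ = ["SyntheticConfig", "generate_dataset", "plant_outliers"]

# Overtone/combination band positions (cm^-1) typical of NIR spectra of
# dried plant powders: C-H combination (~4280), O-H/C-O combination
# (~4400, glucose), C-O/O-H (~4750), O-H + C-O overtone (~5170, water and
# polysaccharides), C-H first overtone (~5800), O-H first overtone
# (~6800), C-H second overtone (~8300).
DEFAULT_BAND_CENTERS = (4280.0, 4400.0, 4750.0, 5170.0, 5800.0, 6800.0, 8300.0)
DEFAULT_BAND_WIDTHS = (60.0, 70.0, 90.0, 120.0, 160.0, 180.0, 110.0)
DEFAULT_BAND_AMPLITUDES = (0.45, 0.55, 0.40, 0.90, 0.35, 0.60, 0.25)

# Class sizes mirroring a 15-site / 10-region collection totalling 207.
DEFAULT_CLASS_SIZES = (14, 20, 32, 32, 9, 12, 14, 21, 40, 13)


@dataclass
class SyntheticConfig:
    n_classes: int = 10
    class_sizes: Sequence[int] | None = DEFAULT_CLASS_SIZES
    samples_per_class: int = 21
    grid_start: float = 10_000.0
    grid_end: float = 4_000.0
    n_points: int = 1557
    band_centers: Sequence[float] = DEFAULT_BAND_CENTERS
    band_widths: Sequence[float] = DEFAULT_BAND_WIDTHS
    band_amplitudes: Sequence[float] = DEFAULT_BAND_AMPLITUDES
    # Bands (indices into band_centers) carrying class effects: the five
    # strong overtone/combination bands at 4400, 4750, 5170, 6800 and
    # 8300 cm^-1; the remaining peaks are class-constant background.
    class_effect_bands: Sequence[int] = (1, 2, 3, 5, 6)
    # Per-(class, band) amplitude multipliers 1 +/- U(lo, hi); (0, 0)
    # switches class structure off entirely.
    class_effect_range: tuple[float, float] = (0.12, 0.30)
    # One minor class-unique band per class (width/amplitude below).
    unique_band_amplitude: float = 0.06
    unique_band_width: float = 45.0
    # Within-class compositional variability: each sample sits at
    # 1 + s_i (s_i ~ Normal(0, sd)) along its class's band-effect
    # signature, emulating an environmental/compositional gradient
    # within a collection region. This class-specific covariance
    # structure is what the dynamic spectra of 2DCOS respond to.
    within_class_profile_sd: float = 0.5
    # Fraction of the class marker band riding the compositional
    # gradient (the rest is a stable class identifier).
    marker_profile_fraction: float = 0.5
    # Scatter model the MSC step is built to undo: x -> a + b * x.
    scatter_slope_sigma: float = 0.1  # b ~ LogNormal(0, sigma)
    scatter_offset_sigma: float = 0.02  # a ~ Normal(0, sigma) AU
    noise_sd: float = 0.003  # AU
    n_outliers: int = 5
    outlier_magnitude: float = 0.5
    seed: int = 0

    def resolved_class_sizes(self) -> list[int]:
        if self.class_sizes is not None:
            sizes = [int(s) for s in self.class_sizes]
            if len(sizes) != self.n_classes:
                raise ValueError("class_sizes length must equal n_classes")
        else:
            sizes = [int(self.samples_per_class)] * self.n_classes
        if any(s <= 0 for s in sizes):
            raise ValueError("class sizes must be positive")
        return sizes

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.within_class_profile_sd < 0:
            raise ValueError("within_class_profile_sd must be >= 0")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_amplitudes)):
            raise ValueError("band centers/widths/amplitudes must align")
        lo, hi = self.class_effect_range
        if lo < 0 or hi < lo:
            raise ValueError("class_effect_range must satisfy 0 <= lo <= hi")
        self.resolved_class_sizes()


def _gaussian(v: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((v - center) / width) ** 2)


def _class_clean_spectra(cfg: SyntheticConfig, grid: WavenumberGrid, rng: np.random.Generator):
    """Noise-free mean spectrum per class plus band bookkeeping."""
    v = grid.values
    centers = np.asarray(cfg.band_centers, float)
    widths = np.asarray(cfg.band_widths, float)
    amps = np.asarray(cfg.band_amplitudes, float)
    lo, hi = cfg.class_effect_range

    # Shared baseline: gentle scattering slope, identical for all classes.
    baseline = 0.15 + 1.5e-5 * (v - v.min())

    effect_bands = sorted(int(k) for k in cfg.class_effect_bands)
    if effect_bands and not (0 <= effect_bands[0] and effect_bands[-1] < centers.size):
        raise ValueError("class_effect_bands index out of range")

    # Per-(class, band) multipliers: random sign, magnitude U(lo, hi),
    # applied only at the class-effect bands.
    magnitudes = rng.uniform(lo, hi, size=(cfg.n_classes, centers.size))
    signs = rng.choice([-1.0, 1.0], size=(cfg.n_classes, centers.size))
    multipliers = np.ones((cfg.n_classes, centers.size))
    for k in effect_bands:
        multipliers[:, k] = 1.0 + signs[:, k] * magnitudes[:, k]

    # Class-unique minor bands spread over a quiet region of the grid.
    unique_centers = np.linspace(6050.0, 7750.0, cfg.n_classes)
    rng.shuffle(unique_centers)

    clean = np.empty((cfg.n_classes, v.size))
    # Each class's band-effect signature: the deviation of its mean from
    # the class-neutral base, Sum_k amp_k (m_ck - 1) G_k. Samples vary
    # along this direction (compositional gradient within a region).
    effect_profiles = np.zeros((cfg.n_classes, v.size))
    for c in range(cfg.n_classes):
        spectrum = baseline.copy()
        for k in range(centers.size):
            band = amps[k] * _gaussian(v, centers[k], widths[k])
            spectrum += multipliers[c, k] * band
            effect_profiles[c] += (multipliers[c, k] - 1.0) * band
        if cfg.unique_band_amplitude > 0:
            marker = cfg.unique_band_amplitude * _gaussian(
                v, unique_centers[c], cfg.unique_band_width
            )
            spectrum += marker
            # part of the class marker compound varies along the same
            # compositional gradient as the main band effects
            effect_profiles[c] += cfg.marker_profile_fraction * marker
        clean[c] = spectrum

    # Ground-truth "informative" indices: the core windows (+/- 0.4
    # sigma, where the Gaussian holds >= 92% of its peak amplitude) of
    # the class-effect bands, where between-class amplitude variance is
    # strong. The weak class-unique minor bands are reported separately
    # and are not part of the guaranteed-recovery core.
    informative = np.zeros(v.size, dtype=bool)
    band_windows: list[tuple[float, float]] = []
    if hi > 0:
        for k in effect_bands:
            half = 0.4 * widths[k]
            informative |= np.abs(v - centers[k]) <= half
            band_windows.append((centers[k] - half, centers[k] + half))
    unique_windows = [
        (uc - cfg.unique_band_width, uc + cfg.unique_band_width) for uc in unique_centers
    ] if cfg.unique_band_amplitude > 0 else []
    return clean, effect_profiles, informative, band_windows, unique_windows, unique_centers


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectralDataset, dict]:
    """Generate a dataset plus a ground-truth record.

    The truth record holds the informative variable indices (grid points
    inside class-varying bands), planted outlier row indices, the
    per-sample scatter coefficients (a, b), and the noise-free class
    mean spectra. Bit-exact under a fixed config seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = make_wavenumber_grid(cfg.grid_start, cfg.grid_end, cfg.n_points)
    sizes = cfg.resolved_class_sizes()
    n = sum(sizes)
    if cfg.n_outliers > n:
        raise ValueError("more outliers than samples")

    (clean, effect_profiles, informative, band_windows, unique_windows,
     unique_centers) = _class_clean_spectra(cfg, grid, rng)

    labels, rows, offsets, slopes, comp_factors, ids = [], [], [], [], [], []
    for c, size in enumerate(sizes):
        label = f"C{c + 1:02d}"
        for j in range(size):
            b = float(rng.lognormal(0.0, cfg.scatter_slope_sigma)) if cfg.scatter_slope_sigma > 0 else 1.0
            a = float(rng.normal(0.0, cfg.scatter_offset_sigma)) if cfg.scatter_offset_sigma > 0 else 0.0
            s = float(rng.normal(0.0, cfg.within_class_profile_sd)) if cfg.within_class_profile_sd > 0 else 0.0
            noise = rng.normal(0.0, cfg.noise_sd, grid.n_points) if cfg.noise_sd > 0 else 0.0
            sample_clean = clean[c] + s * effect_profiles[c]
            rows.append(a + b * sample_clean + noise)
            offsets.append(a)
            slopes.append(b)
            comp_factors.append(s)
            labels.append(label)
            ids.append(f"{label}-{j + 1:02d}")

    dataset = SpectralDataset(
        grid=grid,
        absorbance=np.asarray(rows),
        labels=np.asarray(labels),
        sample_ids=np.asarray(ids, dtype=object),
        meta={"source": "synthetic", "seed": cfg.seed},
    )

    outlier_indices = np.sort(rng.choice(n, size=cfg.n_outliers, replace=False)) if cfg.n_outliers else np.array([], dtype=int)
    if cfg.n_outliers:
        dataset = plant_outliers(dataset, outlier_indices, cfg.outlier_magnitude)

    truth = {
        "informative_indices": np.flatnonzero(informative),
        "informative_mask": informative,
        "band_windows": band_windows,
        "unique_band_windows": unique_windows,
        "unique_band_centers": unique_centers,
        "outlier_indices": outlier_indices,
        "scatter_offsets": np.asarray(offsets),
        "scatter_slopes": np.asarray(slopes),
        "compositional_factors": np.asarray(comp_factors),
        "class_clean_spectra": clean,
        "class_effect_profiles": effect_profiles,
        "class_order": [f"C{c + 1:02d}" for c in range(cfg.n_classes)],
    }
    return dataset, truth


def plant_outliers(
    dataset: SpectralDataset, indices: Sequence[int], magnitude: float
) -> SpectralDataset:
    """Distort the listed rows by a broad affine corruption.

    Each flagged row x becomes (1 + magnitude) * x + magnitude, a gross
    multiplicative-plus-offset excursion of the kind a failed scan or a
    mis-packed sample cup produces. magnitude 0 is the identity.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= dataset.n_samples):
        raise ValueError("outlier index out of range")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicate outlier index")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    absorbance = dataset.absorbance.copy()
    absorbance[idx] = (1.0 + magnitude) * absorbance[idx] + magnitude
    return dataset.with_absorbance(absorbance)
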
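"""Scatter correction and derivative preprocessing.

MSC (multiplicative scatter correction) regresses each spectrum on a
reference spectrum and removes the fitted offset and slope; SD is the
Savitzky-Golay second derivative, which suppresses baselines and
sharpens overlapping NIR bands. The study chain is MSC followed by SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset

__all__ = ["MSCResult", "SavGolConfig", "msc", "savgol_second_derivative", "preprocess_pipeline"]


class DegenerateReferenceError(ValueError):
    """Reference spectrum has zero variance; MSC slope is undefined."""


@dataclass
class MSCResult:
    corrected: SpectralDataset
    reference: np.ndarray
    offsets: np.ndarray  # a_i
    slopes: np.ndarray  # b_i


@dataclass(frozen=True)
class SavGolConfig:
    """Savitzky-Golay filter settings; second derivative by default.

    Window of 15 points (~54 cm^-1 on the 1557-point grid) with a
    quadratic fit is common NIR practice.
    """

    window_points: int = 15
    poly_order: int = 2
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0 or self.window_points <= self.poly_order:
            raise ValueError("window must be odd and exceed poly_order")
        if self.deriv_order > self.poly_order:
            raise ValueError("deriv_order must not exceed poly_order")


def msc(dataset: SpectralDataset, reference: np.ndarray | None = None) -> MSCResult:
    """Regress every row on the reference (default: mean spectrum) by
    OLS, x_i ~ a_i + b_i * ref, and return (x_i - a_i) / b_i."""
    X = dataset.absorbance
    if reference is None:
        if dataset.n_samples < 2:
            raise ValueError("MSC needs >= 2 samples when no reference is given")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (dataset.n_points,):
        raise ValueError("reference length must match grid")
    ref_centered = reference - reference.mean()
    denom = float(ref_centered @ ref_centered)
    if denom <= 0.0:
        raise DegenerateReferenceError("reference spectrum has zero variance")
    # Closed-form simple regression of each row on ref.
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_centered / denom
    offsets = X.mean(axis=1) - slopes * reference.mean()
    corrected = (X - offsets[:, None]) / slopes[:, None]
    return MSCResult(
        corrected=dataset.with_absorbance(corrected, preprocessing="msc"),
        reference=reference,
        offsets=offsets,
        slopes=slopes,
    )


def savgol_second_derivative(
    dataset: SpectralDataset, cfg: SavGolConfig = SavGolConfig()
) -> SpectralDataset:
    """Savitzky-Golay derivative along wavenumber, in AU per (cm^-1)^deriv.

    Uses the grid's physical spacing, so values are instrument-unit
    correct. Edges are evaluated from the boundary polynomial fits,
    keeping the output aligned with the input grid.
    """
    if cfg.window_points > dataset.n_points:
        raise ValueError("window exceeds number of grid points")
    out = savgol_filter(
        dataset.absorbance,
        window_length=cfg.window_points,
        polyorder=cfg.poly_order,
        deriv=cfg.deriv_order,
        delta=dataset.grid.spacing,
        axis=1,
        mode="interp",
    )
    return dataset.with_absorbance(out, preprocessing="sd", savgol=cfg)


_STEPS = {"msc", "sd"}


def preprocess_pipeline(
    dataset: SpectralDataset,
    steps: list[str],
    savgol: SavGolConfig = SavGolConfig(),
    msc_reference: np.ndarray | None = None,
) -> SpectralDataset:
    """Apply preprocessing steps in order; steps are 'msc' and/or 'sd'."""
    if not steps:
        raise ValueError("steps must be non-empty")
    unknown = [s for s in steps if s not in _STEPS]
    if unknown:
        raise ValueError(f"unknown preprocessing step(s): {unknown}")
    out = dataset
    for step in steps:
        if step == "msc":
            out = msc(out, reference=msc_reference).corrected
        else:
            out = savgol_second_derivative(out, savgol)
    out.meta["preprocessing_chain"] = list(steps)
    return out
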
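"""Core containers for FT-NIR spectral data.

A spectrum is absorbance (AU) sampled on a uniformly spaced, descending
wavenumber grid (cm^-1), the convention of FT-NIR instruments that scan
from 10,000 down to 4000 cm^-1. A dataset is a samples x wavenumbers
matrix with one class label and one unique sample id per row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["WavenumberGrid", "SpectralDataset", "make_wavenumber_grid"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly descending, uniformly spaced wavenumber axis in cm^-1.

    Instrument grids are uniform to within 1e-9 relative (the default
    tolerance). Block-averaged (binned) axes with near-equal bin sizes
    may relax `spacing_rtol` explicitly.
    """

    values: np.ndarray
    spacing_rtol: float = 1e-9

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least 2 points")
        diffs = np.diff(values)
        if not np.all(diffs < 0):
            raise ValueError("grid must be strictly descending")
        spacing = np.mean(diffs)
        if not np.allclose(diffs, spacing, rtol=self.spacing_rtol, atol=0.0):
            raise ValueError("grid spacing must be uniform")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Physical step |dv| in cm^-1 (positive)."""
        return float(self.values[0] - self.values[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.allclose(self.values, other.values, rtol=1e-12)
        )


def make_wavenumber_grid(start: float, end: float, n_points: int) -> WavenumberGrid:
    """Build a descending uniform grid from `start` down to `end` cm^-1.

    The instrument range 10,000-4000 cm^-1 sampled at 1557 points gives a
    spacing of ~3.856 cm^-1.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not start > end:
        raise ValueError("start must exceed end (descending grid)")
    return WavenumberGrid(np.linspace(float(start), float(end), int(n_points)))


@dataclass
class SpectralDataset:
    """Samples x wavenumbers absorbance matrix with labels and ids."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.labels = np.asarray(self.labels)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x points)")
        n = self.absorbance.shape[0]
        if self.absorbance.shape[1] != self.grid.n_points:
            raise ValueError("absorbance column count must match grid")
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("labels/sample_ids must align with rows")
        if len(set(self.sample_ids.tolist())) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return int(self.absorbance.shape[0])

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    @property
    def classes(self) -> np.ndarray:
        """Distinct labels in order of first appearance."""
        _, idx = np.unique(self.labels, return_index=True)
        return self.labels[np.sort(idx)]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SpectralDataset":
        """Row subset preserving order of `indices`."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[idx].copy(),
            labels=self.labels[idx].copy(),
            sample_ids=self.sample_ids[idx].copy(),
            meta=dict(self.meta),
        )

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "SpectralDataset":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return SpectralDataset(
            grid=self.grid,
            absorbance=absorbance,
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
            meta=new_meta,
        )

    def class_indices(self, label) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    # ---- delimited-table I/O ------------------------------------------

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        """Write as a delimited table: sample_id, label, then one column
        per wavenumber (header row holds the wavenumbers)."""
        cols = [f"{v:.10f}" for v in self.grid.values]
        df = pd.DataFrame(self.absorbance, columns=cols)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep=sep, index=False, encoding="utf-8")

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "SpectralDataset":
        df = pd.read_csv(path, sep=sep, encoding="utf-8")
        if df.columns[0] != "sample_id" or df.columns[1] != "label":
            raise ValueError("table must start with sample_id and label columns")
        grid = WavenumberGrid(np.array([float(c) for c in df.columns[2:]]))
        return cls(
            grid=grid,
            absorbance=df.iloc[:, 2:].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            sample_ids=df["sample_id"].to_numpy(dtype=object),
        )


def save_ground_truth(path: str | Path, truth: dict) -> None:
    """JSON sidecar for generator ground truth (informative bands, outliers)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, indent=2, default=_default))


def load_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
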
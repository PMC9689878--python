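"""Kennard-Stone representative sample-set partitioning.

Deterministic maximin selection: start from the most distant pair, then
repeatedly add the sample whose minimum Euclidean distance to the
selected set is largest. Ties break toward the lowest row index so the
split is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset

__all__ = ["SplitResult", "kennard_stone", "split_dataset"]


@dataclass
class SplitResult:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray | None = None
    fractions: dict = field(default_factory=dict)
    metric: str = "euclidean"

    def sets(self) -> dict[str, np.ndarray]:
        out = {"train": self.train, "test": self.test}
        if self.validation is not None:
            out["validation"] = self.validation
        return out


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Return the ordered maximin selection of `n_select` row indices."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError("n_select must be in [2, n]")

    # Pairwise squared distances via the Gram expansion; n is small
    # (hundreds) in calibration-transfer practice, so O(n^2) memory is fine.
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    # First two picks: the most distant pair, lowest indices on ties.
    flat = np.argmax(d2)  # argmax returns the first (lowest) flat index
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False

    mind2 = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < n_select:
        cand = np.where(remaining, mind2, -np.inf)
        pick = int(np.argmax(cand))  # first occurrence = lowest index tie-break
        selected.append(pick)
        remaining[pick] = False
        np.minimum(mind2, d2[pick], out=mind2)
    return np.asarray(selected, dtype=int)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(dataset: SpectralDataset, fractions: dict[str, float]) -> SplitResult:
    """KS split into train/test(/validation) by the given fractions.

    Counts are round-half-up on n*fraction, with the final set taking
    the remainder: 202 samples at {train: 0.7} give the study's
    141-train / 61-test partition. KS first selects the training set
    from all samples; for three-way splits it is re-run on the
    remainder to pick the test set, and the leftover samples form the
    validation set.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    known = {"train", "test", "validation"}
    if not set(fractions) <= known:
        raise ValueError(f"fraction names must be among {sorted(known)}")
    if any(f <= 0 for f in fractions.values()):
        raise ValueError("fractions must be positive")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("fractions must sum to at most 1")

    n = dataset.n_samples
    X = dataset.absorbance
    n_train = _round_half_up(n * fractions["train"])
    three_way = "validation" in fractions or len(fractions) == 3
    if "test" in fractions:
        n_test = _round_half_up(n * fractions["test"])
    else:
        n_test = n - n_train
        three_way = False
    if n_train < 2 or n_test < 1:
        raise ValueError("split leaves an empty or degenerate set")

    train_idx = kennard_stone(X, n_train)
    rest = np.setdiff1d(np.arange(n), train_idx)

    if three_way:
        n_val = n - n_train - n_test
        if n_val < 1:
            raise ValueError("validation set would be empty")
        if n_test < 2:
            raise ValueError("test set too small for KS selection")
        test_local = kennard_stone(X[rest], n_test)
        test_idx = rest[test_local]
        val_idx = np.setdiff1d(rest, test_idx)
        return SplitResult(
            train=np.sort(train_idx),
            test=np.sort(test_idx),
            validation=np.sort(val_idx),
            fractions=dict(fractions),
        )
    if rest.size == 0:
        raise ValueError("test set is empty")
    return SplitResult(train=np.sort(train_idx), test=np.sort(rest), fractions=dict(fractions))
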
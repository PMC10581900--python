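"""Pairwise dissimilarities for discrete character matrices.

The workhorse is Gower's coefficient for unordered characters: for a pair of
units, the dissimilarity is the fraction of *comparable* characters on which
they differ.  A character is comparable for a pair only when both cells carry
coded states — missing and inapplicable cells drop out — and, under the
default ``ignore_matching_zeros`` mode, when the cells are not both zero, so
shared absence (or shared inapplicability recoded as absence) carries no
similarity signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix_io import CharacterMatrix

logger = logging.getLogger("phytodisparity")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with per-pair comparable counts.

    ``flagged`` marks pairs whose value is a fallback (no comparable
    characters existed); such pairs carry no information and downstream
    ordination gives them zero weight.
    """

    labels: list[str]
    values: np.ndarray
    comparable_counts: np.ndarray | None = None
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("values must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.flagged is None:
            self.flagged = np.zeros((n, n), dtype=bool)
        if self.comparable_counts is not None:
            self.comparable_counts = np.asarray(self.comparable_counts)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major (scipy squareform) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(
            list(labels),
            self.values[sel],
            None if self.comparable_counts is None else self.comparable_counts[sel],
            self.flagged[sel],
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, index_label="unit", float_format="%.10g"
        )
        if self.flagged.any():
            iu = np.triu_indices(self.n, k=1)
            rows = [
                {"unit_a": self.labels[i], "unit_b": self.labels[j]}
                for i, j in zip(*iu)
                if self.flagged[i, j]
            ]
            pd.DataFrame(rows).to_csv(
                str(path).replace(".csv", "") + ".flags.csv", index=False
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls([str(x) for x in df.index], df.to_numpy(dtype=float))

    @classmethod
    def from_coordinates(cls, labels: list[str], coords: np.ndarray) -> "DistanceMatrix":
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return cls(list(labels), d)


def _cells_and_masks(m: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    cells = m.cells.astype(np.int16)
    coded = cells >= 0
    return cells, coded


def _finalize(labels, d, comparable, undefined) -> DistanceMatrix:
    flagged = undefined.copy()
    np.fill_diagonal(flagged, False)
    if flagged.any():
        defined = ~undefined
        np.fill_diagonal(defined, False)
        if not defined.any():
            raise ValueError("no pair of units shares any comparable character")
        fill = d[defined].max()
        d = d.copy()
        d[flagged] = fill
        logger.warning(
            "%d pairs had no comparable characters; set to max observed %.4g",
            int(flagged.sum()) // 2,
            fill,
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, comparable, flagged)


def gower(m: CharacterMatrix, zero_mode: str = "ignore_matching_zeros") -> DistanceMatrix:
    """Gower dissimilarity over unordered discrete characters.

    Per pair: (# comparable characters with unequal states) / (# comparable
    characters).  Under ``ignore_matching_zeros`` a character where both
    cells are state 0 is excluded from the comparable set; ``count_zeros``
    keeps it (contributing similarity).  Pairs with an empty comparable set
    are imputed to the maximum observed distance and flagged.
    """
    if zero_mode not in {"count_zeros", "ignore_matching_zeros"}:
        raise ValueError(f"unknown zero_mode {zero_mode!r}")
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    cells, coded = _cells_and_masks(m)
    n = m.n_taxa
    # Pairwise over taxa; vectorised across characters per row pair block.
    comparable = np.zeros((n, n), dtype=np.int64)
    mismatch = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = coded[i][None, :] & coded  # (n, nchar)
        if zero_mode == "ignore_matching_zeros":
            both &= ~((cells[i][None, :] == 0) & (cells == 0))
        diff = both & (cells[i][None, :] != cells)
        comparable[i] = both.sum(axis=1)
        mismatch[i] = diff.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), np.nan)
    undefined = comparable == 0
    d = np.where(undefined, 0.0, d)
    return _finalize(list(m.taxa), d, comparable, undefined)


def euclidean(m: CharacterMatrix) -> DistanceMatrix:
    """Euclidean distance over comparable characters, missingness-rescaled.

    sqrt of summed squared state differences over comparable characters,
    multiplied by sqrt(total / comparable) so sparsely compared pairs are
    not biased toward zero.
    """
    if m.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    cells, coded = _cells_and_masks(m)
    n, p = m.n_taxa, m.n_characters
    comparable = np.zeros((n, n), dtype=np.int64)
    ss = np.zeros((n, n))
    fc = cells.astype(float)
    for i in range(n):
        both = coded[i][None, :] & coded
        diff2 = np.where(both, (fc[i][None, :] - fc) ** 2, 0.0)
        comparable[i] = both.sum(axis=1)
        ss[i] = diff2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(ss * (p / np.maximum(comparable, 1)))
    undefined = comparable == 0
    d = np.where(undefined, 0.0, d)
    return _finalize(list(m.taxa), d, comparable, undefined)
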
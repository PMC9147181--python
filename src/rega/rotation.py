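"""Feature-subset rotation: PCA on continuous columns, MCA on binary columns.

A subset of columns from the fused matrix is split by column kind. The
continuous part is rotated by a full-rank PCA (all components of nonzero
variance retained, Rotation-Forest style: the space is rotated, not
reduced). The binary part is rotated by multiple correspondence analysis
of its complete disjunctive coding (two indicator columns per feature),
via the SVD of the standardized residual matrix

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},

where P is the relative-frequency table of the indicator matrix and r, c
its row and column margins. Row coordinates of new samples are obtained
from the stored column margins and right singular vectors, so held-out
rows are projected without refitting. The two rotated parts are then
concatenated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Singular values at or below this fraction of the largest are treated as zero.
SVD_RTOL = 1e-10


class DegenerateSubsetError(ValueError):
    """Raised when a subset has no usable columns to rotate."""


@dataclass
class ColumnPartition:
    continuous_cols: np.ndarray
    binary_cols: np.ndarray


def partition_columns(subset: Sequence[int],
                      column_kinds: Sequence[str]) -> ColumnPartition:
    """Split a feature subset by column kind, deduplicating within the subset.

    Duplicate indices (legal in the GA encoding) are removed keeping the
    first occurrence; each retained index is routed by its column kind.
    """
    kinds = np.asarray(column_kinds, dtype=object)
    seen: set[int] = set()
    cont, binary = [], []
    for idx in subset:
        idx = int(idx)
        if idx < 0 or idx >= len(kinds):
            raise IndexError(f"feature index {idx} out of range [0, {len(kinds)})")
        if idx in seen:
            continue
        seen.add(idx)
        if kinds[idx] == "continuous":
            cont.append(idx)
        else:
            binary.append(idx)
    return ColumnPartition(np.asarray(cont, dtype=int), np.asarray(binary, dtype=int))


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if loadings.size == 0:
        return loadings
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


@dataclass
class PcaFit:
    means: np.ndarray          # column means of the fitting block
    loadings: np.ndarray       # d_c x r_c, orthonormal columns
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @classmethod
    def fit(cls, block: np.ndarray) -> "PcaFit":
        means = block.mean(axis=0)
        centered = block - means
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        keep = s > SVD_RTOL * (s[0] if s.size else 0.0)
        loadings = _fix_signs(vt[keep].T)
        return cls(means, loadings, s[keep])

    def transform(self, block: np.ndarray) -> np.ndarray:
        return (block - self.means) @ self.loadings


@dataclass
class McaFit:
    """MCA of the complete disjunctive coding of a binary block."""

    feature_cols: np.ndarray       # original column indices actually retained
    col_margins: np.ndarray        # c: margins of the 2m indicator columns
    right_vectors: np.ndarray      # D_c^{-1/2} V, shape 2m x r_b
    singular_values: np.ndarray
    dropped_constant: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_components(self) -> int:
        return self.right_vectors.shape[1]

    @staticmethod
    def indicator(block: np.ndarray) -> np.ndarray:
        """Complete disjunctive coding: per feature, a 0- and a 1-indicator column."""
        n, m = block.shape
        Z = np.empty((n, 2 * m))
        Z[:, 0::2] = 1.0 - block
        Z[:, 1::2] = block
        return Z

    @classmethod
    def fit(cls, block: np.ndarray, feature_cols: np.ndarray) -> "McaFit":
        constant = np.ptp(block, axis=0) == 0
        dropped = feature_cols[constant]
        block = block[:, ~constant]
        feature_cols = feature_cols[~constant]
        if block.shape[1] == 0:
            return cls(feature_cols, np.empty(0), np.empty((0, 0)), np.empty(0),
                       dropped_constant=dropped)
        Z = cls.indicator(block)
        P = Z / Z.sum()
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        _, s, vt = np.linalg.svd(S, full_matrices=False)
        keep = s > SVD_RTOL * (s[0] if s.size else 0.0)
        V = _fix_signs(vt[keep].T)
        right = V / np.sqrt(c)[:, None]
        return cls(feature_cols, c, right, s[keep], dropped_constant=dropped)

    def transform(self, block: np.ndarray) -> np.ndarray:
        if self.n_components == 0:
            return np.empty((block.shape[0], 0))
        Z = self.indicator(block)
        profiles = Z / Z.sum(axis=1, keepdims=True)
        return (profiles - self.col_margins) @ self.right_vectors


class SubsetRotation:
    """Rotation of one feature subset; fit on training rows, applied anywhere.

    Parameters
    ----------
    subset : sequence of int
        Feature indices (duplicates permitted; deduplicated internally).
    column_kinds : sequence of {"binary", "continuous"}
        Kind of every column of the full matrix.
    """

    def __init__(self, subset: Sequence[int], column_kinds: Sequence[str]):
        self.subset = np.asarray(subset, dtype=int)
        self.column_kinds = column_kinds

    def fit(self, X: np.ndarray) -> "SubsetRotation":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a rotation")
        part = partition_columns(self.subset, self.column_kinds)
        self.partition_ = part
        self.pca_ = (PcaFit.fit(X[:, part.continuous_cols])
                     if part.continuous_cols.size else None)
        self.mca_ = (McaFit.fit(X[:, part.binary_cols], part.binary_cols)
                     if part.binary_cols.size else None)
        r_c = self.pca_.n_components if self.pca_ else 0
        r_b = self.mca_.n_components if self.mca_ else 0
        if r_c + r_b == 0:
            raise DegenerateSubsetError(
                "degenerate subset: no non-constant column to rotate")
        self.n_components_ = r_c + r_b
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        parts = []
        if self.pca_ is not None:
            parts.append(self.pca_.transform(X[:, self.partition_.continuous_cols]))
        if self.mca_ is not None and self.mca_.n_components:
            parts.append(self.mca_.transform(X[:, self.mca_.feature_cols]))
        return np.hstack(parts) if parts else np.empty((X.shape[0], 0))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_rotation(X: np.ndarray, subset: Sequence[int],
                 column_kinds: Sequence[str]) -> SubsetRotation:
    return SubsetRotation(subset, column_kinds).fit(X)


def apply_rotation(rot: SubsetRotation, X: np.ndarray) -> np.ndarray:
    return rot.transform(X)
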
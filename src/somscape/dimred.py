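"""Truncated SVD of the feature matrix and projection into fingerprint space.

High-dimensional feature tables (e.g. thousands of fragment-occurrence rows)
are reduced before map training: the top-``k`` singular directions of the
(optionally column-mean-centered) matrix define a k-dimensional space, and
each pattern's *fingerprint* is its coordinate vector in that space.  With
centering on, this is exactly the PCA scores representation of the patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .io import FeatureMatrix

__all__ = ["SVDResult", "Fingerprints", "truncated_svd", "project_fingerprints"]


@dataclass
class SVDResult:
    """Top-k singular triples of the (centered) feature matrix.

    ``left_vectors`` (n_features x k) and ``right_vectors`` (n_patterns x k)
    have orthonormal columns; ``singular_values`` is nonincreasing and
    nonnegative.  ``column_mean`` records the per-feature mean subtracted
    before decomposition (all zeros when centering was off).
    """

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors: np.ndarray
    k: int
    column_mean: np.ndarray


@dataclass
class Fingerprints:
    """Reduced-dimension pattern vectors, one row per pattern id."""

    vectors: np.ndarray  # (n_patterns, k)
    pattern_ids: list
    k: int

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.pattern_ids), self.k):
            raise ValidationError(
                f"fingerprint array shape {self.vectors.shape} does not match "
                f"{len(self.pattern_ids)} patterns x k={self.k}"
            )

    @property
    def n_patterns(self) -> int:
        return self.vectors.shape[0]


def default_k(n_features: int, n_patterns: int) -> int:
    """Default reduced dimensionality: min(10, min(n_features, n_patterns))."""
    return min(10, n_features, n_patterns)


def truncated_svd(matrix: FeatureMatrix, k: int | None = None, center: bool = True) -> SVDResult:
    """Compute the top-``k`` singular triples of the feature matrix.

    Parameters
    ----------
    matrix : FeatureMatrix
        Input table, features x patterns.
    k : int, optional
        Number of singular directions to keep; defaults to
        ``min(10, n_features, n_patterns)``.
    center : bool
        Subtract the per-feature mean across patterns first (default).

    Notes
    -----
    Signs are fixed so the largest-magnitude entry of each left singular
    vector is positive, making results reproducible across runs and
    LAPACK backends.
    """
    A = matrix.values
    n_features, n_patterns = A.shape
    if k is None:
        k = default_k(n_features, n_patterns)
    if not (1 <= k <= min(n_features, n_patterns)):
        raise ValidationError(
            f"k={k} out of range [1, {min(n_features, n_patterns)}]"
        )
    if center:
        column_mean = A.mean(axis=1)
    else:
        column_mean = np.zeros(n_features)
    U, s, Vt = np.linalg.svd(A - column_mean[:, None], full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k, :]
    # deterministic sign: largest-|entry| of each left vector made positive
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    return SVDResult(
        left_vectors=U,
        singular_values=s,
        right_vectors=Vt.T,
        k=k,
        column_mean=column_mean,
    )


def project_fingerprints(matrix: FeatureMatrix, svd: SVDResult) -> Fingerprints:
    """Project each pattern column onto the retained singular directions.

    The fingerprint of pattern j is ``left_vectors.T @ (column_j - column_mean)``.
    """
    if matrix.values.shape[0] != svd.left_vectors.shape[0]:
        raise ValidationError(
            f"matrix has {matrix.values.shape[0]} features but the SVD was "
            f"computed for {svd.left_vectors.shape[0]}"
        )
    centered = matrix.values - svd.column_mean[:, None]
    vectors = centered.T @ svd.left_vectors
    return Fingerprints(vectors=vectors, pattern_ids=list(matrix.pattern_ids), k=svd.k)
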
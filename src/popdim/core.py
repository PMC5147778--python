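"""PCA-based dimensionality of samples-by-features matrices.

The central quantity throughout the package is the *dimensionality* of a
data matrix: the minimal number of orthonormal basis patterns (principal
axes in feature space) whose cumulative explained variance reaches a stated
threshold (90% by default).  The matrix rows may be movie frames (features =
pixel-block intensities) or time bins of trial-averaged population activity
(features = neurons); the machinery is identical.

Centering is performed exactly once per matrix and recorded in metadata;
windowed analyses downstream deliberately consume slices of the globally
centered matrix without re-centering, so the flag is part of the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, DegenerateDataError, InvalidInputError

DEFAULT_VARIANCE_THRESHOLD = 0.9

#: Singular values below this multiple of the leading one are treated as
#: numerically zero when building variance curves.
RANK_FLOOR = 1e-12


@dataclass
class DataMatrix:
    """A samples x features real matrix with centering metadata.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_features)``.
    centered
        True iff every feature column has zero mean.
    feature_means
        Per-feature means recorded at centering time (None if not centered).
    provenance
        Free-text label describing where the matrix came from.
    """

    values: np.ndarray
    centered: bool = False
    feature_means: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("DataMatrix requires a 2-d array")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("DataMatrix must not contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class BasisPatternSet:
    """Orthonormal feature-space patterns with their variance fractions.

    ``patterns`` has shape ``(ambient_dim, k)`` where ``k`` is the smallest
    number of leading principal axes whose cumulative variance fraction
    reaches ``variance_threshold``.  ``variance_fractions`` holds the
    fractions of the retained patterns (descending).
    """

    patterns: np.ndarray
    variance_fractions: np.ndarray
    variance_threshold: float
    ambient_dim: int
    provenance: str = ""

    @property
    def k(self) -> int:
        return self.patterns.shape[1]


def center_features(matrix: DataMatrix) -> DataMatrix:
    """Subtract each feature's mean, recording the means in metadata.

    Asking to center an already-centered matrix warns and returns the input
    unchanged (centering is idempotent but the double request usually
    indicates a pipeline bug).
    """
    if matrix.centered:
        warnings.warn("matrix is already centered; returning it unchanged",
                      stacklevel=2)
        return matrix
    means = matrix.values.mean(axis=0)
    return DataMatrix(values=matrix.values - means, centered=True,
                      feature_means=means, provenance=matrix.provenance)


def _fix_signs(patterns: np.ndarray) -> np.ndarray:
    """Make each pattern's largest-magnitude coefficient positive.

    PCA signs are arbitrary; fixing them makes serialized outputs
    reproducible across BLAS implementations.
    """
    idx = np.argmax(np.abs(patterns), axis=0)
    signs = np.sign(patterns[idx, np.arange(patterns.shape[1])])
    signs[signs == 0] = 1.0
    return patterns * signs


def variance_spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values and variance fractions of a (pre-centered) matrix.

    Returns ``(singular_values, fractions)`` with numerically-zero singular
    values (below ``RANK_FLOOR`` x the largest) removed.
    """
    s = np.linalg.svd(values, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        raise DegenerateDataError("matrix has zero total variance")
    s = s[s > RANK_FLOOR * s[0]]
    var = s ** 2
    return s, var / var.sum()

def count_dimensions(fractions: np.ndarray, variance_threshold: float) -> int:
    """Minimal k with cumulative variance fraction >= threshold (inclusive)."""
    if not 0.0 < variance_threshold <= 1.0:
        raise InvalidInputError("variance_threshold must be in (0, 1]")
    cum = np.cumsum(fractions)
    # tolerance keeps exact-equality ties (e.g. eigenvalues {9, 1} at 0.9)
    # on the inclusive side despite float rounding
    k = int(np.searchsorted(cum, variance_threshold - 1e-12)) + 1
    return min(k, fractions.size)


def patterns_of_rows(values: np.ndarray,
                     variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Leading right singular vectors reaching the variance threshold.

    Operates on the rows as given (no centering), which is what windowed
    analyses need.  Returns ``(patterns, fractions_of_retained)``.
    """
    U, s, Vt = np.linalg.svd(values, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        raise DegenerateDataError("matrix has zero total variance")
    keep = s > RANK_FLOOR * s[0]
    s = s[keep]
    Vt = Vt[keep]
    var = s ** 2
    fractions = var / var.sum()
    k = count_dimensions(fractions, variance_threshold)
    return _fix_signs(Vt[:k].T), fractions[:k]


def _require_centered(matrix: DataMatrix) -> None:
    if not matrix.centered:
        raise ContractError(
            "matrix must be centered first (use center_features); windowed "
            "analyses rely on a single global centering")


def pca_patterns(matrix: DataMatrix,
                 variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                 ) -> BasisPatternSet:
    """Basis patterns of a centered matrix up to the variance threshold."""
    _require_centered(matrix)
    if matrix.n_samples < 2:
        raise InvalidInputError("need at least 2 samples for PCA")
    patterns, fractions = patterns_of_rows(matrix.values, variance_threshold)
    return BasisPatternSet(patterns=patterns, variance_fractions=fractions,
                           variance_threshold=variance_threshold,
                           ambient_dim=matrix.n_features,
                           provenance=matrix.provenance)


def dimensionality(matrix: DataMatrix,
                   variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                   ) -> int:
    """Number of basis patterns needed to reach the variance threshold."""
    _require_centered(matrix)
    if matrix.n_samples < 2:
        raise InvalidInputError("need at least 2 samples for PCA")
    _, fractions = variance_spectrum(matrix.values)
    return count_dimensions(fractions, variance_threshold)


def cumulative_variance_curve(matrix: DataMatrix) -> np.ndarray:
    """Nondecreasing cumulative variance fractions, ending at 1."""
    _require_centered(matrix)
    _, fractions = variance_spectrum(matrix.values)
    return np.cumsum(fractions)


def total_variance(matrix: DataMatrix) -> float:
    """Summed sample variance over features (1/(n-1) normalization)."""
    _require_centered(matrix)
    return float(np.sum(matrix.values ** 2) / max(matrix.n_samples - 1, 1))
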
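"""Time-resolved dimensionality: tiled windows, growing windows, window-pair
similarity matrices, subsampled error bars and the time-shuffle control.

All windowed analyses consume a matrix that was centered exactly once,
globally; the per-window mean is never re-subtracted, so dimensionality is
measured in a common reference frame across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregation import (DEFAULT_RANK_THRESHOLD, AggregatedPatterns,
                          chance_distribution, effective_rank,
                          similarity_index)
from .core import (DEFAULT_VARIANCE_THRESHOLD, DataMatrix, count_dimensions,
                   patterns_of_rows, variance_spectrum)
from .errors import ContractError, DegenerateDataError, InvalidInputError


@dataclass
class WindowSpec:
    """Windowing of a binned time series."""

    window_length_s: float = 1.0
    bin_width_ms: float = 20.0
    mode: str = "tiled"            # "tiled" or "growing"

    @property
    def bins_per_window(self) -> int:
        bins = self.window_length_s * 1000.0 / self.bin_width_ms
        if bins <= 0 or abs(bins - round(bins)) > 1e-9:
            raise InvalidInputError(
                "window length must be a positive multiple of the bin width")
        return int(round(bins))


@dataclass
class SimilarityMatrix:
    """Similarity indices for every pair of time windows."""

    s_values: np.ndarray           # symmetric, NaN where degenerate
    window_starts_s: np.ndarray

    @property
    def mean_offdiag(self) -> float:
        n = self.s_values.shape[0]
        mask = ~np.eye(n, dtype=bool)
        vals = self.s_values[mask]
        return float(np.nanmean(vals))


def _check_centered(matrix: DataMatrix) -> None:
    if not matrix.centered:
        raise ContractError("windowed analyses require a globally centered "
                            "matrix (center exactly once)")


def _window_slices(n_samples: int, bins: int) -> list[slice]:
    if bins > n_samples:
        raise InvalidInputError(
            f"window of {bins} bins longer than record of {n_samples}")
    return [slice(i, i + bins) for i in range(0, n_samples - bins + 1, bins)]


def _dim_of_rows(values: np.ndarray, variance_threshold: float) -> int:
    _, fractions = variance_spectrum(values)
    return count_dimensions(fractions, variance_threshold)


def windowed_dimensionality(matrix: DataMatrix, spec: WindowSpec,
                            variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                            ) -> np.ndarray:
    """Dimensionality of each non-overlapping window of the record."""
    _check_centered(matrix)
    bins = spec.bins_per_window
    return np.array([_dim_of_rows(matrix.values[sl], variance_threshold)
                     for sl in _window_slices(matrix.n_samples, bins)])


def growing_window_dimensionality(matrix: DataMatrix,
                                  variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                                  spec: WindowSpec | None = None) -> np.ndarray:
    """Dimensionality of windows growing from the record start.

    Window lengths are 1, 2, ... multiples of the base window; the final
    (unsmoothed) value equals the whole-record dimensionality whenever the
    record length is a multiple of the base window.
    """
    _check_centered(matrix)
    spec = spec or WindowSpec()
    bins = spec.bins_per_window
    n_windows = matrix.n_samples // bins
    if n_windows < 1:
        raise InvalidInputError("record shorter than one window")
    return np.array([_dim_of_rows(matrix.values[:(i + 1) * bins],
                                  variance_threshold)
                     for i in range(n_windows)])


def smooth_curve(values: np.ndarray, kernel_sd: float = 1.5,
                 sample_interval: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with edge-renormalized (truncated) kernel.

    The kernel is discretized at the sampling interval, truncated at
    4 standard deviations, and renormalized over its available support at
    the edges so constant series pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    if kernel_sd <= 0:
        return values.copy()
    sd_bins = kernel_sd / sample_interval
    half = max(int(np.ceil(4 * sd_bins)), 1)
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sd_bins) ** 2)
    n = values.size
    out = np.empty(n)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half, n - 1)
        w = kernel[(lo - i) + half:(hi - i) + half + 1]
        out[i] = np.dot(w, values[lo:hi + 1]) / w.sum()
    return out


def window_similarity_matrix(matrix: DataMatrix, spec: WindowSpec,
                             variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                             t: float = DEFAULT_RANK_THRESHOLD,
                             n_draws: int = 100,
                             rng_seed: int | np.random.Generator | None = None,
                             ) -> SimilarityMatrix:
    """Similarity index between pattern sets of every window pair.

    Chance levels are Monte-Carlo draws at the matrix's ambient dimension,
    cached per pair of set sizes.  Degenerate (zero-variance) windows yield
    NaN entries that are excluded from the off-diagonal mean.
    """
    _check_centered(matrix)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    bins = spec.bins_per_window
    slices = _window_slices(matrix.n_samples, bins)
    if len(slices) < 2:
        raise InvalidInputError("need at least two windows")
    sets: list[np.ndarray | None] = []
    for sl in slices:
        try:
            p, _ = patterns_of_rows(matrix.values[sl], variance_threshold)
            sets.append(p)
        except DegenerateDataError:
            sets.append(None)
    n = len(slices)
    chance_cache: dict[tuple[int, int], float] = {}
    s_mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            if sets[i] is None or sets[j] is None:
                continue
            ki, kj = sets[i].shape[1], sets[j].shape[1]
            agg = AggregatedPatterns(np.hstack([sets[i], sets[j]]),
                                     set_sizes=(ki, kj), rank_threshold=t)
            k_agg = effective_rank(agg)
            key = (min(ki, kj), max(ki, kj))
            if key not in chance_cache:
                chance_cache[key] = chance_distribution(
                    key, matrix.n_features, t=t, n_draws=n_draws,
                    rng_seed=rng).mean_chance
            s = similarity_index(k_agg, chance_cache[key], (ki, kj))
            s_mat[i, j] = s_mat[j, i] = s
    starts = np.array([sl.start * spec.bin_width_ms / 1000.0 for sl in slices])
    return SimilarityMatrix(s_values=s_mat, window_starts_s=starts)


def shuffle_time(matrix: DataMatrix,
                 rng_seed: int | np.random.Generator | None = None,
                 ) -> DataMatrix:
    """Permute time bins (rows) identically across all features.

    Destroys temporal correlations while leaving whole-record PCA, and
    hence whole-record dimensionality, exactly unchanged.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    perm = rng.permutation(matrix.n_samples)
    return DataMatrix(values=matrix.values[perm], centered=matrix.centered,
                      feature_means=matrix.feature_means,
                      provenance=matrix.provenance + " (time-shuffled)")


def subsample_dimensionality(matrix: DataMatrix, fraction: float = 0.5,
                             n_repeats: int = 100,
                             variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                             rng_seed: int | np.random.Generator | None = None,
                             ) -> np.ndarray:
    """Dimensionality over repeated row subsamples (without replacement).

    The standard deviation of the returned values is the conventional
    error bar for dimensionality estimates.
    """
    _check_centered(matrix)
    if not 0.0 < fraction <= 1.0:
        raise InvalidInputError("fraction must be in (0, 1]")
    size = int(round(fraction * matrix.n_samples))
    if size < 2:
        raise InvalidInputError("subsample would keep fewer than 2 samples")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = np.empty(n_repeats, dtype=int)
    for r in range(n_repeats):
        rows = (np.arange(matrix.n_samples) if fraction == 1.0
                else rng.choice(matrix.n_samples, size=size, replace=False))
        out[r] = _dim_of_rows(matrix.values[rows], variance_threshold)
    return out
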
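"""Trial-averaged population activity (PSTHs) and a planted-structure
synthesizer used to exercise the dimensionality pipeline end-to-end.

Conventions: spike counts are taken in fixed-width time bins (20 ms by
default) and averaged across trials; rates are expressed in spikes/s
(counts divided by the bin width in seconds).  The spikes/s scaling is a
global scalar and leaves every dimensionality statistic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, center_features
from .errors import InvalidInputError, UndefinedIndexError

DEFAULT_BIN_WIDTH_MS = 20.0


@dataclass
class TrialRaster:
    """Spike counts indexed (neuron, trial, time bin)."""

    counts: np.ndarray
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise InvalidInputError("raster counts must be (neuron, trial, bin)")
        if np.any(self.counts < 0):
            raise InvalidInputError("spike counts must be non-negative")


@dataclass
class PSTHSet:
    """Trial-averaged firing rates, one row per neuron, in spikes/s."""

    rates: np.ndarray              # (n_neurons, n_bins)
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS
    centered: bool = False
    feature_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2:
            raise InvalidInputError("PSTH rates must be (neuron, bin)")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def to_data_matrix(self, center: bool = True,
                       provenance: str = "psth") -> DataMatrix:
        """Time bins as samples, neurons as features; optionally centered."""
        m = DataMatrix(values=self.rates.T, centered=self.centered,
                       feature_means=self.feature_means,
                       provenance=provenance)
        if center and not m.centered:
            m = center_features(m)
        return m


@dataclass
class PlantedStructure:
    """Ground-truth decomposition: orthonormal neuron-space patterns,
    time-varying latent weights, per-neuron offsets, additive noise."""

    true_patterns: np.ndarray      # (n_neurons, K), orthonormal columns
    latent_weights: np.ndarray     # (K, n_bins)
    mean_offsets: np.ndarray       # (n_neurons,)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.true_patterns = np.asarray(self.true_patterns, dtype=float)
        self.latent_weights = np.atleast_2d(np.asarray(self.latent_weights,
                                                       dtype=float))
        self.mean_offsets = np.asarray(self.mean_offsets, dtype=float)
        gram = self.true_patterns.T @ self.true_patterns
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10):
            raise InvalidInputError("true_patterns must be orthonormal")


def build_psth(raster: TrialRaster) -> PSTHSet:
    """Average spike counts across trials and convert to spikes/s."""
    n, n_trials, n_bins = raster.counts.shape
    if n == 0 or n_trials == 0 or n_bins == 0:
        raise InvalidInputError("raster must have >= 1 neuron, trial and bin")
    mean_counts = raster.counts.mean(axis=1)
    rates = mean_counts / (raster.bin_width_ms / 1000.0)
    return PSTHSet(rates=rates, bin_width_ms=raster.bin_width_ms,
                   centered=False)


def rate_filter(psth: PSTHSet, min_rate: float = 1.0) -> PSTHSet:
    """Keep neurons whose mean rate is strictly greater than ``min_rate``.

    Strict inequality implements "greater than 1 spike per second".
    """
    if psth.centered:
        raise InvalidInputError("rate_filter requires uncentered rates")
    keep = psth.rates.mean(axis=1) > min_rate
    return PSTHSet(rates=psth.rates[keep], bin_width_ms=psth.bin_width_ms,
                   centered=False)


def direction_index(preferred_response: float, null_response: float) -> float:
    """1 - null/preferred; near 1 for direction-selective neurons."""
    if preferred_response <= 0:
        raise UndefinedIndexError(
            "direction index undefined for non-positive preferred response")
    if null_response < 0:
        raise InvalidInputError("null response must be non-negative")
    return 1.0 - null_response / preferred_response


def smoothed_gaussian_latents(n_patterns: int, n_bins: int,
                              rng: np.random.Generator,
                              smooth_bins: int = 3,
                              scale: float = 1.0) -> np.ndarray:
    """Independent standard-Gaussian latent series smoothed with a
    moving average, giving planted data PSTH-like temporal smoothness."""
    w = rng.standard_normal((n_patterns, n_bins)) * scale
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        w = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"),
                                1, w)
    return w


def make_planted_structure(n_neurons: int, n_patterns: int, n_bins: int,
                           rng_seed: int | np.random.Generator | None = None,
                           noise_sd: float = 0.0,
                           mean_rate: float = 5.0,
                           latent_scale: float = 1.0) -> PlantedStructure:
    """Random orthonormal patterns with smoothed-Gaussian latents."""
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    from .aggregation import random_orthonormal
    patterns = random_orthonormal(n_neurons, n_patterns, rng)
    weights = smoothed_gaussian_latents(n_patterns, n_bins, rng,
                                        scale=latent_scale)
    offsets = np.full(n_neurons, float(mean_rate))
    return PlantedStructure(true_patterns=patterns, latent_weights=weights,
                            mean_offsets=offsets, noise_sd=noise_sd)


def simulate_psths(structure: PlantedStructure, n_bins: int,
                   rng_seed: int | np.random.Generator | None = None,
                   ) -> tuple[PSTHSet, PlantedStructure]:
    """Synthesize rates = offsets + patterns @ weights + Gaussian noise.

    Returns the PSTH set together with its ground-truth structure.
    """
    if structure.latent_weights.shape[1] != n_bins:
        raise InvalidInputError(
            f"latent_weights has {structure.latent_weights.shape[1]} bins, "
            f"expected {n_bins}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    signal = structure.true_patterns @ structure.latent_weights
    rates = structure.mean_offsets[:, None] + signal
    if structure.noise_sd > 0:
        rates = rates + structure.noise_sd * rng.standard_normal(rates.shape)
    return PSTHSet(rates=rates, centered=False), structure
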
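"""Pattern aggregation: joint dimensionality of several basis-pattern sets.

Given orthonormal pattern sets U_1 ... U_m (one per condition) in a common
N-dimensional feature space, the sets are concatenated into a single matrix
V = [U_1 U_2 ... U_m] and the joint dimensionality is the *effective rank*
of V: the number of singular values above a rank threshold t in (0, 1].
The statistic is bracketed by max_i k_i (fully overlapping subspaces) and
sum_i k_i (mutually orthogonal subspaces).

For two unit vectors at angle theta the singular values of V are
sqrt(1 +- cos(theta)), so with threshold t the pair counts as two dimensions
iff cos(theta) < 1 - t^2; at t = 0.5 the one-to-two transition sits at
arccos(0.75) ~ 41.4 degrees.

Chance levels come from a Monte-Carlo null in which each condition's
patterns are drawn as an independent uniformly-random orthonormal set in the
ambient (or an explicitly constrained M-dimensional) space.  The similarity
index s = (chance - observed) / (sum - max) is positive when subspaces
overlap more than chance and negative when they are closer to orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BasisPatternSet
from .errors import InfeasibleError, InvalidInputError, UndefinedIndexError

DEFAULT_RANK_THRESHOLD = 0.5
DEFAULT_N_DRAWS = 1000

#: Absolute floor (relative to the leading singular value) so that exact
#: duplicate columns never inflate the rank even at t -> 0.
_SV_FLOOR = 1e-10


@dataclass
class AggregatedPatterns:
    """Unit-norm feature-space vectors gathered from >= 2 pattern sets."""

    columns: np.ndarray            # (N, sum k_i)
    set_sizes: tuple[int, ...]
    rank_threshold: float = DEFAULT_RANK_THRESHOLD

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] == 0:
            raise InvalidInputError("need at least one aggregated column")
        norms = np.linalg.norm(self.columns, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise InvalidInputError("all aggregated columns must be unit norm")
        if not 0.0 < self.rank_threshold <= 1.0:
            raise InvalidInputError("rank threshold must be in (0, 1]")


@dataclass
class ChanceDistribution:
    """Aggregated dimensionalities of randomly drawn orthonormal sets."""

    samples: np.ndarray
    ambient_dim: int
    n_draws: int
    seed: int | None = None

    @property
    def mean_chance(self) -> float:
        return float(np.mean(self.samples))


@dataclass
class SimilarityResult:
    """Observed joint dimensionality with its chance context."""

    k_agg: int
    set_sizes: tuple[int, ...]
    lower_bound: int          # max_i k_i
    upper_bound: int          # sum_i k_i
    chance: ChanceDistribution
    s: float
    p_value: float
    rank_threshold: float


def effective_rank(agg: AggregatedPatterns) -> int:
    """Count singular values of the aggregated matrix above the threshold."""
    sv = np.linalg.svd(agg.columns, compute_uv=False)
    cutoff = max(agg.rank_threshold, _SV_FLOOR * sv[0])
    return int(np.sum(sv > cutoff))


def aggregate_dimensionality(sets: list[BasisPatternSet] | list[np.ndarray],
                             t: float = DEFAULT_RANK_THRESHOLD) -> int:
    """Effective rank of the concatenation of several pattern sets."""
    mats = [s.patterns if isinstance(s, BasisPatternSet) else np.asarray(s)
            for s in sets]
    if len(mats) < 2:
        raise InvalidInputError("need at least two pattern sets to aggregate")
    dims = {m.shape[0] for m in mats}
    if len(dims) != 1:
        raise InvalidInputError(
            f"pattern sets live in different ambient dimensions: {sorted(dims)}")
    agg = AggregatedPatterns(columns=np.hstack(mats),
                             set_sizes=tuple(m.shape[1] for m in mats),
                             rank_threshold=t)
    return effective_rank(agg)


def random_orthonormal(ambient_dim: int, k: int,
                       rng: np.random.Generator) -> np.ndarray:
    """k orthonormal columns uniform on the Stiefel manifold.

    Orthonormalizing a standard-Gaussian matrix is rotation invariant,
    hence uniform over k-dimensional subspaces.
    """
    if k > ambient_dim:
        raise InfeasibleError(
            f"cannot draw {k} orthonormal vectors in {ambient_dim} dimensions")
    q, r = np.linalg.qr(rng.standard_normal((ambient_dim, k)))
    # fix the QR sign ambiguity so draws are well-defined
    return q * np.sign(np.diag(r))


def chance_distribution(set_sizes: tuple[int, ...] | list[int],
                        ambient_dim: int,
                        t: float = DEFAULT_RANK_THRESHOLD,
                        n_draws: int = DEFAULT_N_DRAWS,
                        rng_seed: int | np.random.Generator | None = None,
                        ) -> ChanceDistribution:
    """Monte-Carlo null: aggregated dimensionality of random subspaces.

    Each draw samples one independent orthonormal set per condition in the
    ambient space (possibly a constrained M < N) and records the aggregated
    dimensionality at threshold ``t``.
    """
    set_sizes = tuple(int(k) for k in set_sizes)
    if any(k <= 0 for k in set_sizes) or not set_sizes:
        raise InvalidInputError("set sizes must be positive")
    for k in set_sizes:
        if k > ambient_dim:
            raise InfeasibleError(
                f"set size {k} exceeds ambient dimension {ambient_dim}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    samples = np.empty(n_draws, dtype=int)
    for i in range(n_draws):
        cols = [random_orthonormal(ambient_dim, k, rng) for k in set_sizes]
        agg = AggregatedPatterns(columns=np.hstack(cols),
                                 set_sizes=set_sizes, rank_threshold=t)
        samples[i] = effective_rank(agg)
    seed = rng_seed if isinstance(rng_seed, (int, np.integer)) else None
    return ChanceDistribution(samples=samples, ambient_dim=ambient_dim,
                              n_draws=n_draws, seed=seed)


def similarity_index(k_agg: float, mean_chance: float,
                     set_sizes: tuple[int, ...] | list[int]) -> float:
    """Normalized overlap index s = (chance - observed) / (sum - max).

    s = 0 at chance, s -> 1 for full overlap against an orthogonal chance
    level, s < 0 for subspaces closer to orthogonal than chance.
    """
    set_sizes = tuple(int(k) for k in set_sizes)
    if not set_sizes:
        raise InvalidInputError("set_sizes must be nonempty")
    span = sum(set_sizes) - max(set_sizes)
    if span == 0:
        raise UndefinedIndexError(
            "similarity index undefined when sum(k_i) == max(k_i)")
    return (mean_chance - k_agg) / span


def permutation_pvalue(k_agg: float, chance: ChanceDistribution,
                       alternative: str = "overlap") -> float:
    """Add-one tail probability of the observed value under the null.

    ``overlap``: P(null <= observed), small when the observed aggregated
    dimensionality sits below the chance distribution (subspaces overlap).
    ``orthogonal``: the mirrored upper tail.
    """
    n = chance.samples.size
    if n < 1:
        raise InvalidInputError("chance distribution has no samples")
    if alternative == "overlap":
        hits = int(np.sum(chance.samples <= k_agg))
    elif alternative == "orthogonal":
        hits = int(np.sum(chance.samples >= k_agg))
    else:
        raise InvalidInputError("alternative must be 'overlap' or 'orthogonal'")
    return (1 + hits) / (1 + n)


def compare_pattern_sets(sets: list[BasisPatternSet],
                         t: float = DEFAULT_RANK_THRESHOLD,
                         n_draws: int = DEFAULT_N_DRAWS,
                         rng_seed: int | np.random.Generator | None = None,
                         ambient_dim: int | None = None,
                         ) -> SimilarityResult:
    """Full comparison: observed joint dimensionality, chance, s, p.

    ``ambient_dim`` overrides the pattern sets' ambient dimension for the
    chance draws (the constrained-M variant); observed aggregation always
    uses the actual patterns.
    """
    k_agg = aggregate_dimensionality(sets, t)
    sizes = tuple(s.k for s in sets)
    N = ambient_dim if ambient_dim is not None else sets[0].ambient_dim
    chance = chance_distribution(sizes, N, t=t, n_draws=n_draws,
                                 rng_seed=rng_seed)
    s = similarity_index(k_agg, chance.mean_chance, sizes)
    p = permutation_pvalue(k_agg, chance, alternative="overlap")
    return SimilarityResult(k_agg=k_agg, set_sizes=sizes,
                            lower_bound=max(sizes), upper_bound=sum(sizes),
                            chance=chance, s=s, p_value=p, rank_threshold=t)


def equalized_aggregate(matrices: list,
                        n_conditions: int,
                        variance_threshold: float = 0.9,
                        t: float = DEFAULT_RANK_THRESHOLD,
                        subsample_fraction: float = 0.5,
                        n_subsamples: int = 100,
                        rng_seed: int | np.random.Generator | None = None,
                        ) -> dict[int, int]:
    """Aggregated dimensionality per condition count at a fixed column budget.

    Controls for the fact that aggregating more conditions mechanically
    supplies more columns: for every condition count c = 1..n_conditions the
    same total number of patterns is aggregated, gathering them from
    repeated row-subsampled pattern extractions of the first c conditions
    (cycled round-robin) until the budget is met.  The budget is the total
    number of full-data patterns over all ``n_conditions`` conditions, so at
    ``n_subsamples=1, subsample_fraction=1`` the top condition count reduces
    to plain :func:`aggregate_dimensionality`.
    """
    from .core import DataMatrix, patterns_of_rows  # local: avoid cycle

    if not 0.0 < subsample_fraction <= 1.0:
        raise InvalidInputError("subsample_fraction must be in (0, 1]")
    if not 1 <= n_conditions <= len(matrices):
        raise InvalidInputError("n_conditions out of range")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))

    def full_patterns(m: DataMatrix) -> np.ndarray:
        return patterns_of_rows(m.values, variance_threshold)[0]

    def subsample_patterns(m: DataMatrix) -> np.ndarray:
        n = m.values.shape[0]
        size = max(int(round(subsample_fraction * n)), 2)
        rows = rng.choice(n, size=size, replace=False)
        return patterns_of_rows(m.values[rows], variance_threshold)[0]

    budget = sum(full_patterns(m).shape[1] for m in matrices[:n_conditions])

    out: dict[int, int] = {}
    for c in range(1, n_conditions + 1):
        cols: list[np.ndarray] = []
        total = 0
        # at fraction 1 every cycle repeats the same full-data patterns;
        # duplicates add no rank, so cycle freely until the budget is met
        max_cycles = (n_subsamples if subsample_fraction < 1.0
                      else max(n_subsamples, budget))
        for cycle in range(max_cycles):
            for m in matrices[:c]:
                p = (full_patterns(m) if subsample_fraction == 1.0
                     else subsample_patterns(m))
                cols.append(p)
                total += p.shape[1]
                if total >= budget:
                    break
            if total >= budget:
                break
        if total < budget:
            raise InfeasibleError(
                f"cannot reach column budget {budget} for condition count {c} "
                f"within {n_subsamples} subsample cycles")
        V = np.hstack(cols)[:, :budget]
        agg = AggregatedPatterns(columns=V, set_sizes=(budget,),
                                 rank_threshold=t)
        out[c] = effective_rank(agg)
    return out
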
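"""Orientation-sweep experiment drivers.

Given per-orientation population responses (one centered matrix per
drifting-grating orientation, 30 degrees apart), these drivers measure how
joint dimensionality grows with the number of consecutive orientations
combined, and how it varies with the angular offset between two
orientations, together with Monte-Carlo chance curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregation import (DEFAULT_RANK_THRESHOLD, AggregatedPatterns,
                          chance_distribution, effective_rank)
from .core import (DEFAULT_VARIANCE_THRESHOLD, DataMatrix, patterns_of_rows)
from .errors import ContractError, InvalidInputError


@dataclass
class OrientationSweepResult:
    """Mean/SE dimensionality and chance level per sweep point."""

    x_values: np.ndarray          # condition counts or offsets in degrees
    mean_dim: np.ndarray
    sem_dim: np.ndarray
    chance_mean: np.ndarray
    variance_threshold: float
    rank_threshold: float


def _pattern_sets(psths: list[DataMatrix], variance_threshold: float,
                  ) -> list[np.ndarray]:
    for m in psths:
        if not m.centered:
            raise ContractError("orientation sweeps require centered matrices")
    dims = {m.n_features for m in psths}
    if len(dims) != 1:
        raise InvalidInputError("all conditions must share the neuron set")
    return [patterns_of_rows(m.values, variance_threshold)[0] for m in psths]


def _agg(sets: list[np.ndarray], t: float) -> int:
    cols = np.hstack(sets)
    return effective_rank(AggregatedPatterns(
        cols, set_sizes=tuple(s.shape[1] for s in sets), rank_threshold=t))


def consecutive_orientation_sweep(psths: list[DataMatrix],
                                  variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                                  t: float = DEFAULT_RANK_THRESHOLD,
                                  rng_seed=None,
                                  n_chance_draws: int = 100,
                                  ) -> OrientationSweepResult:
    """Joint dimensionality versus number of consecutive orientations.

    For every count m = 1..n and every cyclic starting orientation, the m
    consecutive conditions' pattern sets are aggregated; mean and standard
    error are taken over starts.  The chance curve redraws each start's
    pattern-set sizes as random subspaces of the neuron space.
    """
    sets = _pattern_sets(psths, variance_threshold)
    n = len(sets)
    N = psths[0].n_features
    rng = np.random.default_rng(rng_seed)
    x, mean_d, sem_d, chance = [], [], [], []
    for m in range(1, n + 1):
        vals, ch = [], []
        for start in range(n):
            chosen = [sets[(start + j) % n] for j in range(m)]
            if m == 1:
                vals.append(chosen[0].shape[1])
                ch.append(chosen[0].shape[1])
                continue
            vals.append(_agg(chosen, t))
            sizes = tuple(s.shape[1] for s in chosen)
            ch.append(chance_distribution(sizes, N, t=t,
                                          n_draws=n_chance_draws,
                                          rng_seed=rng).mean_chance)
        vals = np.array(vals, dtype=float)
        x.append(m)
        mean_d.append(vals.mean())
        sem_d.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1
                     else 0.0)
        chance.append(float(np.mean(ch)))
    return OrientationSweepResult(
        x_values=np.array(x), mean_dim=np.array(mean_d),
        sem_dim=np.array(sem_d), chance_mean=np.array(chance),
        variance_threshold=variance_threshold, rank_threshold=t)


def angle_offset_sweep(psths: list[DataMatrix],
                       variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
                       t: float = DEFAULT_RANK_THRESHOLD,
                       rng_seed=None,
                       n_chance_draws: int = 100,
                       subsample_fraction: float = 0.5,
                       n_subsamples: int = 20,
                       ) -> OrientationSweepResult:
    """Joint dimensionality of orientation pairs versus angular offset.

    Offsets run from one orientation step up to 180 degrees.  The 0-degree
    reference aggregates an equal number of patterns gathered from repeated
    row-subsampled extractions of the same condition, so the comparison is
    not confounded by column count.
    """
    sets = _pattern_sets(psths, variance_threshold)
    n = len(sets)
    N = psths[0].n_features
    step = 360.0 / n
    rng = np.random.default_rng(rng_seed)

    x, mean_d, sem_d, chance = [], [], [], []

    # 0-degree reference with equalized pattern counts
    zero_vals = []
    for i, m in enumerate(psths):
        budget = sets[i].shape[1] + sets[(i + n // 2) % n].shape[1]
        cols, total = [sets[i]], sets[i].shape[1]
        for _ in range(n_subsamples):
            if total >= budget:
                break
            rows = rng.choice(m.n_samples,
                              size=max(int(round(subsample_fraction
                                                 * m.n_samples)), 2),
                              replace=False)
            p = patterns_of_rows(m.values[rows], variance_threshold)[0]
            cols.append(p)
            total += p.shape[1]
        V = np.hstack(cols)[:, :budget]
        zero_vals.append(effective_rank(AggregatedPatterns(
            V, set_sizes=(V.shape[1],), rank_threshold=t)))
    zero_vals = np.array(zero_vals, dtype=float)
    x.append(0.0)
    mean_d.append(zero_vals.mean())
    sem_d.append(zero_vals.std(ddof=1) / np.sqrt(zero_vals.size))
    chance.append(np.nan)

    for lag in range(1, n // 2 + 1):
        vals, ch = [], []
        for i in range(n):
            pair = [sets[i], sets[(i + lag) % n]]
            vals.append(_agg(pair, t))
            sizes = (pair[0].shape[1], pair[1].shape[1])
            ch.append(chance_distribution(sizes, N, t=t,
                                          n_draws=n_chance_draws,
                                          rng_seed=rng).mean_chance)
        vals = np.array(vals, dtype=float)
        x.append(lag * step)
        mean_d.append(vals.mean())
        sem_d.append(vals.std(ddof=1) / np.sqrt(vals.size))
        chance.append(float(np.mean(ch)))

    return OrientationSweepResult(
        x_values=np.array(x), mean_dim=np.array(mean_d),
        sem_dim=np.array(sem_d), chance_mean=np.array(chance),
        variance_threshold=variance_threshold, rank_threshold=t)


def threshold_grid(psths: list[DataMatrix],
                   variance_thresholds=(0.7, 0.8, 0.9),
                   rank_thresholds=(DEFAULT_RANK_THRESHOLD,),
                   rng_seed=None,
                   n_chance_draws: int = 100,
                   ) -> dict[tuple[float, float], OrientationSweepResult]:
    """Consecutive-orientation sweep for every threshold combination."""
    rng = np.random.default_rng(rng_seed)
    out = {}
    for v in variance_thresholds:
        for t in rank_thresholds:
            out[(v, t)] = consecutive_orientation_sweep(
                psths, variance_threshold=v, t=t, rng_seed=rng,
                n_chance_draws=n_chance_draws)
    return out
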
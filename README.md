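# popdim

Dimensionality and basis-pattern overlap of neural population activity and
visual stimuli.

## The scientific problem

When principal component analysis (PCA) is applied to trial-averaged
population activity (PSTHs) in a sensory area, two questions arise. First,
how many dimensions — *basis patterns*, orthonormal directions in the
population firing-rate space — does the activity occupy, and how does that
number track the complexity of the stimulus?  Second, do responses to
different stimuli occupy the *same* dimensions, or different ones?

`popdim` implements the analysis toolkit for both questions, aimed at
systems neuroscientists who record population activity (or who model it)
and want interpretable, seeded, end-to-end-reproducible dimensionality
comparisons:

- **PCA dimensionality** of a samples × features matrix: the minimal `k`
  with cumulative explained variance ≥ a threshold (90% by default). The
  matrix can hold PSTH time bins × neurons or movie frames × pixel blocks.
- **The pattern aggregation method**: given per-condition orthonormal
  pattern sets `U_A (N×k_A)`, `U_B (N×k_B)`, form `V = [U_A U_B]` and count
  singular values of `V` above a rank threshold `t` (default 0.5). The
  joint dimensionality `k_AB` is bracketed by `max(k_A,k_B)` (identical
  subspaces) and `k_A + k_B` (orthogonal subspaces). For two unit vectors
  at angle θ the singular values are `sqrt(1 ± cos θ)`, so `t = 0.5` puts
  the one-to-two–dimension transition at `arccos(1 − t²) ≈ 41.4°`.
- **Chance levels and the similarity index**: `k̂_AB` is the Monte-Carlo
  mean of `k_AB` for independently drawn random orthonormal sets in the
  ambient (or a constrained `M`-dimensional) space, and
  `s = (k̂_AB − k_AB) / (k_A + k_B − max(k_A, k_B))`,
  with `s > 0` meaning more subspace overlap than chance. Tail
  probabilities use an add-one permutation estimator.
- **Stimulus generators**: a 750-frame drifting-grating sequence movie
  (98 orientations, 1.3 cycles/degree, 6.25 Hz), a jittered white-noise
  movie (40×40 grid of 8×8-pixel squares), and a synthetic natural-movie
  surrogate (1/f² spatial spectrum, autoregressive frame correlation,
  global luminance drift), plus the standard pixel preprocessing
  (320×320 crop → 8×8 block means → 1600-dimensional frame vectors).
- **Parametric image manipulations**: per-image contrast scaling, Fourier
  phase randomization with bounded offsets, and power-spectrum flattening.
- **A four-stage V1 receptive-field model**: space-time Gabor filtering
  with rectification, untuned suppressive subtraction, divisive
  normalization, and a pointwise output nonlinearity.
- **Windowed analyses** (tiled and growing windows, window-pair similarity
  matrices, time shuffling, subsampled error bars), **orientation sweeps**,
  and a **correlation-dimension (fractal) estimator** as a nonlinear
  cross-check.

## Worked example

```python
import numpy as np
from popdim import (gratings_movie, noise_movie, preprocess_movie,
                    dimensionality, pca_patterns, compare_pattern_sets)

gratings = preprocess_movie(gratings_movie(rng_seed=1))   # 750 x 1600
noise = preprocess_movie(noise_movie(rng_seed=1))

print(dimensionality(gratings, 0.9))   # 30
print(dimensionality(noise, 0.9))      # 462

sets = [pca_patterns(gratings, 0.9), pca_patterns(noise, 0.9)]
res = compare_pattern_sets(sets, t=0.5, n_draws=100, rng_seed=0)
print(res.k_agg, round(res.chance.mean_chance, 1), round(res.s, 2))
# 480 492.0 0.4
```

The gratings movie needs far fewer dimensions than the noise movie: its
frames live near a ring of spatial-frequency components, while jittered
noise spreads variance over hundreds of directions.  Aggregating the two
pattern sets (30 + 462 = 492 columns) gives a joint dimensionality of 480,
below the chance level of 492 for random subspaces of these sizes in a
1600-dimensional pixel space: the noise movie's dimensions absorb a
sizable, above-chance fraction of the gratings movie's patterns
(s = 0.4, p ≈ 0.01 at 100 chance draws).

The same machinery runs from the shell:

```sh
popdim make-stimulus gratings --seed 1 --out gratings.h5
popdim preprocess --movie gratings.h5 --out gratings_mat.h5
popdim dims --input gratings_mat.h5 --variance 0.9
popdim chance --set-sizes 24,64 --ambient-dim 1600 --n-draws 100 --seed 0
```

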
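# Methods

This note documents the models and procedures implemented in `popdim`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## PCA dimensionality

A data matrix holds samples (movie frames or PSTH time bins) in rows and
features (pixel blocks or neurons) in columns.  Features are centered
exactly once; the per-feature means are recorded so the operation is
auditable, and every windowed analysis consumes slices of the *globally*
centered matrix without re-centering.  This keeps all window-level
dimensionality measurements in one reference frame: a window's apparent
dimensionality includes the direction of its own offset from the global
mean, which is deliberate — re-centering each window would make window
dimensionalities incomparable.

Dimensionality at variance threshold `v ∈ (0, 1]` is the minimal number of
leading principal axes whose cumulative variance fraction reaches `v`,
inclusive at exact equality (eigenvalues {9, 1} at `v = 0.9` give k = 1).
Variance fractions come from the singular values of the centered matrix;
singular values below 1e−12 of the leading one are treated as numerical
zeros.  The `1/(n−1)` vs `1/n` covariance normalization cancels in
fractions; `1/(n−1)` is used where absolute variances are reported.
Pattern signs are fixed by making each pattern's largest-magnitude
coefficient positive, so serialized outputs are reproducible across BLAS
implementations.

## Pattern aggregation

The joint dimensionality of several conditions is the *effective rank* of
the matrix that concatenates their orthonormal pattern sets: the number of
singular values strictly greater than the rank threshold `t ∈ (0, 1]`
(with an absolute floor of 1e−10 × the leading singular value so exact
duplicate columns never inflate the rank as `t → 0`).  The threshold is
applied to the raw singular values of the unit-column matrix.  This
semantics is the only one consistent with three anchor behaviors at once:
`t → 0` counts any deviation as a new dimension, `t → 1` requires
orthogonality, and `t = 0.5` places the two-vector transition at
`arccos(1 − t²) ≈ 41.4°` (a normalized σ₂/σ₁ rule would put it at 53.1°).

Chance levels draw, per Monte-Carlo repetition, one independent orthonormal
set per condition (QR of a standard-Gaussian matrix — rotation-invariant,
hence uniform on the subspace manifold) in the ambient space, or in a
constrained `M`-dimensional space when there is reason to believe the
population cannot express all of its nominal dimensions.  The two sets are
*not* jointly re-orthonormalized.  The default is 1000 draws (100 suffices
for means; p-values need more).

The similarity index `s = (chance − observed) / (Σk − max k)` generalizes
to more than two sets by reusing the two-set normalization with the
maximum over all sets; this multi-set form is an assumption of this
package.  The reported p-value is the add-one tail probability of the
observed joint dimensionality under the random-subspace null —
`p = (1 + #{null ≤ observed}) / (1 + n_draws)` for the overlap
alternative — so p is never exactly zero.

The *equalized* aggregation control answers whether joint dimensionality
grows with condition count merely because more columns are aggregated.
Every condition count aggregates the same total number of patterns: the
budget is the summed full-data pattern count over all conditions, and each
count fills it by cycling over its conditions, drawing patterns from fresh
random row-subsamples (fraction 0.5 by default).  At
`n_subsamples = 1, fraction = 1` the procedure reduces to plain
aggregation.  The precise bookkeeping here is this package's
interpretation; only the principle (equal column budgets via subsampled
pattern draws) is externally specified.

## Synthetic population activity

`simulate_psths` builds rates = offsets + patterns × latents + Gaussian
noise from a planted structure whose patterns are exactly orthonormal.
Default latents are standard-Gaussian series smoothed with a 3-bin moving
average, giving the temporal smoothness of real PSTHs without committing
to a dynamical model.  Planted data provide ground truth for every
downstream stage: noiseless simulations have known rank, shared vs
orthogonal planted subspaces have known joint dimensionality, and the
similarity index must recover ≈1 for shared and ≈0 for orthogonal planted
patterns when the ambient dimension dwarfs the subspaces.

What the generator does *not* emulate: Poisson spiking statistics (rates
are Gaussian around the planted signal), tuning-curve structure across
conditions, and any nonlinear manifold geometry.  Passing recovery tests
therefore demonstrates correctness of the estimators on linear planted
structure, not robustness to every property of cortical data.

## Stimulus generators

Geometry: 80 pixels per degree, frames at 25 Hz (40 ms), luminance on
[0, 1] with mean gray 0.5.  Absolute luminance and display gamma are
irrelevant to dimensionality (scale/offset invariance) and omitted.

**Gratings movie** — 98 orientations spaced 360/98 ≈ 3.67°, plus two blank
elements, in a seeded random order; each element is a full-contrast
drifting sinusoid (1.3 cycles/degree, 6.25 Hz, i.e. a quarter cycle per
frame) inside a 640-pixel circular aperture on mean gray.  300 ms at 25 Hz
is 7.5 frames, so element lengths alternate 8 and 7 via cumulative
rounding, totalling exactly 750 frames.  Each element starts at phase
zero; phase continuity across elements is not enforced (PCA over the frame
set is insensitive to it — verified during design).

**Noise movie** — per frame, a fresh (41×41) grid of independent uniform
intensities rendered as 8×8-pixel squares and cropped with an independent
1–8-pixel jitter per axis, so square borders move relative to the fixed
8×8 analysis blocks.  Jitter leaves adjacent block means positively
correlated — the movie is deliberately not perfect white noise after
preprocessing, and its eigenspectrum is correspondingly not flat.

**Natural-movie surrogate** — a stationary Gaussian process with 1/f²
spatial power (amplitude 1/f on the frequency grid), first-order
autoregressive Fourier coefficients across frames (`temporal_correlation`,
default 0.9 — high frame-to-frame similarity, as in film footage), and an
additive slow sinusoidal global-luminance drift (amplitude 0.1 relative to
an RMS contrast of 0.15) standing in for camera zooming/panning.  It is
labelled synthetic throughout: it reproduces the second-order statistics
of natural movies but, being Gaussian, has *no higher-order phase
structure* — no edges, contours or objects.  This matters for one analysis
(below).

**Preprocessing** — center-crop to 320×320, average fixed 8×8 blocks to
40×40, flatten to 1600-vectors, stack frames as rows, center features.

**Manipulations** — contrast: per image, deviations from that image's own
mean are scaled by level/100.  Phase randomization: per frame, independent
uniform offsets on [−α, α] are added to the phases of one DFT half-plane
with conjugate partners negated (frames stay real to machine precision);
self-conjugate frequencies, including DC, are untouched, so mean luminance
is exactly conserved.  Spectrum flattening: per image the power spectrum
is normalized by its sum λ, raised to the exponent `q`, and rescaled by λ,
phases kept; the DC term is excluded from the normalization and preserved,
since flattening it would destroy mean luminance (the operation's purpose
is to reshape the *spatial-frequency* falloff).

## Receptive-field model

Each of N model neurons applies, per frame t:

1. `L1 = Σ_m Σ_{x,y} G(x, y, m − t) I_m(x, y)` over the past T = 15
   frames, with `G` the unit-Frobenius-norm real part of a 3-d Gaussian
   envelope times a complex sinusoid; spatial coordinates are rotated by
   the preferred orientation θ and space-time coordinates further by the
   drift direction β ∈ {0, π}.  `R1 = max(0, L1)`.
2. `L2` = inner product of a difference of normalized 2-d Gaussians
   (σ₁ = 20, σ₂ = 30 px) at the RF center with the current frame;
   `R2 = R1 − max(0, ω L2)`.
3. `R3 = R2 / (σ_offset + mean_{j≠i} R1_j)` (divisive normalization; the
   denominator is bounded below by σ_offset > 0).
4. `R4 = max(0, R3)^q`.

Outputs for the first T − 1 frames are dropped, not zero-padded, to avoid
spurious onset dimensions.  The temporal frequency is fixed at 6.25 Hz
(0.25 cycles/frame at 25 Hz); `σ_t = 8d` with the direction-selectivity
constant `d ∈ [0, 1]`, and `d = 0` is implemented as the σ_t → 0 limit — a
single-frame temporal delta.  The spatial sum runs over the full frame.
RF centers are Gaussian with mean 160 px and *variance* 20 (sd ≈ 4.5 px;
the source convention could also be read as sd — taken literally here), so
the population's RFs overlap near the frame center; σ_x = 20 + |ε| with ε
standard normal.  The phase term enters the carrier as 2π(γ_s x′ + φ +
γ_t t′), exactly as specified by the model's defining equations, even
though this multiplies φ by 2π; φ is drawn on [0, 2π), so the extra factor
only relabels phases.

Parameters without a fixed published value are drawn from documented,
user-overridable defaults: aspect ratio c ~ lognormal(median 1.7,
log-sd 0.3); spatial frequency γ_s ~ lognormal(median 0.13 cycles/px,
log-sd 0.4); suppression weight ω ~ half-normal(sd 0.5); normalization
offset σ_offset ~ lognormal(median 0.1, log-sd 0.5); output exponent
q ~ U(1, 3); d ~ U(0, 1).  These are plausibility defaults: only *trends*
of model dimensionality across stimuli are meaningful, never absolute
values.  The location/scale entries (x_loc, y_loc, σ_x base) live in the
same config so the model runs on frames of any size in tests.

### Trend suite and a known limitation

On manipulated surrogate movies (200 frames, 96 px, 100 neurons — the
model population size of the original design, with frames and duration
scaled to the test budget) the final-stage (R4) dimensionality reliably
*decreases with contrast* and *increases with spectral flattening* across
seeds.  The third expected direction — dimensionality decreasing with the
phase-randomization extent α — does not emerge with this surrogate, and
cannot: for a stationary Gaussian field the Fourier phases are already
independent and uniform, so adding phase offsets preserves each frame's
spatial distribution exactly; the only systematic effect is the
destruction of frame-to-frame correlation, which *raises* the number of
distinct patterns in a record.  The phase-randomization effect in real
data rides on higher-order, phase-aligned structure (edges, textures) that
a Gaussian surrogate lacks by construction.  The corresponding test is
kept, documents this, and fails — an honest negative: exercising that
prediction requires imagery with genuine higher-order structure.

## Windowed analyses

Windows tile the record without overlap (1 s = 50 bins at 20 ms, or 25
frames at 40 ms); growing windows always start at the record start, so the
final unsmoothed value equals the whole-record dimensionality.  Smoothing
uses a Gaussian kernel (sd 1.5 s) truncated at 4 sd and renormalized over
its available support, so constant series pass through unchanged.  Error
bars are standard deviations over 100 random half subsamples of the
window's time bins (subsampling, not bootstrapping — resampling with
replacement biases dimensionality when samples are few relative to
features).  The time-shuffle control permutes rows globally and leaves
whole-record PCA exactly invariant while raising short-window
dimensionality for temporally smooth data.  Window-pair similarity indices
use chance draws at the matrix's ambient dimension, cached per pair of
set sizes; zero-variance windows yield missing entries excluded from the
off-diagonal mean.

## Orientation sweeps

Consecutive-orientation combinations wrap cyclically (all 12 starting
orientations contribute at every count m).  The angular-offset sweep
aggregates all orientation pairs at each offset; its 0° reference gathers
an equal number of patterns from repeated row-subsampled extractions of
the same condition, so comparing 0° against 180° is not confounded by
column count.  Chance curves redraw the observed per-condition pattern-set
sizes as random subspaces of the neuron space (ambient N = neuron count;
a constrained M is available through the aggregation API).

## Fractal (correlation) dimensionality

For each of 50 log-spaced radii between the 1st and 99th percentiles of
pairwise distances, the mean number of *other* points within the radius is
counted; the estimate is the least-squares slope of ln N(r) against
ln r restricted to a window on the log-neighbor axis — (6, 12) by default
for ~750-point pixel clouds, (4, 10) for smaller population-activity
clouds — excluding the sparse small-r and saturated large-r regimes.
Natural logarithms throughout; the slope is base-invariant and invariant
to isotropic rescaling of the cloud.  Neighbor counts are per-point means
(total pair counts would shift the intercept only).

## Numerical and degenerate-input policy

Zero-variance matrices, non-orthonormal planted patterns, non-unit
aggregated columns, subsamples below two rows, windows longer than the
record, and orthonormal draws exceeding the ambient dimension all raise
typed errors rather than returning silently wrong numbers.  Double
centering warns and is the identity.  All stochastic stages accept either
a seed or a live `numpy` Generator; the CLI derives per-stage generators
from one master seed via named substreams (CRC-32 of the stage label into
a `SeedSequence`), so partial pipeline reruns are reproducible.

## Problem sizes used in the shipped checks

The end-to-end checks regenerate the full 750-frame movies and analyze the
750 × 1600 pixel matrices directly; Monte-Carlo chance levels use 100
draws where only the mean is needed.  Model-based checks run on
96-px/200-frame surrogates with 100 neurons, and estimator checks on
planted clouds of up to 10⁴ points — sizes chosen so the whole suite runs
on a single CPU in minutes while keeping every estimate comfortably out of
its small-sample regime.

## Known limitations

- The gratings/noise generators reproduce printed protocol parameters, not
  the exact movie files shown in any particular experiment; quantities that
  depend on fine eigenvalue structure (e.g. the exact 90% crossing of the
  gratings movie) can differ from values measured on the original footage
  even when coarser statements (the near-100% plateau, orderings between
  stimuli, overlap structure) agree.
- The natural surrogate is Gaussian; see the trend-suite limitation above.
- Dimensionality values are meaningful only relatively, at fixed variance
  and rank thresholds, neuron counts and record lengths; the package
  deliberately reports no "absolute" dimensionality.
- PCA is linear; the correlation-dimension estimator is provided as a
  nonlinear cross-check of orderings, not as a manifold-learning method.
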
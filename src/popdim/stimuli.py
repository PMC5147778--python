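"""Procedural visual stimuli: drifting-grating and jittered-noise movies,
a natural-movie surrogate, pixel preprocessing, and parametric image
manipulations (contrast scaling, phase randomization, spectral flattening).

Geometry conventions: 80 pixels per degree of visual angle (a 320 x 320
frame subtends 4 degrees), luminance in arbitrary units on [0, 1] with mean
gray 0.5, frames at an effective rate of 25 Hz (40 ms per frame).
Orientation is the drift-direction angle in degrees, counterclockwise from
the horizontal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, center_features
from .errors import DegenerateDataError, InvalidInputError

PIXELS_PER_DEGREE = 80.0
FRAME_RATE_HZ = 25.0
FRAME_DURATION_MS = 1000.0 / FRAME_RATE_HZ
MEAN_LUMINANCE = 0.5
CROP_SIZE = 320
BLOCK_SIZE = 8


@dataclass
class MovieStimulus:
    """Grayscale frame stack with its frame duration."""

    frames: np.ndarray             # (n_frames, height, width)
    frame_duration_ms: float = FRAME_DURATION_MS

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidInputError("frames must be (frame, height, width)")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("frames must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class GratingSpec:
    """Drifting sinusoidal grating protocol parameters.

    Defaults describe the movie protocol: 98 orientations equally spaced
    over 360 degrees plus two blank elements, 300 ms per element at 25 Hz,
    full contrast, 1.3 cycles/degree, 6.25 Hz drift, 640-pixel circular
    aperture on a mean-gray surround.
    """

    n_orientations: int = 98
    spatial_freq_cpd: float = 1.3
    temporal_freq_hz: float = 6.25
    aperture_diameter_px: int = 640
    field_size_px: int = 640
    element_duration_ms: float = 300.0
    stimulus_duration_ms: float = 1280.0   # individual-grating trials
    contrast: float = 1.0
    n_blanks: int = 2

    @property
    def orientation_step_deg(self) -> float:
        return 360.0 / self.n_orientations


@dataclass
class NoiseSpec:
    """Jittered white-noise protocol: a grid of uniform-intensity squares,
    shifted by an integer jitter each frame to avoid static grid effects."""

    grid_squares: int = 40
    square_size_px: int = BLOCK_SIZE
    jitter_min_px: int = 1
    jitter_max_px: int = 8
    n_frames: int = 750

    @property
    def frame_size_px(self) -> int:
        return self.grid_squares * self.square_size_px


def _grating_frames(orientation_deg: float, n_frames: int, spec: GratingSpec,
                    size: int, start_phase: float = 0.0) -> np.ndarray:
    """Frames of one drifting sinusoid within a circular aperture."""
    f_cpp = spec.spatial_freq_cpd / PIXELS_PER_DEGREE
    cycles_per_frame = spec.temporal_freq_hz / FRAME_RATE_HZ
    y, x = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    th = np.deg2rad(orientation_deg)
    spatial = 2 * np.pi * f_cpp * ((x - c) * np.cos(th) + (y - c) * np.sin(th))
    phases = start_phase + 2 * np.pi * cycles_per_frame * np.arange(n_frames)
    frames = MEAN_LUMINANCE + (0.5 * spec.contrast) * np.cos(
        spatial[None, :, :] - phases[:, None, None])
    r2 = (x - c) ** 2 + (y - c) ** 2
    outside = r2 > (spec.aperture_diameter_px / 2.0) ** 2
    frames[:, outside] = MEAN_LUMINANCE
    return frames


def _element_lengths(n_elements: int, frames_per_element: float) -> np.ndarray:
    """Integer frame counts per element whose total matches exactly.

    Cumulative rounding: 300 ms at 25 Hz is 7.5 frames, giving alternating
    8- and 7-frame elements and 100 elements in exactly 750 frames.
    """
    edges = np.floor(np.arange(n_elements + 1) * frames_per_element + 0.5)
    return np.diff(edges).astype(int)


def gratings_movie(spec: GratingSpec | None = None,
                   rng_seed: int | np.random.Generator | None = None,
                   ) -> MovieStimulus:
    """Pseudo-random sequence of drifting gratings plus blank elements.

    98 orientations and 2 blanks, 300 ms each, total 750 frames at 25 Hz.
    Each element starts at spatial phase zero; drift advances the phase by
    temporal_freq / frame_rate cycles per frame.
    """
    spec = spec or GratingSpec()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    orientations: list[float | None] = [i * spec.orientation_step_deg
                                        for i in range(spec.n_orientations)]
    orientations += [None] * spec.n_blanks
    order = rng.permutation(len(orientations))
    n_elements = len(orientations)
    fpe = spec.element_duration_ms / FRAME_DURATION_MS
    lens = _element_lengths(n_elements, fpe)
    size = spec.field_size_px
    chunks = []
    for idx, n_f in zip(order, lens):
        ori = orientations[idx]
        if ori is None:
            chunks.append(np.full((n_f, size, size), MEAN_LUMINANCE))
        else:
            chunks.append(_grating_frames(ori, n_f, spec, size))
    return MovieStimulus(frames=np.concatenate(chunks, axis=0))


def noise_movie(spec: NoiseSpec | None = None,
                rng_seed: int | np.random.Generator | None = None,
                ) -> MovieStimulus:
    """Jittered white noise: independent uniform square intensities each
    frame, with the square grid shifted by 1-8 pixels per frame and axis."""
    spec = spec or NoiseSpec()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    size = spec.frame_size_px
    g, b = spec.grid_squares, spec.square_size_px
    frames = np.empty((spec.n_frames, size, size))
    for i in range(spec.n_frames):
        # one extra row/column of squares so the shifted grid covers the frame
        grid = rng.uniform(0.0, 1.0, size=(g + 1, g + 1))
        big = np.kron(grid, np.ones((b, b)))
        dy = int(rng.integers(spec.jitter_min_px, spec.jitter_max_px + 1))
        dx = int(rng.integers(spec.jitter_min_px, spec.jitter_max_px + 1))
        frames[i] = big[dy:dy + size, dx:dx + size]
    return MovieStimulus(frames=frames)


def natural_surrogate(n_frames: int = 750, size: int = CROP_SIZE,
                      temporal_correlation: float = 0.9,
                      luminance_drift_amplitude: float = 0.1,
                      rng_seed: int | np.random.Generator | None = None,
                      ) -> MovieStimulus:
    """Synthetic stand-in for a natural film.

    Emulates three statistics of natural movies: a 1/f^2 spatial power
    spectrum, frame-to-frame self-similarity (first-order autoregressive
    Fourier coefficients with coefficient ``temporal_correlation``), and a
    slow global-luminance drift such as camera zooming/panning produces.
    It is synthetic: it has none of the object structure of real scenes.
    """
    if n_frames <= 0 or size <= 0:
        raise InvalidInputError("n_frames and size must be positive")
    if not 0.0 <= temporal_correlation <= 1.0:
        raise InvalidInputError("temporal_correlation must be in [0, 1]")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nonzero = f > 0
    amp[nonzero] = 1.0 / f[nonzero]          # amplitude 1/f -> power 1/f^2
    rho = temporal_correlation

    def draw() -> np.ndarray:
        return (rng.standard_normal(f.shape)
                + 1j * rng.standard_normal(f.shape))

    z = draw()
    innov = np.sqrt(max(1.0 - rho ** 2, 0.0))
    # slow luminance drift: random phase sinusoid over the movie
    t = np.arange(n_frames)
    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = luminance_drift_amplitude * np.sin(
        2 * np.pi * t / max(n_frames, 2) + drift_phase)
    frames = np.empty((n_frames, size, size))
    scale = None
    for i in range(n_frames):
        img = np.fft.irfft2(amp * z, s=(size, size))
        if scale is None:
            # fix RMS contrast of the first frame at ~0.15 and keep the
            # scale for the whole movie (stationary process)
            scale = 0.15 / max(img.std(), 1e-12)
        frames[i] = MEAN_LUMINANCE + scale * img + drift[i]
        if rho < 1.0:
            z = rho * z + innov * draw()
    return MovieStimulus(frames=frames)


def individual_grating_trials(spec: GratingSpec | None = None,
                              n_orientations: int = 12,
                              field_size_px: int = CROP_SIZE,
                              ) -> list[MovieStimulus]:
    """One drifting-grating movie per orientation (30 degrees apart).

    Orientations i and i+6 share a spatial pattern and differ only in drift
    direction.  Each movie lasts the spec's stimulus duration (1.28 s); the
    conventional analysis window is the first second.
    """
    spec = spec or GratingSpec(aperture_diameter_px=2 * field_size_px)
    n_frames = int(round(spec.stimulus_duration_ms / FRAME_DURATION_MS))
    step = 360.0 / n_orientations
    return [MovieStimulus(frames=_grating_frames(i * step, n_frames, spec,
                                                 field_size_px))
            for i in range(n_orientations)]


def preprocess_movie(movie: MovieStimulus,
                     crop_size: int = CROP_SIZE,
                     block_size: int = BLOCK_SIZE) -> DataMatrix:
    """Center-crop, block-average, flatten, and center the frame stack.

    Frames are cropped to ``crop_size`` squared, averaged over fixed
    ``block_size`` squared pixel blocks, flattened to vectors (frames as
    samples), and feature-centered: the standard pixel pipeline producing
    750 x 1600 matrices from 320 x 320 movies.
    """
    n, h, w = movie.frames.shape
    if h < crop_size or w < crop_size:
        raise InvalidInputError(
            f"frames {h}x{w} smaller than crop size {crop_size}")
    y0 = (h - crop_size) // 2
    x0 = (w - crop_size) // 2
    cropped = movie.frames[:, y0:y0 + crop_size, x0:x0 + crop_size]
    nb = crop_size // block_size
    blocks = cropped.reshape(n, nb, block_size, nb, block_size).mean(axis=(2, 4))
    flat = blocks.reshape(n, nb * nb)
    m = DataMatrix(values=flat, centered=False, provenance="movie pixels")
    return center_features(m)


def adjust_contrast(movie: MovieStimulus, level: float) -> MovieStimulus:
    """Scale each frame's deviations from its own mean by level/100."""
    if level < 0:
        raise InvalidInputError("contrast level must be >= 0")
    means = movie.frames.mean(axis=(1, 2), keepdims=True)
    frames = means + (level / 100.0) * (movie.frames - means)
    return MovieStimulus(frames=frames,
                         frame_duration_ms=movie.frame_duration_ms)


def _conjugate_partner_mask(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical half-plane and self-conjugate masks of an h x w DFT grid."""
    iy, ix = np.mgrid[0:h, 0:w]
    py, px = (-iy) % h, (-ix) % w
    self_conj = (py == iy) & (px == ix)
    canonical = (iy < py) | ((iy == py) & (ix < px))
    return canonical, self_conj


def randomize_phases(movie: MovieStimulus, alpha_deg: float,
                     rng_seed: int | np.random.Generator | None = None,
                     ) -> MovieStimulus:
    """Add independent uniform offsets on [-alpha, alpha] to each frame's
    Fourier phases, keeping magnitudes (and hence power spectra) intact.

    Offsets are drawn for one half-plane; conjugate-symmetric partners get
    the negated offset so frames stay real.  Self-conjugate frequencies
    (DC and Nyquist combinations) are left untouched, preserving the mean
    luminance exactly.  alpha = 180 degrees turns natural-statistics images
    into pink noise.
    """
    if not 0.0 <= alpha_deg <= 180.0:
        raise InvalidInputError("alpha must be in [0, 180] degrees")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n, h, w = movie.frames.shape
    canonical, self_conj = _conjugate_partner_mask(h, w)
    alpha = np.deg2rad(alpha_deg)
    iy, ix = np.mgrid[0:h, 0:w]
    py, px = (-iy) % h, (-ix) % w
    out = np.empty_like(movie.frames)
    for i in range(n):
        F = np.fft.fft2(movie.frames[i])
        offsets = np.zeros((h, w))
        draws = rng.uniform(-alpha, alpha, size=(h, w))
        offsets[canonical] = draws[canonical]
        offsets[py[canonical], px[canonical]] = -draws[canonical]
        offsets[self_conj] = 0.0
        out[i] = np.fft.ifft2(F * np.exp(1j * offsets)).real
    return MovieStimulus(frames=out,
                         frame_duration_ms=movie.frame_duration_ms)


def flatten_spectrum(movie: MovieStimulus, exponent: float) -> MovieStimulus:
    """Raise each frame's normalized power spectrum to ``exponent``.

    Per image: power spectrum P -> lambda * (P / lambda)^q where lambda is
    the sum of the (non-DC) power values, phases preserved.  q = 1 is the
    identity; q = 0 flattens a pink-noise spectrum to white.  The DC
    component is preserved so mean luminance is unchanged.
    """
    if not 0.0 <= exponent <= 1.0:
        raise InvalidInputError("spectrum exponent must be in [0, 1]")
    n, h, w = movie.frames.shape
    out = np.empty_like(movie.frames)
    for i in range(n):
        F = np.fft.fft2(movie.frames[i])
        P = np.abs(F) ** 2
        dc = P[0, 0]
        P[0, 0] = 0.0
        lam = P.sum()
        if lam <= 0 and exponent < 1.0:
            raise DegenerateDataError(
                "zero-power image cannot be spectrally flattened")
        newP = np.zeros_like(P)
        if lam > 0:
            # q = 0 flattens every non-DC bin to lambda (x**0 == 1)
            newP = lam * (P / lam) ** exponent
        newP[0, 0] = dc
        phases = np.angle(F)
        out[i] = np.fft.ifft2(np.sqrt(newP) * np.exp(1j * phases)).real
    return MovieStimulus(frames=out,
                         frame_duration_ms=movie.frame_duration_ms)


def radial_power_slope(frames: np.ndarray,
                       f_lo: float = 0.01, f_hi: float = 0.25) -> float:
    """Log-log slope of the radially averaged spatial power spectrum.

    Diagnostic used to verify 1/f^q constructions; fits log power against
    log frequency between ``f_lo`` and ``f_hi`` (cycles/pixel).
    """
    n, h, w = frames.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx).ravel()
    P = np.zeros(h * w)
    for i in range(n):
        P += (np.abs(np.fft.fft2(frames[i])) ** 2).ravel()
    sel = (f >= f_lo) & (f <= f_hi) & (P > 0)
    logf = np.log(f[sel])
    logp = np.log(P[sel])
    slope = np.polyfit(logf, logp, 1)[0]
    return float(slope)
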
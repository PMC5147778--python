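"""Four-stage V1 receptive-field model.

Each model neuron transforms a grayscale movie through a cascade of
components common to many V1 models:

1. a space-time (3-d) Gabor filter, half-rectified;
2. subtraction of a rectified untuned suppressive drive (difference of
   2-d Gaussians at the neuron's receptive-field center);
3. divisive normalization by the mean rectified Gabor drive of the other
   model neurons plus an offset;
4. a pointwise output nonlinearity max(0, x)^q.

The Gabor is the real part of a Gaussian envelope times a complex
sinusoid, with spatial coordinates rotated by the preferred orientation
theta and the space-time coordinates further rotated by the drift-direction
angle beta (0 or pi), and is normalized to unit Frobenius norm.  The filter
spans the past T frames; outputs for the first T-1 frames are undefined and
dropped, not zero-padded, to avoid spurious onset dimensions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InvalidInputError
from .stimuli import FRAME_RATE_HZ, MovieStimulus

#: Default sampling distributions for the per-neuron parameters that have
#: no fixed value.  Locations/scales are in pixels of a 320 x 320 frame;
#: all entries may be overridden through ``distribution_config``.
DEFAULT_DISTRIBUTIONS: dict[str, dict] = {
    "x_loc": {"mean": 160.0, "var": 20.0},        # Gaussian, variance 20
    "y_loc": {"mean": 160.0, "var": 20.0},
    "sigma_x_base": 20.0,                          # sigma_x = base + |N(0,1)|
    "aspect_ratio": {"log_median": np.log(1.7), "log_sd": 0.3},
    "spatial_freq": {"log_median": np.log(0.13), "log_sd": 0.4},  # cycles/px
    "omega": {"half_normal_sd": 0.5},              # suppression weight
    "sigma_offset": {"log_median": np.log(0.1), "log_sd": 0.5},
    "q": {"low": 1.0, "high": 3.0},                # output exponent
    "d": {"low": 0.0, "high": 1.0},                # direction selectivity
}

TEMPORAL_SUPPORT = 15           # frames
TEMPORAL_FREQ_HZ = 6.25         # matched to the drifting gratings
SIGMA_UNTUNED_1 = 20.0
SIGMA_UNTUNED_2 = 30.0


@dataclass
class NeuronParams:
    """Parameters of one model neuron (pixels, radians, frames)."""

    x_loc: float
    y_loc: float
    phase: float                  # spatial phase phi, radians
    theta: float                  # orientation, radians
    beta: float                   # drift direction, 0 or pi
    sigma_x: float
    sigma_y: float
    sigma_t: float                # frames; 8*d
    spatial_freq: float           # cycles/pixel
    temporal_freq_hz: float = TEMPORAL_FREQ_HZ
    d: float = 0.5
    omega: float = 0.0
    sigma_offset: float = 0.1
    q: float = 2.0
    sigma_1: float = SIGMA_UNTUNED_1
    sigma_2: float = SIGMA_UNTUNED_2
    T: int = TEMPORAL_SUPPORT

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise InvalidInputError("spatial envelope scales must be positive")
        if self.sigma_t < 0:
            raise InvalidInputError("temporal envelope scale must be >= 0")
        if self.q <= 0 or self.sigma_offset <= 0:
            raise InvalidInputError("q and sigma_offset must be positive")
        if self.beta not in (0.0, np.pi):
            raise InvalidInputError("beta must be 0 or pi")


@dataclass
class GaborFilter:
    """Space-time filter weights with unit Frobenius norm."""

    weights: np.ndarray           # (T, height, width), index 0 = oldest
    norm: float                   # Frobenius norm before normalization


@dataclass
class ModelResponse:
    """Responses of all neurons at the four model stages."""

    R1: np.ndarray                # (n_neurons, n_valid_frames), >= 0
    R2: np.ndarray
    R3: np.ndarray
    R4: np.ndarray                # >= 0
    L1: np.ndarray
    L2: np.ndarray
    first_valid_frame: int = field(default=TEMPORAL_SUPPORT - 1)


def sample_params(n_neurons: int,
                  rng_seed: int | np.random.Generator | None = None,
                  distribution_config: dict | None = None,
                  ) -> list[NeuronParams]:
    """Draw biologically plausible parameters for a model population."""
    if n_neurons < 2:
        raise InvalidInputError("normalization needs at least 2 neurons")
    cfg = dict(DEFAULT_DISTRIBUTIONS)
    if distribution_config:
        cfg.update(distribution_config)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    out = []
    for _ in range(n_neurons):
        x = rng.normal(cfg["x_loc"]["mean"], np.sqrt(cfg["x_loc"]["var"]))
        y = rng.normal(cfg["y_loc"]["mean"], np.sqrt(cfg["y_loc"]["var"]))
        phi = rng.uniform(0, 2 * np.pi)
        theta = rng.uniform(0, np.pi)
        beta = float(rng.choice([0.0, np.pi]))
        sigma_x = cfg["sigma_x_base"] + abs(rng.standard_normal())
        c = np.exp(rng.normal(cfg["aspect_ratio"]["log_median"],
                              cfg["aspect_ratio"]["log_sd"]))
        gs = np.exp(rng.normal(cfg["spatial_freq"]["log_median"],
                               cfg["spatial_freq"]["log_sd"]))
        omega = abs(rng.normal(0.0, cfg["omega"]["half_normal_sd"]))
        s_off = np.exp(rng.normal(cfg["sigma_offset"]["log_median"],
                                  cfg["sigma_offset"]["log_sd"]))
        q = rng.uniform(cfg["q"]["low"], cfg["q"]["high"])
        d = rng.uniform(cfg["d"]["low"], cfg["d"]["high"])
        out.append(NeuronParams(x_loc=x, y_loc=y, phase=phi, theta=theta,
                                beta=beta, sigma_x=sigma_x, sigma_y=c * sigma_x,
                                sigma_t=8.0 * d, spatial_freq=gs, d=d,
                                omega=omega, sigma_offset=s_off, q=q))
    return out


def build_gabor(params: NeuronParams, spatial_shape: tuple[int, int],
                T: int | None = None,
                frame_rate_hz: float = FRAME_RATE_HZ) -> GaborFilter:
    """Evaluate the oriented space-time Gabor on the frame grid.

    Temporal index runs over the past T frames, t = -(T-1) ... 0 relative
    to the current frame.  ``sigma_t = 0`` (a non-direction-selective
    neuron) is the temporal-delta limit: the envelope collapses onto the
    current frame.
    """
    T = T or params.T
    h, w = spatial_shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    t = np.arange(-(T - 1), 1, dtype=float)        # oldest ... current
    dx = x - params.x_loc
    dy = y - params.y_loc

    ct, st = np.cos(params.theta), np.sin(params.theta)
    cb, sb = np.cos(params.beta), np.sin(params.beta)

    def rotate(u, v, s):
        """Apply R = R_beta(v,s plane) @ R_theta(u,v plane)."""
        u1 = ct * u - st * v
        v1 = st * u + ct * v
        v2 = cb * v1 - sb * s
        s2 = sb * v1 + cb * s
        return u1, v2, s2

    # broadcast space (h, w) against time (T,) -> (T, h, w)
    dxb = dx[None, :, :]
    dyb = dy[None, :, :]
    tb = t[:, None, None]

    xp, yp, tp = rotate(dxb, dyb, tb)

    if params.sigma_t == 0:
        xs, ys, _ = rotate(dxb / params.sigma_x, dyb / params.sigma_y,
                           np.zeros_like(tb))
        envelope = np.exp(-0.5 * (xs ** 2 + ys ** 2))
        envelope = envelope * (tb == 0)
    else:
        xs, ys, ts = rotate(dxb / params.sigma_x, dyb / params.sigma_y,
                            tb / params.sigma_t)
        envelope = np.exp(-0.5 * (xs ** 2 + ys ** 2 + ts ** 2))

    gamma_t = params.temporal_freq_hz / frame_rate_hz   # cycles/frame
    carrier = np.exp(-2j * np.pi * (params.spatial_freq * xp + params.phase
                                    + gamma_t * tp))
    g = (envelope * carrier).real
    norm = float(np.linalg.norm(g))
    if norm == 0:
        raise DegenerateFilter(params)
    return GaborFilter(weights=g / norm, norm=norm)


class DegenerateFilter(DegenerateDataError):
    def __init__(self, params: NeuronParams):
        super().__init__("Gabor filter has zero norm on this support")


def component1(movie: MovieStimulus, filt: GaborFilter,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Rectified space-time filtering: L1 and R1 = max(0, L1).

    Outputs cover frames T-1 ... end (the first T-1 are dropped).
    """
    T = filt.weights.shape[0]
    F = movie.n_frames
    if F < T:
        raise InvalidInputError(f"movie of {F} frames shorter than filter {T}")
    flat_movie = movie.frames.reshape(F, -1)
    flat_g = filt.weights.reshape(T, -1)
    # projection of every frame on every temporal slice of the filter
    proj = flat_movie @ flat_g.T                   # (F, T)
    n_valid = F - T + 1
    L1 = np.zeros(n_valid)
    for j in range(T):
        # slice j (offset j - (T-1) relative to current frame)
        L1 += proj[j:j + n_valid, j]
    R1 = np.maximum(0.0, L1)
    return L1, R1


def untuned_filter(params: NeuronParams,
                   spatial_shape: tuple[int, int]) -> np.ndarray:
    """Difference of normalized 2-d Gaussians at the RF center."""
    h, w = spatial_shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    d2 = (x - params.x_loc) ** 2 + (y - params.y_loc) ** 2

    def gauss(sigma: float) -> np.ndarray:
        return np.exp(-0.5 * d2 / sigma ** 2) / (2 * np.pi * sigma ** 2)

    return gauss(params.sigma_1) - gauss(params.sigma_2)


def component2(R1: np.ndarray, movie: MovieStimulus, params: NeuronParams,
               first_valid_frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the rectified untuned suppressive drive.

    L2 is the inner product of the difference-of-Gaussians filter with the
    current frame; R2 = R1 - max(0, omega * L2).
    """
    g = untuned_filter(params, movie.frames.shape[1:])
    frames = movie.frames[first_valid_frame:]
    L2 = frames.reshape(frames.shape[0], -1) @ g.ravel()
    S2 = np.maximum(0.0, params.omega * L2)
    return L2, R1 - S2


def component3(R2_all: np.ndarray, R1_all: np.ndarray,
               sigma_offsets: np.ndarray) -> np.ndarray:
    """Divisive normalization by the other neurons' mean rectified drive."""
    n = R1_all.shape[0]
    if n < 2:
        raise InvalidInputError("divisive normalization needs >= 2 neurons")
    total = R1_all.sum(axis=0, keepdims=True)
    mean_others = (total - R1_all) / (n - 1)
    return R2_all / (np.asarray(sigma_offsets)[:, None] + mean_others)


def component4(R3: np.ndarray, q: np.ndarray | float) -> np.ndarray:
    """Pointwise output nonlinearity max(0, x)^q."""
    q = np.asarray(q)
    if np.any(q <= 0):
        raise InvalidInputError("exponent q must be positive")
    qcol = q[:, None] if q.ndim == 1 else q
    return np.maximum(0.0, R3) ** qcol


def run_model(movie: MovieStimulus, params_list: list[NeuronParams],
              ) -> ModelResponse:
    """Run the full cascade for a population of model neurons."""
    if len(params_list) < 2:
        raise InvalidInputError("need at least 2 neurons")
    T = params_list[0].T
    shape = movie.frames.shape[1:]
    n_valid = movie.n_frames - T + 1
    if n_valid < 1:
        raise InvalidInputError("movie shorter than the temporal support")
    n = len(params_list)
    L1 = np.empty((n, n_valid))
    R1 = np.empty((n, n_valid))
    L2 = np.empty((n, n_valid))
    R2 = np.empty((n, n_valid))
    for i, p in enumerate(params_list):
        filt = build_gabor(p, shape, T=T,
                           frame_rate_hz=1000.0 / movie.frame_duration_ms)
        L1[i], R1[i] = component1(movie, filt)
        L2[i], R2[i] = component2(R1[i], movie, p, first_valid_frame=T - 1)
    R3 = component3(R2, R1, np.array([p.sigma_offset for p in params_list]))
    R4 = component4(R3, np.array([p.q for p in params_list]))
    return ModelResponse(R1=R1, R2=R2, R3=R3, R4=R4, L1=L1, L2=L2,
                         first_valid_frame=T - 1)


def response_matrix(responses: np.ndarray, provenance: str = "rf model"):
    """Wrap a (neuron x time) stage output as a centered DataMatrix."""
    from .core import DataMatrix, center_features
    m = DataMatrix(values=np.asarray(responses).T, centered=False,
                   provenance=provenance)
    return center_features(m)
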
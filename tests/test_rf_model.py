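"""Receptive-field model components against closed forms and a fully
independent straight-line reimplementation."""

import numpy as np
import pytest

from popdim.errors import InvalidInputError
from popdim.rf_model import (NeuronParams, build_gabor, component1,
                             component2, component3, component4,
                             response_matrix, run_model, sample_params)
from popdim.stimuli import MovieStimulus

SMALL_CFG = {"x_loc": {"mean": 32.0, "var": 20.0},
             "y_loc": {"mean": 32.0, "var": 20.0},
             "sigma_x_base": 8.0}


def mk_params(**kw):
    base = dict(x_loc=16.0, y_loc=16.0, phase=0.3, theta=0.7, beta=0.0,
                sigma_x=5.0, sigma_y=7.0, sigma_t=4.0, spatial_freq=0.1,
                omega=0.5, sigma_offset=0.2, q=2.0, sigma_1=4.0, sigma_2=6.0,
                T=15)
    base.update(kw)
    return NeuronParams(**base)


class TestSampleParams:
    def test_deterministic_given_seed(self):
        a = sample_params(5, rng_seed=3)
        b = sample_params(5, rng_seed=3)
        assert all(vars(x) == vars(y) for x, y in zip(a, b))

    def test_location_distribution(self):
        ps = sample_params(1000, rng_seed=0)
        xs = np.array([p.x_loc for p in ps])
        se = np.sqrt(20.0 / 1000)
        assert abs(xs.mean() - 160.0) < 4 * se

    def test_direction_angles_binary(self):
        ps = sample_params(200, rng_seed=1)
        assert set(p.beta for p in ps) <= {0.0, np.pi}
        assert all(p.sigma_t == 8.0 * p.d for p in ps)

    def test_single_neuron_rejected(self):
        with pytest.raises(InvalidInputError):
            sample_params(1)


class TestBuildGabor:
    def test_unit_frobenius_norm(self):
        g = build_gabor(mk_params(), (32, 32))
        assert np.linalg.norm(g.weights) == pytest.approx(1.0, abs=1e-9)

    def test_opposite_drift_reverses_temporal_frequency(self):
        """At theta = 0 the beta = pi rotation negates the temporal
        carrier: the filter equals the beta = 0 filter built with the
        temporal frequency sign-flipped (verified against direct
        evaluation of the rotation algebra)."""
        flipped = build_gabor(mk_params(beta=np.pi, theta=0.0), (33, 33))
        negated = build_gabor(mk_params(beta=0.0, theta=0.0,
                                        temporal_freq_hz=-6.25), (33, 33))
        assert np.allclose(flipped.weights, negated.weights, atol=1e-9)
        forward = build_gabor(mk_params(beta=0.0, theta=0.0), (33, 33))
        assert not np.allclose(flipped.weights, forward.weights, atol=1e-3)

    def test_nonselective_neuron_is_temporally_punctate(self):
        g = build_gabor(mk_params(sigma_t=0.0), (32, 32))
        assert np.allclose(g.weights[:-1], 0.0)
        assert np.linalg.norm(g.weights[-1]) == pytest.approx(1.0)


class TestComponent1:
    def test_zero_movie_zero_response(self):
        movie = MovieStimulus(frames=np.zeros((20, 32, 32)))
        g = build_gabor(mk_params(), (32, 32))
        L1, R1 = component1(movie, g)
        assert np.allclose(L1, 0.0) and np.allclose(R1, 0.0)

    def test_matched_template_peaks_at_one(self):
        g = build_gabor(mk_params(), (32, 32))
        # replay the filter itself: oldest slice first, current slice last
        movie = MovieStimulus(frames=g.weights.copy())
        L1, _ = component1(movie, g)
        assert L1[-1] == pytest.approx(1.0, abs=1e-9)

    def test_orientation_selectivity(self):
        p = mk_params(theta=0.0, sigma_t=2.0, x_loc=16, y_loc=16)
        g = build_gabor(p, (32, 32))
        y, x = np.mgrid[0:32, 0:32].astype(float)

        def grating_movie(theta):
            frames = []
            for t in range(40):
                sp = 2 * np.pi * p.spatial_freq * (
                    (x - 16) * np.cos(theta) + (y - 16) * np.sin(theta))
                frames.append(np.cos(sp - 2 * np.pi * 0.25 * t))
            return MovieStimulus(frames=np.array(frames))

        _, r_pref = component1(grating_movie(0.0), g)
        _, r_orth = component1(grating_movie(np.pi / 2), g)
        assert r_pref.mean() > r_orth.mean()

    def test_short_movie_rejected(self):
        g = build_gabor(mk_params(), (16, 16))
        with pytest.raises(InvalidInputError):
            component1(MovieStimulus(frames=np.zeros((5, 16, 16))), g)

    def test_contrast_scaling_never_decreases_r1(self, rng):
        movie = MovieStimulus(frames=rng.standard_normal((25, 24, 24)))
        double = MovieStimulus(frames=2.0 * movie.frames)
        g = build_gabor(mk_params(x_loc=12, y_loc=12, sigma_x=4, sigma_y=4),
                        (24, 24))
        _, r1 = component1(movie, g)
        _, r2 = component1(double, g)
        assert np.all(r2 >= r1 - 1e-12)


class TestComponent2:
    def test_constant_frame_barely_suppresses(self):
        p = mk_params(x_loc=40, y_loc=40, sigma_1=4.0, sigma_2=6.0)
        movie = MovieStimulus(frames=np.full((20, 80, 80), 0.6))
        R1 = np.ones(6)
        L2, R2 = component2(R1, movie, p, first_valid_frame=14)
        # both Gaussians integrate to ~1 on this support, so L2 ~ 0
        assert np.all(np.abs(L2) < 1e-6)
        assert np.allclose(R2, R1, atol=1e-6)

    def test_zero_weight_identity(self, rng):
        p = mk_params(omega=0.0)
        movie = MovieStimulus(frames=rng.standard_normal((20, 32, 32)))
        R1 = rng.uniform(0, 1, 6)
        _, R2 = component2(R1, movie, p, first_valid_frame=14)
        assert np.array_equal(R2, R1)

    def test_center_surround_suppression(self):
        p = mk_params(x_loc=40, y_loc=40, omega=1.0, sigma_1=4.0, sigma_2=8.0)
        frames = np.zeros((15, 80, 80))
        y, x = np.mgrid[0:80, 0:80]
        center = (x - 40) ** 2 + (y - 40) ** 2 < 6 ** 2
        frames[:, center] = 1.0          # bright center, dark surround
        movie = MovieStimulus(frames=frames)
        R1 = np.ones(1)
        L2, R2 = component2(R1, movie, p, first_valid_frame=14)
        assert L2[0] > 0
        assert R2[0] < R1[0]


class TestComponents34:
    def test_direct_substitution(self):
        R2 = np.array([[4.0], [0.0]])
        R1 = np.array([[4.0], [2.0]])
        R3 = component3(R2, R1, np.array([1.0, 1.0]))
        assert np.allclose(R3, [[4.0 / 3.0], [0.0]])

    def test_silent_population_divides_by_offset(self):
        R2 = np.array([[2.0, 1.0], [3.0, 0.5]])
        R1 = np.zeros((2, 2))
        R3 = component3(R2, R1, np.array([0.5, 0.25]))
        assert np.allclose(R3, R2 / np.array([[0.5], [0.25]]))

    def test_matches_loop_evaluation(self, rng):
        n, T = 5, 7
        R1 = rng.uniform(0, 2, (n, T))
        R2 = rng.normal(0, 1, (n, T))
        offsets = rng.uniform(0.1, 1.0, n)
        R3 = component3(R2, R1, offsets)
        for i in range(n):
            for t in range(T):
                denom = offsets[i] + np.mean([R1[j, t] for j in range(n)
                                              if j != i])
                assert R3[i, t] == pytest.approx(R2[i, t] / denom, rel=1e-12)

    def test_single_neuron_rejected(self):
        with pytest.raises(InvalidInputError):
            component3(np.ones((1, 3)), np.ones((1, 3)), np.array([1.0]))

    @pytest.mark.parametrize("r3,q,expected",
                             [(-2.0, 2.0, 0.0), (3.0, 1.0, 3.0),
                              (3.0, 2.0, 9.0)])
    def test_pointwise_nonlinearity(self, r3, q, expected):
        out = component4(np.array([[r3]]), np.array([q]))
        assert out[0, 0] == pytest.approx(expected)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(InvalidInputError):
            component4(np.ones((1, 1)), np.array([0.0]))


def straight_line_model(movie, params_list):
    """Independent nested-loop evaluation of the full cascade, written
    directly from the component definitions with no shared code paths."""
    n = len(params_list)
    T = params_list[0].T
    F, h, w = movie.frames.shape
    n_valid = F - T + 1
    R1 = np.zeros((n, n_valid))
    L2 = np.zeros((n, n_valid))
    for i, p in enumerate(params_list):
        # build the filter value by value
        G = np.zeros((T, h, w))
        for ti, t in enumerate(range(-(T - 1), 1)):
            for yy in range(h):
                for xx in range(w):
                    u, v = xx - p.x_loc, yy - p.y_loc
                    ct, st_ = np.cos(p.theta), np.sin(p.theta)
                    cb, sb = np.cos(p.beta), np.sin(p.beta)
                    xp = ct * u - st_ * v
                    v1 = st_ * u + ct * v
                    tp = sb * v1 + cb * t
                    us, vs = u / p.sigma_x, v / p.sigma_y
                    if p.sigma_t == 0:
                        if t != 0:
                            continue
                        ss = 0.0
                    else:
                        ss = t / p.sigma_t
                    xs = ct * us - st_ * vs
                    v1s = st_ * us + ct * vs
                    ys = cb * v1s - sb * ss
                    ts = sb * v1s + cb * ss
                    env = np.exp(-0.5 * (xs ** 2 + ys ** 2 + ts ** 2))
                    arg = -2 * np.pi * (p.spatial_freq * xp + p.phase
                                        + 0.25 * tp)
                    G[ti, yy, xx] = env * np.cos(arg)
        G /= np.linalg.norm(G)
        for vdx in range(n_valid):
            acc = 0.0
            for j in range(T):
                acc += np.sum(G[j] * movie.frames[vdx + j])
            R1[i, vdx] = max(0.0, acc)
        # untuned drive
        y, x = np.mgrid[0:h, 0:w].astype(float)
        d2 = (x - p.x_loc) ** 2 + (y - p.y_loc) ** 2
        g1 = np.exp(-0.5 * d2 / p.sigma_1 ** 2) / (2 * np.pi * p.sigma_1 ** 2)
        g2 = np.exp(-0.5 * d2 / p.sigma_2 ** 2) / (2 * np.pi * p.sigma_2 ** 2)
        for vdx in range(n_valid):
            L2[i, vdx] = np.sum((g1 - g2) * movie.frames[T - 1 + vdx])
    R2 = np.zeros_like(R1)
    for i, p in enumerate(params_list):
        R2[i] = R1[i] - np.maximum(0.0, p.omega * L2[i])
    R3 = np.zeros_like(R1)
    for i, p in enumerate(params_list):
        others = [j for j in range(n) if j != i]
        for vdx in range(R1.shape[1]):
            R3[i, vdx] = R2[i, vdx] / (
                p.sigma_offset + np.mean([R1[j, vdx] for j in others]))
    R4 = np.zeros_like(R1)
    for i, p in enumerate(params_list):
        R4[i] = np.maximum(0.0, R3[i]) ** p.q
    return R1, R2, R3, R4


class TestFullCascade:
    def test_zero_contrast_movie_silences_cascade(self):
        movie = MovieStimulus(frames=np.zeros((20, 24, 24)))
        params = sample_params(3, rng_seed=0, distribution_config={
            "x_loc": {"mean": 12.0, "var": 4.0},
            "y_loc": {"mean": 12.0, "var": 4.0}, "sigma_x_base": 4.0})
        resp = run_model(movie, params)
        for arr in (resp.R1, resp.R2, resp.R3, resp.R4):
            assert np.allclose(arr, 0.0)

    def test_matches_straight_line_reimplementation(self, rng):
        movie = MovieStimulus(frames=rng.uniform(0, 1, (24, 12, 12)),
                              frame_duration_ms=40.0)
        params = [mk_params(x_loc=5.0, y_loc=6.0, sigma_x=3.0, sigma_y=4.0,
                            sigma_t=3.0, theta=0.6, beta=0.0, omega=0.7),
                  mk_params(x_loc=7.0, y_loc=4.0, sigma_x=2.5, sigma_y=3.0,
                            sigma_t=0.0, theta=2.0, beta=np.pi, omega=0.2,
                            q=1.5, sigma_offset=0.4)]
        resp = run_model(movie, params)
        R1, R2, R3, R4 = straight_line_model(movie, params)
        assert np.allclose(resp.R1, R1, atol=1e-9)
        assert np.allclose(resp.R2, R2, atol=1e-9)
        assert np.allclose(resp.R3, R3, atol=1e-9)
        assert np.allclose(resp.R4, R4, atol=1e-9)

    def test_output_nonlinearity_compresses_dimensionality(self):
        from popdim.core import dimensionality
        from popdim.stimuli import natural_surrogate

        movie = natural_surrogate(n_frames=80, size=64, rng_seed=2)
        params = sample_params(25, rng_seed=3, distribution_config=SMALL_CFG)
        resp = run_model(movie, params)
        k3 = dimensionality(response_matrix(resp.R3), 0.9)
        k4 = dimensionality(response_matrix(resp.R4), 0.9)
        assert k4 <= k3

    def test_invariants(self, rng):
        movie = MovieStimulus(frames=rng.uniform(0, 1, (30, 24, 24)))
        params = sample_params(4, rng_seed=5, distribution_config={
            "x_loc": {"mean": 12.0, "var": 4.0},
            "y_loc": {"mean": 12.0, "var": 4.0}, "sigma_x_base": 4.0})
        resp = run_model(movie, params)
        assert np.all(resp.R1 >= 0)
        assert np.all(resp.R4 >= 0)
        # denominator of the normalization is positive, so R3 keeps R2's sign
        assert np.all(np.sign(resp.R3) == np.sign(resp.R2))
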
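"""Unit and property tests of the generative pixel-fluorescence model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from puffsnr import (DegenerateInputError, FluctuationParams, ParameterError,
                     mean_fluorescence, occupancy_from_type3, sample_pixel,
                     sample_pixels, type1_slope, type2_coefficients,
                     type3_line, variance_fluorescence)

# strategy over well-conditioned parameter sets
params_st = st.builds(
    FluctuationParams,
    gain=st.floats(0.5, 5.0),
    eps_bound=st.floats(0.01, 1.0),
    eps_free=st.just(0.0),
    occupancy=st.floats(0.01, 0.99),
    mean_molecules=st.floats(5.0, 2000.0),
).map(lambda p: FluctuationParams(p.gain, p.eps_bound,
                                  p.eps_bound * 0.3, p.occupancy,
                                  p.mean_molecules))


class TestClosedFormMoments:
    def test_reference_values(self, params):
        # A<N>(eps_b lam + eps_f (1-lam)) at the reference point
        assert mean_fluorescence(params) == pytest.approx(6.5)
        assert variance_fluorescence(params) == pytest.approx(14.03)

    def test_equal_brightness_removes_occupancy(self):
        vals = [mean_fluorescence(FluctuationParams(2.0, 0.2, 0.2, lam, 50.0))
                for lam in (0.0, 0.3, 1.0)]
        assert vals == pytest.approx([2.0 * 50.0 * 0.2] * 3)

    def test_dark_limit(self):
        p = FluctuationParams(2.0, 0.1, 0.0, 0.0, 50.0)
        assert mean_fluorescence(p) == 0.0

    @given(params_st)
    @settings(derandomize=True, max_examples=50)
    def test_variance_exceeds_shot_noise(self, p):
        # sigma^2 - A<F> is the molecule-number term, always nonnegative
        assert variance_fluorescence(p) >= p.gain * mean_fluorescence(p) - 1e-12

    def test_shot_noise_ratio_vanishes_monotonically(self):
        # sigma^2/(A<F>) - 1 -> 0 monotonically as eps_b -> 0 at fixed r
        excess = []
        for eps_b in (0.5, 0.2, 0.1, 0.02, 0.004):
            p = FluctuationParams(1.5, eps_b, 0.05 * eps_b, 0.3, 100.0)
            excess.append(variance_fluorescence(p)
                          / (p.gain * mean_fluorescence(p)) - 1.0)
        assert all(e > 0 for e in excess)
        assert excess == sorted(excess, reverse=True)
        assert excess[-1] < 0.005


class TestSampling:
    def test_monte_carlo_moments_match_closed_forms(self, params, rng):
        n = 200_000
        x = sample_pixels(params, n, rng)
        mean, var = mean_fluorescence(params), variance_fluorescence(params)
        se_mean = np.sqrt(var / n)
        assert x.mean() == pytest.approx(mean, abs=4 * se_mean)
        se_var = var * np.sqrt(2.0 / n) * 3  # generous for skewed counts
        assert x.var() == pytest.approx(var, abs=4 * se_var)

    def test_output_is_multiple_of_gain(self, params, rng):
        x = sample_pixels(params, 1000, rng)
        assert np.allclose(np.round(x / params.gain), x / params.gain)
        assert (x >= 0).all()

    def test_dark_params_always_zero(self, rng):
        p = FluctuationParams(2.0, 0.1, 0.0, 0.0, 100.0)
        assert not sample_pixels(p, 1000, rng).any()

    def test_seed_determinism(self, params):
        a = sample_pixel(params, np.random.default_rng(7))
        b = sample_pixel(params, np.random.default_rng(7))
        assert a == b


class TestCurveForms:
    """The Type I/II/III rearrangements must reproduce the exact variance."""

    @given(params_st)
    @settings(derandomize=True, max_examples=100)
    def test_type1_identity(self, p):
        slope = type1_slope(p.gain, p.eps_bound, p.ratio, p.occupancy)
        assert slope * mean_fluorescence(p) == pytest.approx(
            variance_fluorescence(p), rel=1e-12)

    @given(params_st, st.floats(0.05, 3.0))
    @settings(derandomize=True, max_examples=100)
    def test_type2_identity_under_brightness_sweep(self, p, scale):
        a1, a2 = type2_coefficients(p.gain, p.mean_molecules, p.occupancy,
                                    p.ratio)
        q = p.scaled_intensity(scale)
        m = mean_fluorescence(q)
        assert a1 * m + a2 * m ** 2 == pytest.approx(
            variance_fluorescence(q), rel=1e-12)

    @given(params_st, st.floats(0.001, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_type3_identity_under_occupancy_sweep(self, p, lam):
        slope, intercept = type3_line(p.gain, p.eps_bound, p.eps_free,
                                      p.mean_molecules)
        q = p.with_occupancy(lam)
        m = mean_fluorescence(q)
        assert slope * m + intercept == pytest.approx(
            variance_fluorescence(q), rel=1e-12)

    def test_type1_limits(self):
        # eps_b -> 0 gives slope A; r = 1 collapses the bracket to 1 + eps_b
        assert type1_slope(1.5, 1e-12, 0.05, 0.1) == pytest.approx(1.5)
        assert type1_slope(1.5, 0.2, 1.0, 0.3) == pytest.approx(1.5 * 1.2)
        assert type1_slope(2.0, 0.1, 0.5, 0.2) >= 2.0

    def test_type2_limits(self):
        _, a2 = type2_coefficients(1.5, 80.0, 0.4, 1.0)
        assert a2 == pytest.approx(1.0 / 80.0)
        _, a2 = type2_coefficients(1.5, 80.0, 0.4, 0.0)
        assert a2 == pytest.approx(1.0 / (80.0 * 0.4))

    def test_type3_limits(self):
        slope, intercept = type3_line(1.5, 0.2, 0.0, 100.0)
        assert (slope, intercept) == (pytest.approx(1.5 * 1.2), 0.0)

    def test_degenerate_occupancy_and_ratio(self):
        with pytest.raises(DegenerateInputError):
            type1_slope(1.5, 0.1, 0.0, 0.0)
        with pytest.raises(DegenerateInputError):
            type2_coefficients(1.5, 100.0, 0.0, 0.0)


class TestOccupancyInversion:
    @given(params_st, st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=100)
    def test_roundtrip_on_noise_free_moments(self, p, lam):
        q = p.with_occupancy(lam)
        rec = occupancy_from_type3(mean_fluorescence(q),
                                   variance_fluorescence(q),
                                   q.gain, q.eps_bound, q.eps_free)
        assert rec == pytest.approx(lam, abs=1e-9)

    def test_rejects_points_off_the_model_manifold(self, params):
        m = mean_fluorescence(params)
        big_var = params.gain * (1 + params.eps_bound + params.eps_free) * m + 1
        with pytest.raises(DegenerateInputError):
            occupancy_from_type3(m, big_var, params.gain, params.eps_bound,
                                 params.eps_free)
        with pytest.raises(DegenerateInputError):
            occupancy_from_type3(m, 1.0, params.gain, params.eps_bound, 0.0)


class TestValidationAndSerialization:
    @pytest.mark.parametrize("kw", [
        {"gain": 0.0}, {"gain": -1.0}, {"eps_bound": 0.0},
        {"eps_free": 0.2}, {"occupancy": 1.5}, {"occupancy": -0.1},
        {"mean_molecules": 0.0}, {"gain": float("nan")},
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(gain=2.0, eps_bound=0.1, eps_free=0.01, occupancy=0.25,
                    mean_molecules=100.0)
        base.update(kw)
        with pytest.raises(ParameterError):
            FluctuationParams(**base)

    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_file_roundtrip(self, params, tmp_path, suffix):
        path = tmp_path / f"params{suffix}"
        params.to_file(path)
        assert FluctuationParams.from_file(path) == params

    def test_missing_key_rejected(self):
        with pytest.raises(ParameterError):
            FluctuationParams.from_dict({"gain": 1.0})
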
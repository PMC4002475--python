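"""Tests of PSF blurring and noisy image synthesis."""

import numpy as np
import pytest

from puffsnr import (FluctuationParams, ParameterError, PSFParams,
                     blur_radial_field, mean_fluorescence, synthesize_image,
                     variance_fluorescence)
from puffsnr.optics import _psf_weight_matrix
from puffsnr.rd import RDConfig, RDSolution, SpeciesSpec, _fv_geometry


def solution_with_field(r, cad, dye_total=36.0, radius=None):
    """Wrap a radial Ca-bound-dye field (nt, nr) into a minimal RDSolution."""
    cfg = RDConfig(species=(SpeciesSpec("dye", 15.0, 240.0, 180.0, dye_total),),
                   radius_um=radius or float(r[-1]), dr_um=float(r[1] - r[0]))
    nt = cad.shape[0]
    return RDSolution(
        r_um=r, t_ms=np.arange(nt, dtype=float), ca=np.zeros_like(cad),
        bound={"dye": cad}, injected_um_um3=np.zeros(nt),
        pumped_um_um3=np.zeros(nt), closing_times_ms=np.array([]),
        cell_volumes_um3=_fv_geometry(cfg)[1], config=cfg)


def oracle_blur(r_grid, field_1d, x, psf, n=120):
    """Independent 3-D quadrature of the PSF-weighted average at scan x."""
    u = np.linspace(-3 * psf.w_r_um, 3 * psf.w_r_um, n)
    w = np.linspace(-3 * psf.w_z_um, 3 * psf.w_z_um, n)
    uu, vv, ww = np.meshgrid(u + x, u, w, indexing="ij")
    g = np.exp(-2 * ((uu - x) ** 2 + vv ** 2) / psf.w_r_um ** 2
               - 2 * ww ** 2 / psf.w_z_um ** 2)
    rad = np.sqrt(uu ** 2 + vv ** 2 + ww ** 2)
    vals = np.interp(rad.ravel(), r_grid, field_1d).reshape(rad.shape)
    return float((vals * g).sum() / g.sum())


class TestBlur:
    def test_uniform_field_unchanged(self):
        r = np.arange(0, 101) * 0.05
        cad = np.full((3, r.size), 7.25)
        blur = blur_radial_field(solution_with_field(r, cad), "dye",
                                 PSFParams(), np.array([0.0, 0.5, 1.0]))
        assert np.allclose(blur.cad_blur_um, 7.25, rtol=1e-12)

    def test_thin_shell_against_quadrature_oracle(self):
        r = np.arange(0, 161) * 0.05
        psf = PSFParams(w_r_um=0.3, w_z_um=1.0)
        shell = np.exp(-0.5 * ((r - 2.0) / 0.05) ** 2)   # shell at r0 = 2 µm
        cad = shell[None, :]
        xs = np.arange(0.0, 3.01, 0.1)
        blur = blur_radial_field(solution_with_field(r, cad), "dye", psf, xs)
        profile = blur.cad_blur_um[:, 0]
        # peak sits at |x| = r0 within one scan step
        assert abs(xs[np.argmax(profile)] - 2.0) <= 0.1
        peak = oracle_blur(r, shell, 2.0, psf)
        for x in (0.0, 1.0, 1.6, 2.0, 2.4, 2.8):
            k = int(round(x / 0.1))
            # relative near the peak, peak-referenced in the far Gaussian tail
            assert profile[k] == pytest.approx(
                oracle_blur(r, shell, x, psf), rel=0.05, abs=0.01 * peak)

    def test_average_never_exceeds_field_maximum(self, rng):
        r = np.arange(0, 101) * 0.05
        cad = rng.uniform(0, 5, size=(4, r.size))
        blur = blur_radial_field(solution_with_field(r, cad), "dye",
                                 PSFParams(), np.array([0.0, 0.4]))
        assert blur.cad_blur_um.max() <= cad.max() + 1e-12

    def test_linearity_in_dye_concentration(self):
        r = np.arange(0, 101) * 0.05
        cad = np.outer(np.ones(2), np.exp(-r))
        xs = np.array([0.0, 0.5])
        b1 = blur_radial_field(solution_with_field(r, cad), "dye",
                               PSFParams(), xs)
        b2 = blur_radial_field(solution_with_field(r, 2 * cad), "dye",
                               PSFParams(), xs)
        assert np.allclose(b2.cad_blur_um, 2 * b1.cad_blur_um, rtol=1e-12)

    def test_scan_beyond_domain_rejected(self):
        r = np.arange(0, 41) * 0.05   # 2 µm domain
        cad = np.ones((1, r.size))
        with pytest.raises(ParameterError):
            blur_radial_field(solution_with_field(r, cad), "dye", PSFParams(),
                              np.array([1.9]))

    def test_psf_validation(self):
        with pytest.raises(ParameterError):
            PSFParams(w_r_um=0.5, w_z_um=0.3)
        with pytest.raises(ParameterError):
            PSFParams(w_r_um=0.0)

    def test_occupancy_map_bounded(self):
        r = np.arange(0, 101) * 0.05
        cad = np.full((2, r.size), 36.0)     # fully bound dye
        blur = blur_radial_field(solution_with_field(r, cad), "dye",
                                 PSFParams(), np.array([0.0]))
        lam = blur.occupancy_map
        assert lam.min() >= 0.0 and lam.max() <= 1.0


class TestWeightMatrix:
    def test_rows_normalised(self):
        r = np.arange(0, 101) * 0.05
        W = _psf_weight_matrix(r, np.array([0.0, 0.5, 1.0]), PSFParams())
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)
        assert (W >= 0).all()


class TestSynthesizeImage:
    def test_seed_reproducibility(self, params):
        lam = np.full((10, 20), 0.2)
        a = synthesize_image(lam, params, np.random.default_rng(3))
        b = synthesize_image(lam, params, np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)

    def test_dark_input_gives_zero_image(self):
        p = FluctuationParams(2.0, 0.1, 0.0, 0.5, 100.0)
        img = synthesize_image(np.zeros((5, 5)), p, np.random.default_rng(0))
        assert not img.values.any()

    def test_uniform_occupancy_matches_model_moments(self, params, rng):
        lam = np.full((100, 400), params.occupancy)
        img = synthesize_image(lam, params, rng)
        n = img.values.size
        var = variance_fluorescence(params)
        assert img.values.mean() == pytest.approx(
            mean_fluorescence(params), abs=3 * np.sqrt(var / n))
        assert img.values.var(ddof=1) == pytest.approx(var, rel=0.05)

    def test_granule_rows_near_target_level(self, rng):
        p = FluctuationParams(2.0, 0.1, 0.001, 0.25, 100.0)
        lam = np.full((30, 200), p.occupancy)
        rows = np.array([3, 7, 20])
        img = synthesize_image(lam, p, rng, granule_rows=rows,
                               granule_level=0.1)
        bright_mean = np.delete(img.values, rows, axis=0).mean()
        dark_mean = img.values[rows].mean()
        assert dark_mean == pytest.approx(0.1 * bright_mean, rel=0.3)

    def test_granule_rows_floor_at_free_dye_fluorescence(self, params, rng):
        # when the free-dye fluorescence alone exceeds the requested dark
        # level, granule occupancy clips at zero and the rows sit at A<N>eps_f
        lam = np.full((20, 300), params.occupancy)
        rows = np.arange(5)
        img = synthesize_image(lam, params, rng, granule_rows=rows,
                               granule_level=0.1)
        floor = params.gain * params.mean_molecules * params.eps_free
        assert img.values[rows].mean() == pytest.approx(floor, rel=0.15)

    def test_invalid_occupancy_rejected(self, params, rng):
        with pytest.raises(ParameterError):
            synthesize_image(np.full((2, 2), 1.5), params, rng)
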
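"""Tests of the Type I/II/III fits and the consolidated calibration."""

import numpy as np
import pytest

from puffsnr import (FixtureSpec, FluctuationParams, MomentEnsemble,
                     ParameterError, calibrate, concentration_ratio_check,
                     fit_type1, fit_type2, fit_type3, gen_moment_ensemble,
                     mean_fluorescence, type3_line, variance_fluorescence)
from puffsnr.linescan import MomentSample


def ensemble_from_points(xs, ys, exp_type, power=None):
    samples = [
        MomentSample(mean_f=x, var_f=y, n_pixels=1000,
                     annotations={"image_id": i,
                                  "power_rel": power[i] if power else 1.0})
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    return MomentEnsemble(samples=samples, experiment_type=exp_type)


class TestFitType1:
    def test_noise_free_line_recovered_exactly(self):
        xs = np.linspace(1.0, 10.0, 12)
        f = fit_type1(ensemble_from_points(xs, 2.0 * xs, "I"))
        assert f.slope == pytest.approx(2.0, abs=1e-10)
        assert f.intercept == pytest.approx(0.0, abs=1e-9)
        assert not f.intercept_warning

    def test_intercept_warning(self):
        xs = np.linspace(1.0, 10.0, 12)
        f = fit_type1(ensemble_from_points(xs, 2.0 * xs + 5.0, "I"))
        assert f.intercept_warning

    def test_recovers_slope_from_synthetic_ensemble(self, basal_params):
        spec = FixtureSpec("I", basal_params, n_images=84, n_pixels=20_000)
        f = fit_type1(gen_moment_ensemble(spec, 11))
        # the Type I slope is A(1 + eps_b g), not A itself
        from puffsnr import type1_slope
        expected = type1_slope(basal_params.gain, basal_params.eps_bound,
                               basal_params.ratio, basal_params.occupancy)
        assert f.slope == pytest.approx(expected, rel=0.05)

    def test_slope_insensitive_to_molecule_scale(self, basal_params):
        # two ensembles differing only in the <N> scale share the slope
        hi = FluctuationParams(basal_params.gain, basal_params.eps_bound,
                               basal_params.eps_free, basal_params.occupancy,
                               basal_params.mean_molecules * 4)
        f_lo = fit_type1(gen_moment_ensemble(
            FixtureSpec("I", basal_params, 40, n_pixels=20_000), 3))
        f_hi = fit_type1(gen_moment_ensemble(
            FixtureSpec("I", hi, 40, n_pixels=20_000), 4))
        assert f_lo.slope_ci[0] < f_hi.slope < f_lo.slope_ci[1] * 1.05

    def test_too_few_points(self):
        with pytest.raises(ParameterError):
            fit_type1(ensemble_from_points([1, 2], [2, 4], "I"))


class TestFitType2:
    def test_noise_free_quadratic_recovered(self):
        xs = np.linspace(0.5, 20.0, 21)
        ys = 1.5 * xs + 0.05 * xs ** 2
        f = fit_type2(ensemble_from_points(xs, ys, "II",
                                           power=list(np.linspace(0.2, 2, 21))))
        assert f.a1 == pytest.approx(1.5, abs=1e-9)
        assert f.a2 == pytest.approx(0.05, abs=1e-10)
        assert not f.linear_regime and not f.model_violation

    def test_mean_molecule_inversion(self):
        xs = np.linspace(0.5, 20.0, 21)
        f = fit_type2(ensemble_from_points(
            xs, 1.5 * xs + 0.01 * xs ** 2, "II",
            power=list(np.linspace(0.2, 2, 21))))
        assert f.mean_molecules(1.0, 1.0) == pytest.approx(1.0 / f.a2, rel=1e-9)

    def test_linear_regime_diagnostic(self, basal_params, rng):
        # noisy points on a pure line: a2 statistically indistinguishable from 0
        xs = np.linspace(0.5, 5.0, 21)
        ys = 1.5 * xs * rng.normal(1.0, 0.02, size=xs.size)
        f = fit_type2(ensemble_from_points(
            list(xs), list(ys), "II", power=list(np.linspace(0.2, 2, 21))))
        assert f.linear_regime

    def test_requires_power_sweep(self):
        xs = np.linspace(1, 10, 8)
        with pytest.raises(ParameterError):
            fit_type2(ensemble_from_points(xs, 2 * xs, "II",
                                           power=[1.0] * 8))


class TestFitType3:
    def test_noise_free_high_subset_slope(self, basal_params):
        # exact moments along an occupancy sweep with eps_f = 0: the line has
        # slope A(1+eps_b) and zero intercept
        p0 = FluctuationParams(1.5, 0.2, 0.0, 0.1, 100.0)
        lams = np.linspace(0.1, 0.9, 30)
        xs = [mean_fluorescence(p0.with_occupancy(l)) for l in lams]
        ys = [variance_fluorescence(p0.with_occupancy(l)) for l in lams]
        f = fit_type3(ensemble_from_points(xs, ys, "III"), gain=1.5, ratio=0.0)
        assert f.slope_high == pytest.approx(1.5 * 1.2, rel=1e-9)
        assert f.eps_bound == pytest.approx(0.2, rel=1e-9)

    def test_noise_free_occupancy_inversion(self):
        p = FluctuationParams(1.5, 0.2, 0.01, 0.1, 100.0)
        lams = np.linspace(0.05, 0.9, 30)
        xs = [mean_fluorescence(p.with_occupancy(l)) for l in lams]
        ys = [variance_fluorescence(p.with_occupancy(l)) for l in lams]
        f = fit_type3(ensemble_from_points(xs, ys, "III"), gain=1.5,
                      ratio=0.05)
        low = np.sort(lams)[:f.occupancies_low.size]
        # the inversion uses the fitted eps_b (slightly below truth because
        # the high-occupancy slope still carries a small free-dye term), so
        # noise-free points come back within a few percent, not exactly
        assert np.allclose(np.sort(f.occupancies_low), low, rtol=0.1)
        assert f.n_excluded == 0

    def test_sensitivity_report_covers_cuts(self, basal_params):
        spec = FixtureSpec("III", basal_params, n_images=55, n_pixels=20_000)
        f = fit_type3(gen_moment_ensemble(spec, 5), gain=1.5, ratio=0.05)
        assert set(f.eps_bound_by_cut) == {0.2, 0.3, 0.4}


@pytest.fixture(scope="module")
def trio():
    truth = FluctuationParams(1.5, 0.1, 0.005, 0.1, 100.0)
    e1 = gen_moment_ensemble(FixtureSpec("I", truth, 40, n_pixels=50_000), 21)
    e2 = gen_moment_ensemble(FixtureSpec("II", truth, 21, n_pixels=50_000), 22)
    e3 = gen_moment_ensemble(FixtureSpec("III", truth, 55, n_pixels=50_000), 23)
    return truth, e1, e2, e3


class TestCalibrate:

    def test_full_trio_recovery_and_consistency(self, trio):
        truth, e1, e2, e3 = trio
        res = calibrate(e1, e2, e3, ratio=0.05, lambda_grid=(0.1,))
        assert res.gain == pytest.approx(truth.gain, rel=0.05)
        assert res.eps_bound == pytest.approx(truth.eps_bound, rel=0.2)
        assert res.lambda_basal == pytest.approx(truth.occupancy, rel=0.3)
        assert res.all_consistent

    def test_order_invariance(self, trio):
        truth, e1, e2, e3 = trio
        res = calibrate(e1, e2, e3, ratio=0.05)
        shuffled = MomentEnsemble(samples=list(reversed(e1.samples)),
                                  experiment_type="I")
        res2 = calibrate(shuffled, e2, e3, ratio=0.05)
        assert res2.gain == pytest.approx(res.gain, rel=1e-12)
        assert res2.eps_bound == pytest.approx(res.eps_bound, rel=1e-12)

    def test_fluorescence_rescaling_moves_only_the_gain(self, trio):
        # multiplying all fluorescence by c rescales A by c and leaves the
        # dimensionless estimates unchanged
        truth, e1, e2, e3 = trio
        c = 3.0

        def rescale(ens):
            samples = [MomentSample(s.mean_f * c, s.var_f * c * c,
                                    s.n_pixels, s.annotations)
                       for s in ens.samples]
            return MomentEnsemble(samples=samples,
                                  experiment_type=ens.experiment_type)

        res = calibrate(e1, e2, e3, ratio=0.05)
        res_c = calibrate(rescale(e1), rescale(e2), rescale(e3), ratio=0.05)
        assert res_c.gain == pytest.approx(c * res.gain, rel=1e-9)
        assert res_c.eps_bound == pytest.approx(res.eps_bound, rel=1e-9)
        assert res_c.lambda_basal == pytest.approx(res.lambda_basal, rel=1e-9)

    def test_missing_type3_disables_brightness(self, trio):
        truth, e1, e2, _ = trio
        res = calibrate(e1, e2, None, ratio=0.05)
        assert res.eps_bound is None
        assert any("eps_bound unavailable" in n for n in res.notes)

    def test_requires_more_than_type1(self, trio):
        truth, e1, _, _ = trio
        with pytest.raises(ParameterError):
            calibrate(e1, None, None, ratio=0.05)

    def test_inconsistent_gains_raise_flag(self):
        xs = np.linspace(1.0, 10.0, 12)
        e1 = ensemble_from_points(xs, 1.0 * xs, "I")
        e2 = ensemble_from_points(xs, 3.0 * xs + 0.02 * xs ** 2, "II",
                                  power=list(np.linspace(0.2, 2, 12)))
        res = calibrate(e1, e2, None, ratio=0.05)
        flag = next(f for f in res.flags if f.name == "gain_type1_vs_type2")
        assert not flag.passed

    def test_json_roundtrip_and_report(self, trio, tmp_path):
        truth, e1, e2, e3 = trio
        res = calibrate(e1, e2, e3, ratio=0.05)
        path = tmp_path / "cal.json"
        res.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["gain"] == pytest.approx(res.gain)
        assert "self-consistency" in res.report()


class TestCsvRoundtrip:
    def test_ensemble_to_from_csv(self, basal_params, tmp_path, rng):
        ens = gen_moment_ensemble(
            FixtureSpec("I", basal_params, 10, n_pixels=1000), 1)
        path = tmp_path / "moments.csv"
        ens.to_csv(path)
        back = MomentEnsemble.from_csv(path)
        assert np.allclose(back.means, ens.means)
        assert np.allclose(back.variances, ens.variances)
        assert back.experiment_type == "I"


class TestConcentrationRatio:
    def test_proportional_n_passes(self, basal_params):
        hi = FluctuationParams(1.5, 0.1, 0.005, 0.1, 250.0)
        res = []
        for truth, seed in ((basal_params, 31), (hi, 32)):
            e1 = gen_moment_ensemble(FixtureSpec("I", truth, 30,
                                                 n_pixels=20_000), seed)
            e2 = gen_moment_ensemble(FixtureSpec("II", truth, 21,
                                                 n_pixels=20_000), seed + 10)
            e3 = gen_moment_ensemble(FixtureSpec("III", truth, 30,
                                                 n_pixels=20_000), seed + 20)
            res.append(calibrate(e1, e2, e3, ratio=0.05))
        flag = concentration_ratio_check(res[0], res[1],
                                         concentration_ratio=2.5)
        assert flag.passed
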
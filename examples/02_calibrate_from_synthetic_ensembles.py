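"""Calibrating the fluctuation model from Type I/II/III stationary ensembles.

Generates synthetic per-image (mean, variance) ensembles with a known ground
truth — Type I varies the imaged region (molecule number), Type II the laser
power (brightness), Type III the cytosolic Ca2+ (occupancy) — then fits the
three variance-vs-mean curves and consolidates the parameter estimates.
"""

from puffsnr import FixtureSpec, FluctuationParams, calibrate, gen_moment_ensemble

truth = FluctuationParams(gain=1.5, eps_bound=0.1, eps_free=0.005,
                          occupancy=0.1, mean_molecules=100.0)

type1 = gen_moment_ensemble(FixtureSpec("I", truth, n_images=84), rng=1)
type2 = gen_moment_ensemble(FixtureSpec("II", truth, n_images=21), rng=2)
type3 = gen_moment_ensemble(FixtureSpec("III", truth, n_images=55), rng=3)

result = calibrate(type1, type2, type3, ratio=truth.ratio)
print(result.report())
print()
print(f"ground truth: A = {truth.gain}, eps_b = {truth.eps_bound}, "
      f"lambda_basal = {truth.occupancy}, <N> = {truth.mean_molecules}")
print("The report's estimates and consistency flags show how well the three")
print("stationary experiment types pin down the noise model before any")
print("signal-evoking experiment is attempted.")
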
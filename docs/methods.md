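# Methods

This note documents the models implemented in `puffsnr`, their assumptions,
the defaults and where they come from, and what the synthetic-data tests do
and do not establish about real recordings.

## 1. Pixel fluorescence model

A pixel of a photon-counting confocal linescan is modelled as

1. `N ~ Poisson(⟨N⟩)` — the number of dye molecules contributing to the
   pixel. Poisson molecule-number statistics is the standard
   Number-&-Brightness assumption for freely diffusing emitters sampled by a
   small observation volume.
2. `B | N ~ Binomial(N, λ)` — each molecule is independently Ca²⁺-bound with
   probability λ (the *occupancy*). The binomial stage is kept exact — no
   deterministic-fraction shortcut — because the occupancy dependence of the
   Type II quadratic coefficient comes from the binomial variance.
3. `P ~ Poisson(ε_b B + ε_f (N−B))` — detected photons per pixel dwell, with
   molecular brightnesses ε_b (bound) and ε_f (free). For a single-wavelength
   dye both forms emit in the same band; their ratio r = ε_f/ε_b is a fixed
   photophysical property of the dye (of the order of the quantum-efficiency
   ratio) while ε_b itself scales with laser intensity.
4. `F = A·P` — the detector multiplies by a gain A with no offset and
   contributes no extra dispersion beyond the Poisson resampling already in
   stage 3. Photon-counting detectors measured in darkness show no offset,
   which justifies the zero-offset choice.

Pixels are statistically independent: spatial/temporal correlation from
diffusion during the dwell time is ignored, consistent with pooling all
cytosol pixels of an image into one moment estimate.

The closed-form moments and the three curve re-parameterisations (Type I
slope, Type II quadratic, Type III line) are exact algebraic consequences of
the chain; the test suite pins each of them to the exact variance at 1e-12
relative over random parameter draws, so a transcription error in any one
form cannot survive.

## 2. Image preprocessing

*Xenopus* oocyte linescans contain persistently dark rows (cortical
granules). The time-averaged spatial profile f(x) is thresholded at
`μ_f + k·σ_f` (its own mean and SD, default k = 0) and only bright rows enter
the pooled moments. The exact inequality used in the original image-analysis
recipe is not recoverable, so k is an explicit, recorded parameter rather
than a hidden constant. Masking a *unimodal* profile would keep only its
brighter half and bias the pooled mean, so a bimodality gate
(`needs_fringe_preprocessing`, coefficient of variation > 0.2) decides
whether masking should be applied at all; cell types without granules skip
it.

Pooled variance uses the sample (n−1) convention by default; the population
convention is a flag. At the pixel counts involved (≥10⁴) the difference is
immaterial, but the choice is explicit.

## 3. Calibration

`fit_type1` is unweighted OLS with intercept; the slope is reported as the
gain estimate in the small-brightness regime, with a warning flag when the
intercept exceeds 10% of the median variance. `fit_type2` is OLS on
(⟨F⟩, ⟨F⟩²) through the origin; a₂ statistically indistinguishable from zero
raises the *linear-regime* diagnostic — the signature of a setting whose
probed powers never reach the fluorescence level where molecule-number
fluctuations are visible, and an early warning that the setting may be unable
to report Ca²⁺ signals. `fit_type3` fits the top 30% of points (by mean
fluorescence) with a through-origin line whose slope tends to A(1+ε_b) at
high occupancy, and inverts each bottom-30% point for its occupancy in closed
form; the ε_b estimate is recomputed for 20/30/40% cuts because it is
genuinely cut-dependent and the spread is part of the result. Unweighted OLS
with standard 95% linear-regression CIs mirrors the generic curve-fitting
practice the method was designed around; no error model is invented for the
per-image moments.

**Gain consolidation.** The Type I slope equals
A·[1 + ε_b(λ+r²(1−λ))/(λ+r(1−λ))], not A: at ε_b = 0.1, r = 0.05, λ = 0.1 the
bracket is 1.07, so equating the gain to the slope would carry a 7% bias.
The Type II linear coefficient a₁ equals A exactly in the model, so
`calibrate` anchors the consolidated gain on a₁ whenever a power sweep is
available and keeps the Type I slope as a self-consistency cross-check
(their ratio must stay within a configurable factor, default 3). An
iterative joint solve of the Type I/III relations was tried first and is
numerically unstable when the estimated basal occupancy drifts high (the
correction denominator 1−g approaches 0); it was abandoned in favour of the
a₁ anchor.

The basal occupancy is the 25th percentile of the occupancies inverted from
the low-fluorescence Type III subset. This works because a realistic Type III
campaign contains a cluster of no-added-Ca²⁺ images (the synthetic generator
reserves 20% of its images for them); the inversion noise is skewed upward
(the ordinate enters through its reciprocal), which is why a low percentile
rather than the median estimates the basal value.

⟨N⟩ is reported two independent ways — from a₂ at caller-supplied (λ, r)
scenarios, and from the observed Type I mean-fluorescence range via
⟨F⟩ = A⟨N⟩(ε_bλ+ε_f(1−λ)) — and the two routes are compared per scenario as a
self-consistency flag. Occupancy scenarios default to λ ∈ {0.05, 0.1, 0.3};
because λ_basal is never known exactly, ranges per scenario are the honest
output. r is a required user input for quantitative work: it is dye-specific
and no universal default is safe.

## 4. Reaction–diffusion puff model

Species: free Ca²⁺ (D = 220 µm²/s, basal 0.1 µM), indicator dye, EGTA
(D = 80, k_on = 5 µM⁻¹s⁻¹, k_off = 0.75 s⁻¹), an immobile endogenous buffer
(k_on = 400, k_off = 800, 300 µM), and optional slow/rapid mobile endogenous
buffers (off by default in puff scenarios). Dye kinetics: Fluo-4
k_on = 240 µM⁻¹s⁻¹, k_off = 180 s⁻¹ (K_d = 0.75 µM); Rhod-2 ships as two
variants, `a` (70/130) and `b` (85/170), because two rate pairs are in
circulation and choosing silently would hide a K_d difference of 8%. Free and
bound forms of each species share a diffusion coefficient, so total species
concentrations stay uniform and only the bound form is propagated.

**Pump.** The pump flux is linearised as J = γ·(Ca − Ca_basal) with
γ = k_off,P·[P]_T/Ca_basal = 0.1 s⁻¹ · 0.9 µM / 0.1 µM = 0.9 s⁻¹. This form
is units-consistent, makes the equilibrium initial condition exactly
stationary, and is a deliberate surrogate: the original pump kinetics are not
specified to this level. Alternative forms can be configured.

**Source.** A cluster of N_ch = 6 channels at the origin, all open at t = 0,
each closing after an exponential time of mean 20 ms. The per-channel flux
(ions/s) is a required parameter because no published per-channel current is
available for this configuration; `calibrate_source_flux` bisects it until
the peak blurred occupancy reaches a target multiple of basal (default 2×,
the smallest-detectable amplitude the method is designed around). Injection
is volumetric into the region r < Δr (divided by the shell volume), the
well-posed point-source surrogate in spherical symmetry.

**Numerics.** Backward Euler in time. Within each step: (1) the source
amount for the step is deposited; (2) diffusion advances implicitly — one
tridiagonal solve per mobile species, using the conservative finite-volume
form of the radial Laplacian (2nd order, first neighbours; exact discrete
mass conservation under no-flux boundaries, which the mass-balance tests rely
on); (3) binding reactions and the pump advance implicitly at every node by a
vectorised Newton iteration on free Ca²⁺ (each bound concentration is an
explicit function of the nodal Ca²⁺ under backward Euler, so the per-node
system reduces to one monotone scalar equation). Defaults Δr = 0.05 µm,
Δt = 0.01 ms, R = 5 µm, chosen by the convergence tests in the suite
(equilibrium drift < 1e-9 per 100 steps; mass imbalance < 1% of injected
ions; point-source profile within 5% of the Green's-function steady state
over 0.2–2 µm; ~4× error reduction per Δr halving).

## 5. Confocal optics and image synthesis

The PSF is a 3-D Gaussian with 1/e² half-widths w_r = 0.3 µm lateral and
w_z = 1.0 µm axial — typical for a 60× high-NA confocal, configurable, and
always recorded in outputs, since the original optical parameters are not
recoverable. The blur of the radial Ca-bound dye field at scan position x is
a normalised Gaussian-weighted average centred at (x, 0, 0), truncated at 3
half-widths and renormalised (a uniform field is reproduced exactly); the
weights form a precomputed (scan × radius) matrix, so blurring a whole time
series is one matrix product. Dividing by the total dye concentration gives
the occupancy map λ(x, t).

Images are drawn pixel-independently from the generative chain with the
pixel's own λ. Scan geometry defaults: Δx = 0.2 µm, line period 2 ms (both
explicit parameters, not claimed to match any particular instrument).
Optional granule rows replace λ so the row mean lands at ~10% of the
cytosolic basal mean — when the free-dye fluorescence alone exceeds that
level the occupancy clips at zero and the rows sit at A⟨N⟩ε_f, the physical
floor. Granule rendering exists for preprocessing tests; it adds no
morphology.

## 6. SNR and equivalence classes

The image-based SNR is (F_max − F_min)/σ_F(λ_basal) over cytosol pixels,
taking the extrema literally; a percentile-based robust variant exists but is
off by default and flagged in its report. Because extrema of ~10³–10⁴ noisy
pixels sit several σ from the means, the image-based value is *positively
biased* relative to the analytic form — by roughly the sum of the two extreme
excursions — and only approaches it when the signal spread dominates
(large ⟨N⟩·ε). The estimators nevertheless rank settings the same way, which
is what the classification uses. The analytic SNR evaluates the exact moments
(the simplified small-ε expression is available as a documented variant,
accurate to ~ε_b/2 relative for ε_b ≤ 0.2). It is exactly gain-free and
∝ √⟨N⟩, which is where the concentration factor √(90/36) ≈ 1.6 between the
two Rhod-2 concentrations comes from.

Equivalence classification is single linkage: settings link when
|SN_a − SN_b|/max(SN_a, SN_b) ≤ 0.25 (default), classes are connected
components. The 0.25 default separates a 40% difference while keeping a 16%
difference together — the regime the method is meant to discriminate; class
boundaries shift with the probed signal amplitude, so the robust scientific
output is the SNR *ordering*, with the classes as a summary at a stated
threshold.

Occupancy translation between dyes assumes dye–Ca²⁺ equilibrium at the
signal peak: Ca_peak = K_d,old·λ/(1−λ), λ_new = Ca_peak/(Ca_peak+K_d,new).

## 7. Scenario defaults (the three concentration sets)

Set (i): 36 µM Fluo-4 + 90 µM EGTA. Set (ii): 36 µM Rhod-2 + 90 µM EGTA.
Set (iii): 90 µM Rhod-2 + 45 µM EGTA. Shared gain A = 1.5 and
ε_b = 0.1 at standard illumination across sets (the same set-up and
comparable detector behaviour for both lasers). Brightness ratios r = 0.025
for Fluo-4 (~40× fluorescence enhancement on Ca²⁺ binding) and r = 0.07 for
Rhod-2 (~14× enhancement) — package defaults consistent with the classic
characterisation of these indicator families and with the observation that
basal Rhod-2 fluorescence is free-dye dominated while Fluo-4's bound and free
contributions are comparable. ⟨N⟩ is proportional to total dye concentration
at 340 molecules per pixel per 36 µM, chosen once so that the reference
set's analytic SNR is ≈2 at the smallest-detectable amplitude
(λ_peak = 2λ_basal) — the design point of the method. The shared source is
calibrated per channel-closing realisation so the reference set reaches that
amplitude.

Under these conditions the pipeline reproduces the method's two headline
behaviours, verified in the acceptance suite across ten source seeds: the
peak/basal blurred Ca-bound dye ratio agrees within 15% across the three
sets (the dye distribution cannot explain detectability differences), while
the SNR orders them (ii) < (iii) ≤ (i) with the free-dye fluorescence
included and *reverses* the (i)/(iii) comparison when ε_f is forced to 0 —
noise alone cannot explain why low-concentration Rhod-2 fails; the free-dye
background can. The (iii) vs (i) comparison is a ~5% effect on the analytic
route and statistically a tie on the image route; the acceptance test
asserts it where it is resolvable.

## 8. What the synthetic tests do and do not show

The generators emulate: per-image moment scatter from finite pixel counts,
regional dye-concentration jitter (log-uniform ×[0.5, 2]), laser-power sweeps
at fixed r, occupancy ramps with a 20% basal cluster, granule dark rows, and
full puff image synthesis with seeded reproducibility (identical seed ⇒
identical bytes). They do not emulate: motion, bleaching, detector
afterpulsing or dead-time, autofluorescence, scan jitter, spatially
structured background, or correlated pixel noise from diffusion during the
dwell. Passing recovery tests therefore shows the estimators are correct and
well-conditioned under the stated model, not that real-oocyte systematics
are absent. Numbers quoted anywhere in this note are computed by the test
suite or the examples; problem sizes (84/21/55 images × 10⁵ pixels for
recovery, 10 source seeds × 10 images for the pipeline properties) are the
package's chosen desk-scale defaults.

## 9. Known limitations

- The pump and per-channel flux are documented surrogates; absolute Ca²⁺
  amounts are only as good as those choices.
- Spherical symmetry: no ER geometry, no cluster spatial extent.
- The image-extreme SNR definition is taken literally and is
  extreme-value-biased; compare like with like (same image size) when using
  it across settings.
- Channel gating is "open at t = 0, exponential closing" — no IP₃R kinetics.
- Calibration assumes the dye's r is known; an error in r propagates into
  ε_f and the occupancy inversions roughly linearly.
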
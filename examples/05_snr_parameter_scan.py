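"""Choosing experimental parameters with the quantified noise model.

Scans the analytic SNR over the experimentally accessible knobs — dye
concentration (through the mean molecule number), laser intensity and basal
occupancy — and shows the occupancy translation used when replacing one dye
by another with a different dissociation constant.
"""

import math

from puffsnr import snr_analytic, snr_surface, translate_occupancy_between_dyes
from puffsnr.pipeline import scenario_fluctuation_params

base = scenario_fluctuation_params("i")    # calibrated Fluo-4 setting
lam_peak = 2 * base.occupancy              # smallest detectable amplitude

surface = snr_surface(base,
                      n_grid=[170, 340, 680],
                      intensity_grid=[0.5, 1.0, 2.0],
                      lambda_basal_grid=[0.06, 0.1176],
                      lambda_peak=lam_peak)
print(surface.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()

sn_36 = snr_analytic(base, lam_peak)
hi = type(base)(base.gain, base.eps_bound, base.eps_free, base.occupancy,
                base.mean_molecules * 90 / 36)
sn_90 = snr_analytic(hi, lam_peak)
print(f"SNR at 36 uM-equivalent <N>: {sn_36:.3f}")
print(f"SNR at 90 uM-equivalent <N>: {sn_90:.3f}")
print(f"concentration factor       : {sn_90 / sn_36:.2f} "
      f"(= sqrt(90/36) = {math.sqrt(2.5):.2f})")
print()

lam_new = translate_occupancy_between_dyes(lam_peak, kd_old_um=0.75,
                                           kd_new_um=0.375)
print(f"a dye with half the K_d would reach occupancy {lam_new:.3f} at the")
print(f"same peak Ca2+ that gives {lam_peak:.3f} for Fluo-4 — the translation")
print("used to predict SNR when swapping indicators.")
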
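"""Ranking dye/EGTA settings by predicted SNR and classing them.

Runs the full pipeline for the three concentration sets — (i) 36 µM Fluo-4 +
90 µM EGTA, (ii) 36 µM Rhod-2 + 90 µM EGTA, (iii) 90 µM Rhod-2 + 45 µM EGTA —
under one shared calibrated source, then groups the settings into equivalence
classes by relative SNR difference.
"""

from puffsnr import classify_equivalence
from puffsnr.pipeline import run_set_comparison

results = run_set_comparison(seed=1, n_image_seeds=5)

print("set   peak/basal  lambda_b  lambda_p  SN(analytic)  SN(image mean)")
for label, r in results.items():
    print(f"{label:4s}  {r.peak_to_basal:9.3f}  {r.lambda_basal:8.4f}  "
          f"{r.lambda_peak:8.4f}  {r.sn_analytic:12.3f}  "
          f"{r.sn_image_mean:14.2f}")

report = classify_equivalence(
    {label: r.sn_analytic for label, r in results.items()}, threshold=0.25)
print()
print(f"equivalence classes at 25% relative SNR difference: "
      f"{[sorted(c) for c in report.classes]}")
print()
print("The blurred Ca-bound dye responds almost identically in all three")
print("sets (peak/basal column), yet the SNR ranks them ii < iii < i: noise")
print("and the free-dye background, not the Ca2+-bound dye distribution,")
print("decide whether puffs are detectable.  The class boundaries shift with")
print("the probed signal amplitude and the dye parameters; the ordering is")
print("the robust output.")
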
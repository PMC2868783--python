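"""Fit of the phosphatidylcholine-vesicle partition model.

Analyzes the printed anchor point (pH 6.54, nbar 0.049, i.e. free UCB
5.1 uM out of 10 uM against 100 uM PC), fits K'' on a noise-free
synthetic titration, and contrasts the two counterfactual scenarios.
"""

import numpy as np

from bilispec import (
    HIGH_PKA,
    LOW_PKA,
    NO_DIMER,
    VesicleDataPoint,
    fit_k,
    free_diacid_at_point,
    gen_vesicle_dataset,
    predict_nbar,
    saturated_nbar_curve,
)

anchor = VesicleDataPoint(6.54, 0.049)

ch2b = free_diacid_at_point(anchor)
fit_hi = fit_k([anchor])
print(f"High pKa: at pH 6.54 the 5.1 uM free pool holds {ch2b:.3f} uM diacid,")
print(f"so the anchor implies K'' = {fit_hi.k_dblprime:.4f} uM^-1.")

fit_lo = fit_k([anchor], ks=LOW_PKA, dim=NO_DIMER)
print(f"\nLow pKa (4.2/4.9): the same pool holds only "
      f"{free_diacid_at_point(anchor, ks=LOW_PKA, dim=NO_DIMER)*1e3:.3f} nM diacid,")
print(f"demanding K'' = {fit_lo.k_dblprime:.0f} uM^-1 -- and the curve then "
      "collapses:")
for ph in (6.54, 6.9, 7.2):
    nb = predict_nbar(ph, fit_lo.k_dblprime, ks=LOW_PKA, dim=NO_DIMER)
    print(f"  pH {ph:4.2f}: predicted nbar = {nb:.4f}")
print("far below the observed plateau (~0.04-0.05 up to pH ~8).")

ds = gen_vesicle_dataset(0.00932, np.linspace(6.5, 9.5, 9))
pts = [VesicleDataPoint(ph, v) for ph, v in ds.rows()]
fit = fit_k(pts)
print(f"\nNoise-free synthetic titration, generating K'' = 0.00932 uM^-1:")
print(f"  fitted K'' = {fit.k_dblprime:.5f} +/- {fit.k_sd:.2g} uM^-1, "
      f"r = {fit.r:.3f} (exact round trip)")

flat = saturated_nbar_curve(anchor.nbar, [6.5, 8.0, 9.5])
print(f"\nNo-supersaturation counterfactual: nbar stays at "
      f"{flat.f_values[0]:.3f} at every pH (free diacid pinned at saturation); "
      "the observed decline shows the free pool was supersaturated.")
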
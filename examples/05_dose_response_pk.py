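"""Downstream evaluation: 4PL IC50 fit and non-compartmental PK analysis.

The dose-response generator produces viability (% of control) over a
5-50 µM design from a four-parameter-logistic curve; the PK generator
produces a one-compartment (Bateman) plasma profile calibrated to a
50 mg/kg intraperitoneal dose with an 11 h terminal half-life.
"""

import numpy as np

from bclscreen.bioeval import fit_ic50, nca, tumor_volume, TumorMeasurement
from bclscreen.synthdata import PKSynthConfig, generate_dose_response, generate_pk_profile

dr = generate_dose_response(ic50=20.0, hill=1.2, top=100.0, bottom=5.0)
fit = fit_ic50(dr)
print(f"IC50 fit: {fit.ic50:.2f} uM (hill {fit.hill:.2f}, "
      f"top {fit.top:.1f}%, bottom {fit.bottom:.1f}%)")

cfg = PKSynthConfig()  # 50 mg/kg IP, ka 1.7/h, ke 0.063/h, V 25 L/kg, MW 775
profile = generate_pk_profile(cfg)
res = nca(profile, mw=cfg.mw)
print(f"NCA: Cmax {res.cmax:.2f} uM at Tmax {res.tmax:g} h; "
      f"AUC_last {res.auc_last:.1f}, AUC_inf {res.auc_inf:.1f} uM*h")
print(f"     lambda_z {res.lambda_z:.4f} 1/h -> t1/2 {res.t_half:.1f} h "
      f"({res.n_lambda_z} terminal points); "
      f"CL {res.clearance_mL_min_kg:.1f} mL/min/kg")
print(f"sanity: t1/2 = ln2/ke = {np.log(2) / cfg.ke:.1f} h by construction")

v = tumor_volume(TumorMeasurement(length=10.0, width=5.0))
print(f"tumor volume for 10 x 5 mm calipers: {v:.2f} mm^3 (L*W^2*pi/6)")
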
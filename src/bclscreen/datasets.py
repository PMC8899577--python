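"""Published reference values for the IS-series Bcl-2-family inhibitors.

These are the SPR-measured equilibrium dissociation constants (two-site fit,
highest-affinity site) and the mouse pharmacokinetic summary for IS21, kept
here so worked examples and acceptance checks can recompute derived
quantities (selectivity indices, candidate bookkeeping) from the measured
inputs rather than hard-coding the derived numbers.
"""

from __future__ import annotations

#: KD (µM) of IS-series compounds and ABT-199 against immobilized Bcl-2.
BCL2_KD_UM: dict[str, float] = {
    "IS1": 0.48,
    "IS9": 4.0,
    "IS20": 0.32,
    "IS21": 0.19,
    "IS27": 4.6,
    "IS29": 3.4,
    "ISP": 0.77,
    "ISQ": 0.53,
    "ABT-199": 0.016,
}

#: KD (µM) against immobilized Bcl-xL (titration series).
BCLXL_KD_UM: dict[str, float] = {
    "IS20": 0.42,
    "IS21": 0.51,
    "ABT-199": 1.40,
}

#: KD (µM) against immobilized Mcl-1 (titration series, 0.3 µM step included).
MCL1_KD_UM: dict[str, float] = {
    "IS20": 3.90,
    "IS21": 1.16,
}

#: IS21 plasma pharmacokinetic summary after 50 mg/kg intraperitoneal dosing
#: in mice (means across animals).
IS21_PK_SUMMARY = {
    "cmax_uM": 4.1,
    "auc_uM_h": 40.9,
    "t_half_h": 11.0,
    "clearance_mL_min_kg": 26.3,
}

#: Virtual-screen triage bookkeeping: top-k per model, vendor-unavailable and
#: DMSO-precipitating candidate counts observed during compound acquisition.
SCREEN_COUNTS = {
    "top_k_per_model": 30,
    "n_models": 2,
    "n_unavailable": 3,
    "n_precipitated": 8,
}
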
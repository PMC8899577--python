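"""Concordance between docking energies and measured binding affinities.

The docking engine is external; this module only quantifies how well its
energies (kcal/mol, more negative = better) track measured dissociation
constants. Because energies are log-affinity-like, the default comparison
scale is pKD = -log10(KD in M); the raw-KD correlation is reported
alongside. Energy-vs-pKD correlations are expected *negative* by sign
convention, so the report carries both the signed r and |r|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .exceptions import InputError

__all__ = ["ConcordanceReport", "pearson", "concordance_report"]


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise InputError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("Pearson correlation undefined for a constant vector")
    return float(pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ConcordanceReport:
    """Docking-energy / affinity agreement on both scales."""

    n: int
    scale: str  # primary scale: "pkd" or "raw_kd"
    r_pkd: float
    r_raw_kd: float

    @property
    def r(self) -> float:
        return self.r_pkd if self.scale == "pkd" else self.r_raw_kd

    @property
    def abs_r(self) -> float:
        return abs(self.r)


def concordance_report(pairs: pd.DataFrame, scale: str = "pkd") -> ConcordanceReport:
    """Correlate docking energies with KDs over a table of compounds.

    ``pairs`` needs columns compound_id, docking_energy (kcal/mol) and kd_M.
    """
    if scale not in ("pkd", "raw_kd"):
        raise InputError(f"unknown scale {scale!r}")
    for col in ("compound_id", "docking_energy", "kd_M"):
        if col not in pairs.columns:
            raise InputError(f"missing column {col!r}")
    if pairs["compound_id"].duplicated().any():
        dups = pairs.loc[pairs["compound_id"].duplicated(), "compound_id"].tolist()
        raise InputError(f"duplicate compound_id(s): {dups}")
    kd = pairs["kd_M"].to_numpy(float)
    if np.any(kd <= 0):
        raise InputError("kd_M values must be positive")
    energy = pairs["docking_energy"].to_numpy(float)
    p_kd = -np.log10(kd)
    return ConcordanceReport(
        n=len(pairs),
        scale=scale,
        r_pkd=pearson(energy, p_kd),
        r_raw_kd=pearson(energy, kd),
    )
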
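"""Curation of bioactivity records into labelled FA/BA modelling datasets.

Records follow the ChEMBL/PubChem convention: one measurement per row with a
compound id, SMILES, target, assay class (FA = functional cell-based,
BA = biochemical binding), endpoint (IC50/Ki/KD/EC50), a relation qualifier,
a positive value and a concentration unit. Curation standardizes values to
pAffinity (-log10 molar), resolves censored relations conservatively,
collapses replicates by median (discarding irreconcilable ones), and
produces reproducible stratified train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import InputError

__all__ = [
    "UNIT_TO_MOLAR",
    "SplitSpec",
    "CuratedDataset",
    "normalize_activity",
    "label_activity",
    "deduplicate",
    "split_dataset",
]

UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}

ENDPOINTS = frozenset({"IC50", "Ki", "KD", "EC50"})
RELATIONS = frozenset({"=", "<", ">", "<=", ">=", "≤", "≥"})

#: Default class boundary: active means pAffinity >= 6 (i.e. <= 1 µM).
DEFAULT_THRESHOLD = 6.0

#: Replicates spanning more than this many log units are irreconcilable.
MAX_REPLICATE_RANGE = 1.0


def normalize_activity(value: float, units: str, endpoint: str = "IC50") -> float:
    """Convert a concentration endpoint to pAffinity = -log10(molar value)."""
    if endpoint not in ENDPOINTS:
        raise InputError(f"unknown endpoint {endpoint!r}")
    if units not in UNIT_TO_MOLAR:
        raise InputError(f"unknown unit {units!r}")
    if not np.isfinite(value) or value <= 0:
        raise InputError(f"activity value must be positive, got {value!r}")
    return float(-np.log10(value * UNIT_TO_MOLAR[units]))


def label_activity(
    p_affinity: float, relation: str = "=", threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Classify one measurement as ``active``/``inactive``/``excluded``.

    The relation qualifies the reported *concentration*, so on the
    pAffinity scale it flips: a "<" record (value below the printed
    concentration) means the true pAffinity is at least the computed bound.
    Censored records only receive a label when the bound itself settles the
    question; otherwise they are excluded rather than guessed. The boundary
    is inclusive: pAffinity exactly at the threshold is active.
    """
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    if relation not in RELATIONS:
        raise InputError(f"unknown relation {relation!r}")
    if relation == "=":
        return "active" if p_affinity >= threshold else "inactive"
    if relation in ("<", "<=", "≤"):  # true pAffinity >= bound
        return "active" if p_affinity >= threshold else "excluded"
    # ">", ">=", "≥": true pAffinity <= bound
    return "inactive" if p_affinity < threshold else "excluded"


@dataclass(frozen=True)
class CuratedDataset:
    """One row per (compound, assay_class) with provenance counts."""

    table: pd.DataFrame  # compound_id, assay_class, p_affinity, label, n_replicates
    n_raw: int
    n_dropped_censored: int
    n_dropped_range: int

    @property
    def n_kept(self) -> int:
        return len(self.table)

    def check_provenance(self) -> bool:
        """Kept rows + dropped records reconcile with the raw input size."""
        n_collapsed = int(self.table["n_replicates"].sum()) if self.n_kept else 0
        return n_collapsed + self.n_dropped_censored + self.n_dropped_range == self.n_raw


def deduplicate(
    records: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> CuratedDataset:
    """Collapse normalized records to one row per (compound, assay_class).

    Expects columns ``compound_id``, ``assay_class``, ``p_affinity`` and
    optionally ``relation`` (default "="). Censored records that
    :func:`label_activity` excludes are dropped first; surviving replicates
    are collapsed to their median pAffinity unless they span more than
    one log unit, in which case the whole group is dropped as
    irreconcilable. The final label is recomputed from the median.
    """
    cols = ["compound_id", "assay_class", "p_affinity"]
    n_raw = len(records)
    if n_raw == 0:
        empty = pd.DataFrame(columns=cols + ["label", "n_replicates"])
        return CuratedDataset(empty, 0, 0, 0)
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise InputError(f"records missing columns: {missing}")
    df = records.copy()
    if "relation" not in df.columns:
        df["relation"] = "="
    lab = df.apply(
        lambda r: label_activity(r["p_affinity"], r["relation"], threshold), axis=1
    )
    censored = lab == "excluded"
    n_censored = int(censored.sum())
    df = df[~censored]

    kept_rows = []
    n_dropped_range = 0
    for (cid, aclass), grp in df.groupby(["compound_id", "assay_class"], sort=True):
        vals = grp["p_affinity"].to_numpy(float)
        if vals.max() - vals.min() > MAX_REPLICATE_RANGE:
            n_dropped_range += len(grp)
            continue
        med = float(np.median(vals))
        kept_rows.append(
            {
                "compound_id": cid,
                "assay_class": aclass,
                "p_affinity": med,
                "label": label_activity(med, "=", threshold),
                "n_replicates": len(grp),
            }
        )
    table = pd.DataFrame(kept_rows, columns=cols + ["label", "n_replicates"])
    return CuratedDataset(table, n_raw, n_censored, n_dropped_range)


@dataclass(frozen=True)
class SplitSpec:
    """Reproducible stratified train/test split parameters."""

    train_fraction: float = 0.8
    seed: int = 0
    stratify_on: str = "label"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise InputError("train_fraction must be in (0, 1)")


def split_dataset(
    dataset: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive, stratified train/test partitions.

    Same spec (fraction + seed) always yields the same split; class
    proportions are preserved to within one row per class.
    """
    if spec.stratify_on not in dataset.columns:
        raise InputError(f"stratification column {spec.stratify_on!r} missing")
    y = dataset[spec.stratify_on]
    if (y.value_counts() < 2).any():
        raise InputError("every class needs >= 2 rows for a stratified split")
    train, test = train_test_split(
        dataset,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=y,
        shuffle=True,
    )
    return train, test
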
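"""End-to-end virtual-screening pipeline on synthetic inputs.

Chains the stages: generate bioactivity records -> curate -> split -> train
one soft-voting ensemble per assay class (FA/BA) -> rank a screening
library with each -> pool top-k -> apply availability/solubility filters.
Fully deterministic for a given seed; intended both as the executable
worked example and as the smoke-tested integration path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .curation import SplitSpec, deduplicate, split_dataset
from .exceptions import InputError
from .qsar import CVReport, FeatureConfig, SoftVotingEnsemble, cross_validate, featurize_dataset
from .screen import SelectionReport, apply_practical_filters, rank_library, select_candidates
from .synthdata import BioSynthConfig, generate_bioactivity_dataset, generate_screening_library

__all__ = ["PipelineResult", "train_class_model", "run_virtual_screen"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything the screening pipeline produced for one seed."""

    cv_reports: dict[str, CVReport]
    models: dict[str, SoftVotingEnsemble]
    ranked: dict[str, pd.DataFrame]
    candidates: pd.DataFrame
    report: SelectionReport


def train_class_model(
    records: pd.DataFrame,
    assay_class: str,
    feature_config: FeatureConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[SoftVotingEnsemble, CVReport]:
    """Curate one assay class's records and train its voting ensemble."""
    subset = records[records["assay_class"] == assay_class]
    if len(subset) == 0:
        raise InputError(f"no records for assay class {assay_class!r}")
    curated = deduplicate(subset)
    merged = curated.table.merge(
        records.drop(columns=["p_affinity"]).drop_duplicates("compound_id"),
        on="compound_id",
        suffixes=("", "_raw"),
    )
    X, kept, _ = featurize_dataset(merged, feature_config)
    y = (kept["label"] == "active").astype(int).to_numpy()
    cv = cross_validate(X, y, n_folds=n_folds, seed=seed)
    model = SoftVotingEnsemble().fit(X, y)
    return model, cv


def run_virtual_screen(
    bio_config: BioSynthConfig | None = None,
    library_size: int = 400,
    k: int = 30,
    unavailable_rate: float = 0.05,
    precipitate_rate: float = 0.1,
    seed: int = 0,
    feature_config: FeatureConfig | None = None,
    force_unavailable: tuple[str, ...] = (),
    force_insoluble: tuple[str, ...] = (),
) -> PipelineResult:
    """Run the whole screen on synthetic data and return all artifacts."""
    bio_config = bio_config or BioSynthConfig(seed=seed)
    fc = feature_config or FeatureConfig(mode="precomputed")
    records = generate_bioactivity_dataset(bio_config)
    library = generate_screening_library(
        library_size,
        unavailable_rate=unavailable_rate,
        precipitate_rate=precipitate_rate,
        seed=seed + 1,
        n_latent_features=bio_config.n_latent_features,
        force_unavailable=force_unavailable,
        force_insoluble=force_insoluble,
    )
    models, cvs, ranked = {}, {}, {}
    for cls in ("FA", "BA"):
        model, cv = train_class_model(records, cls, fc, seed=seed)
        models[cls], cvs[cls] = model, cv
        ranked[cls] = rank_library(model, library, fc)
    candidates = select_candidates(ranked["FA"], ranked["BA"], k=k)
    report = apply_practical_filters(candidates, library)
    return PipelineResult(
        cv_reports=cvs, models=models, ranked=ranked, candidates=candidates, report=report
    )
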
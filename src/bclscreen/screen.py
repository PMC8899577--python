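"""Virtual-screen triage: rank, select top-k per model, apply practical filters.

Two class models (FA: functional cell-based assays; BA: biochemical binding
assays) each rank the library by averaged active-class probability; the
top-k of each are pooled, then candidates are removed for vendor
unavailability and for precipitation when reconstituted in DMSO — in that
order, with per-stage counts recorded so the bookkeeping (e.g.
60 → 57 → 49) always reconciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import InputError
from .qsar import FeatureConfig, SoftVotingEnsemble, featurize_dataset

logger = logging.getLogger(__name__)

__all__ = ["SelectionReport", "rank_library", "select_candidates", "apply_practical_filters"]


def rank_library(
    model: SoftVotingEnsemble,
    library: pd.DataFrame,
    feature_config: FeatureConfig,
) -> pd.DataFrame:
    """Library ranked by predicted active probability, descending.

    Ties break lexicographically on compound_id, so the ranking is
    deterministic and invariant to input row order.
    """
    if len(library) == 0:
        return pd.DataFrame(columns=["compound_id", "probability"])
    if library["compound_id"].duplicated().any():
        raise InputError("library compound_ids must be unique")
    X, kept, skipped = featurize_dataset(library, feature_config)
    proba = model.predict_proba_active(X)
    out = pd.DataFrame(
        {"compound_id": kept["compound_id"].to_numpy(), "probability": proba}
    )
    out = out.sort_values(
        ["probability", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def select_candidates(
    ranked_fa: pd.DataFrame, ranked_ba: pd.DataFrame, k: int = 30
) -> pd.DataFrame:
    """Union of the top-k compounds from each model's ranking.

    Candidates are deduplicated by compound_id and tagged with the model(s)
    that selected them ("FA", "BA" or "FA+BA"). If a ranking is shorter than
    k the whole list is used, with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    tops = {}
    for name, ranked in (("FA", ranked_fa), ("BA", ranked_ba)):
        if k > len(ranked):
            logger.warning("k=%d exceeds %s ranking length %d; using all", k, name, len(ranked))
        tops[name] = list(ranked["compound_id"].head(k))
    sources: dict[str, list[str]] = {}
    for name in ("FA", "BA"):
        for cid in tops[name]:
            sources.setdefault(cid, []).append(name)
    rows = [
        {"compound_id": cid, "source_models": "+".join(mods)}
        for cid, mods in sources.items()
    ]
    return pd.DataFrame(rows).sort_values("compound_id").reset_index(drop=True)


@dataclass(frozen=True)
class SelectionReport:
    """Per-stage survival counts for the candidate triage."""

    n_candidates: int
    removed_unavailable: tuple[str, ...]
    removed_insoluble: tuple[str, ...]
    final_candidates: pd.DataFrame

    @property
    def n_after_availability(self) -> int:
        return self.n_candidates - len(self.removed_unavailable)

    @property
    def n_final(self) -> int:
        return len(self.final_candidates)

    def reconciles(self) -> bool:
        return (
            self.n_candidates
            - len(self.removed_unavailable)
            - len(self.removed_insoluble)
            == self.n_final
        )


def apply_practical_filters(
    candidates: pd.DataFrame, library: pd.DataFrame
) -> SelectionReport:
    """Remove vendor-unavailable, then DMSO-precipitating candidates.

    A compound failing both checks is counted once, at the first failing
    stage (availability). Every candidate must exist in the library.
    """
    lib = library.set_index("compound_id")
    missing = [c for c in candidates["compound_id"] if c not in lib.index]
    if missing:
        raise InputError(f"candidates missing from library: {missing}")
    flags = lib.loc[candidates["compound_id"], ["available", "soluble_in_dmso"]]
    unavailable = tuple(flags.index[~flags["available"]])
    remaining = flags[flags["available"]]
    insoluble = tuple(remaining.index[~remaining["soluble_in_dmso"]])
    removed = set(unavailable) | set(insoluble)
    final = candidates[~candidates["compound_id"].isin(removed)].reset_index(drop=True)
    return SelectionReport(
        n_candidates=len(candidates),
        removed_unavailable=unavailable,
        removed_insoluble=insoluble,
        final_candidates=final,
    )
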
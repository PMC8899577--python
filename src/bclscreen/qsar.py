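"""Hybrid-feature soft-voting QSAR models with cross-validated reporting.

The classifier is a committee of diverse base learners (regularized logistic
regression, random forest, gradient-boosted trees by default) whose
active-class probabilities are averaged ("soft voting"); the decision
threshold on the averaged probability is 0.5, while ranking downstream uses
the raw probability. Features are "hybrid": a molecular fingerprint
concatenated with physicochemical descriptors (toolkit mode, via RDKit), or
precomputed per-compound vectors (e.g. the synthetic generator's latent
features). Model quality is reported as stratified cross-validated accuracy
and Matthews correlation coefficient (MCC), the balanced metric used for
model selection in virtual-screening work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "CVReport",
    "RegressionReport",
    "SoftVotingEnsemble",
    "featurize",
    "featurize_dataset",
    "soft_vote",
    "mcc",
    "cross_validate",
    "fit_regression_qsar",
    "default_learners",
]

DEFAULT_DESCRIPTORS = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "RingCount",
    "FractionCSP3",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Hybrid-feature layout: fingerprint bits + named descriptors.

    mode="toolkit" computes Morgan fingerprints and RDKit descriptors from
    SMILES; mode="precomputed" reads per-compound feature columns (prefix
    ``feature_prefix``) straight from the table — used when structures are
    placeholders and the signal lives in latent features.
    """

    fp_bits: int = 2048
    fp_radius: int = 2
    descriptors: tuple[str, ...] = DEFAULT_DESCRIPTORS
    mode: str = "toolkit"
    feature_prefix: str = "f"

    def __post_init__(self) -> None:
        if self.fp_bits <= 0:
            raise InputError("fp_bits must be > 0")
        if self.mode not in ("toolkit", "precomputed"):
            raise InputError(f"unknown feature mode {self.mode!r}")

    @property
    def n_features(self) -> int:
        return self.fp_bits + len(self.descriptors)


def featurize(smiles: str, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Fingerprint bits concatenated with descriptor values for one SMILES.

    Deterministic for a given molecule: equivalent SMILES notations yield
    identical vectors because RDKit canonicalizes on parse. Raises
    :class:`InputError` on unparsable input; batch callers should use
    :func:`featurize_dataset`, which skips and logs instead.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import Descriptors, rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.fp_radius, fpSize=config.fp_bits
    )
    fp = np.array(gen.GetFingerprint(mol), dtype=float)
    desc = np.array(
        [getattr(Descriptors, name)(mol) for name in config.descriptors], dtype=float
    )
    return np.concatenate([fp, desc])


def featurize_dataset(
    table: pd.DataFrame, config: FeatureConfig = FeatureConfig()
) -> tuple[np.ndarray, pd.DataFrame, list[tuple[str, str]]]:
    """Feature matrix for a table of compounds.

    Returns ``(X, kept_rows, skipped)`` where ``skipped`` lists
    (compound_id, reason) for records that could not be featurized; skips
    are logged, never silent.
    """
    skipped: list[tuple[str, str]] = []
    if config.mode == "precomputed":
        cols = sorted(
            (c for c in table.columns if c.startswith(config.feature_prefix) and c[len(config.feature_prefix):].isdigit()),
            key=lambda c: int(c[len(config.feature_prefix):]),
        )
        if not cols:
            raise InputError("no precomputed feature columns found")
        return table[cols].to_numpy(float), table, skipped
    rows, keep_idx = [], []
    for idx, rec in table.iterrows():
        try:
            rows.append(featurize(rec["smiles"], config))
            keep_idx.append(idx)
        except InputError as exc:
            reason = str(exc)
            skipped.append((str(rec.get("compound_id", idx)), reason))
            logger.warning("skipping %s: %s", rec.get("compound_id", idx), reason)
    if not rows:
        raise InputError("no featurizable records")
    return np.vstack(rows), table.loc[keep_idx], skipped


def soft_vote(probabilities, weights=None) -> float:
    """Weighted arithmetic mean of per-learner active-class probabilities."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise InputError("need at least one learner probability")
    if np.any((p < 0) | (p > 1)):
        raise InputError("probabilities must lie in [0, 1]")
    if weights is None:
        return float(p.mean(axis=0))
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != p.shape[0] or np.any(w < 0):
        raise InputError("weights must be non-negative, one per learner")
    if not np.isclose(w.sum(), 1.0):
        raise InputError("weights must sum to 1")
    return float(np.tensordot(w, p, axes=(0, 0)))


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from a 2x2 confusion table.

    Returns 0 when any marginal is empty (degenerate predictions or labels),
    the standard convention for the undefined 0/0 case.
    """
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise InputError("confusion counts must be non-negative")
    if sum(counts) == 0:
        raise InputError("confusion table is empty")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def default_learners() -> list[tuple[str, object]]:
    """The default diverse committee for soft voting.

    Logistic regression is wrapped in a scaler fitted per training fold so
    descriptor standardization never leaks test information.
    """
    return [
        (
            "logreg",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", LogisticRegression(max_iter=2000, C=1.0)),
                ]
            ),
        ),
        ("rf", RandomForestClassifier(n_estimators=200, random_state=0)),
        ("gboost", HistGradientBoostingClassifier(random_state=0)),
    ]


class SoftVotingEnsemble:
    """Soft-voting committee over sklearn-style probabilistic classifiers."""

    def __init__(self, learners=None, weights=None, threshold: float = 0.5):
        self.learners = learners if learners is not None else default_learners()
        if len(self.learners) < 2:
            raise InputError("a voting committee needs >= 2 base learners")
        if weights is not None:
            w = np.asarray(weights, float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise InputError("weights must be non-negative and sum to 1")
        self.weights = weights
        self.threshold = threshold
        self.fitted_: list[tuple[str, object]] | None = None

    def fit(self, X, y) -> "SoftVotingEnsemble":
        y = np.asarray(y)
        self.fitted_ = [(name, clone(est).fit(X, y)) for name, est in self.learners]
        return self

    def predict_proba_active(self, X) -> np.ndarray:
        if self.fitted_ is None:
            raise InputError("ensemble is not fitted")
        per_learner = np.vstack(
            [est.predict_proba(X)[:, 1] for _, est in self.fitted_]
        )
        return np.array(
            [soft_vote(per_learner[:, j], self.weights) for j in range(per_learner.shape[1])]
        )

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba_active(X) >= self.threshold).astype(int)

    def fresh(self) -> "SoftVotingEnsemble":
        """Unfitted copy with the same committee specification."""
        return SoftVotingEnsemble(
            learners=[(n, clone(e)) for n, e in self.learners],
            weights=self.weights,
            threshold=self.threshold,
        )


@dataclass(frozen=True)
class CVReport:
    """Stratified k-fold cross-validation summary."""

    fold_accuracy: tuple[float, ...]
    fold_mcc: tuple[float, ...]
    n_folds: int
    seed: int
    mean_accuracy: float = field(init=False)
    mean_mcc: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_accuracy", float(np.mean(self.fold_accuracy)))
        object.__setattr__(self, "mean_mcc", float(np.mean(self.fold_mcc)))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    ensemble: SoftVotingEnsemble | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV of a soft-voting ensemble; each row scored once.

    Deterministic given the seed (fold shuffling and any learner randomness
    are all seeded).
    """
    y = np.asarray(y).astype(int)
    X = np.asarray(X, float)
    class_sizes = np.bincount(y)
    if np.any(class_sizes[class_sizes > 0] < n_folds):
        raise InputError("fold count exceeds the smallest class size")
    base = ensemble if ensemble is not None else SoftVotingEnsemble()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, mccs = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = base.fresh().fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        tp, tn, fp, fn = _confusion(y[test_idx], pred)
        accs.append((tp + tn) / len(test_idx))
        mccs.append(mcc(tp, tn, fp, fn))
    return CVReport(tuple(accs), tuple(mccs), n_folds, seed)


@dataclass(frozen=True)
class RegressionReport:
    """Cross-validated regression quality in pAffinity units."""

    r2: float
    rmse: float
    n_folds: int


def fit_regression_qsar(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = 1e-3,
):
    """Companion regression model predicting pAffinity from hybrid features.

    A standardized ridge regression, cross-validated with k-fold (out-of-fold
    R^2 and RMSE pooled over all rows); the returned model is refitted on the
    full data.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(y) < 10:
        raise InputError("need >= 10 rows to fit a regression model")
    if np.ptp(y) == 0:
        raise InputError("constant response vector")
    model = Pipeline([("scale", StandardScaler()), ("reg", Ridge(alpha=alpha))])
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, n_folds)
    oof = np.empty_like(y)
    for k in range(n_folds):
        test_idx = folds[k]
        train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != k])
        m = clone(model).fit(X[train_idx], y[train_idx])
        oof[test_idx] = m.predict(X[test_idx])
    ss_res = float(np.sum((y - oof) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    report = RegressionReport(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(ss_res / len(y))),
        n_folds=n_folds,
    )
    return model.fit(X, y), report
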
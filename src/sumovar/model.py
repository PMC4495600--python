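"""Balanced-negative ensemble of RBF-kernel classifiers.

Ten balanced negative sets are drawn from the (much larger) negative pool,
one soft-margin RBF-kernel SVM with probability outputs is fitted per set,
and the ensemble probability is the unweighted mean over members. Probability
cutoffs for the 70/80/90/95% specificity options are calibrated as empirical
quantiles of out-of-member negative scores; the default cutoff is 0.5.

Persistence uses a JSON manifest plus one array blob per member (the member's
training data; loading refits deterministically) rather than opaque pickles.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import metrics as _metrics
from .seqio import ValidationError

# probability outputs mirror the reference implementation's Platt-scaled
# estimates; sklearn 1.9 deprecates the flag but the replacement changes the
# calibration scheme, so keep it and silence the notice
warnings.filterwarnings(
    "ignore", message=".*probability.*deprecated.*", category=FutureWarning,
    module="sklearn.svm._base",
)

DEFAULT_C = 8.0
DEFAULT_GAMMA = 0.001953
SPECIFICITY_LEVELS = (0.70, 0.80, 0.90, 0.95)
DEFAULT_CUTOFF = 0.5


@dataclass
class TrainConfig:
    C: float = DEFAULT_C
    gamma: float = DEFAULT_GAMMA
    n_negative_sets: int = 10
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    specificity_levels: tuple[float, ...] = SPECIFICITY_LEVELS

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValidationError("C and gamma must be positive")
        if self.folds < 2:
            raise ValidationError("need at least 2 folds")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_svc(config: TrainConfig) -> SVC:
    return SVC(C=config.C, gamma=config.gamma, kernel="rbf",
               probability=True, random_state=config.seed)


def sample_balanced_negatives(
    negatives: Sequence | np.ndarray,
    n_pos: int,
    n_sets: int,
    seed: int,
) -> list[np.ndarray]:
    """Draw ``n_sets`` index sets of size ``n_pos`` from the negative pool.

    Sampling is without replacement within a set; sets are drawn
    independently of each other. Returns arrays of indices into ``negatives``.
    """
    n_neg = len(negatives)
    if n_neg < n_pos:
        raise ValidationError(
            f"negative pool ({n_neg}) smaller than requested set size ({n_pos})"
        )
    rng = np.random.default_rng(seed)
    return [rng.choice(n_neg, size=n_pos, replace=False) for _ in range(n_sets)]


@dataclass
class TrainedEnsemble:
    members: list[SVC]
    feature_names: list[str]
    thresholds: dict[str, float]
    config: TrainConfig
    member_neg_indices: list[np.ndarray]
    member_data: list[tuple[np.ndarray, np.ndarray]]  # (X, y) per member
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Unweighted mean over member probabilities of the positive class."""
        A = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        probs = np.zeros(len(A))
        for clf in self.members:
            pos_col = int(np.where(clf.classes_ == 1)[0][0])
            probs += clf.predict_proba(A)[:, pos_col]
        return probs / len(self.members)

    def cutoff(self, level: str | float = "default") -> float:
        key = "default" if level in ("default", None) else f"{float(level):.2f}"
        if key not in self.thresholds:
            raise ValidationError(f"no cutoff calibrated for level {level!r}")
        return self.thresholds[key]


def train_ensemble(
    pos_X: np.ndarray,
    neg_X: np.ndarray,
    config: TrainConfig,
    feature_names: Sequence[str] | None = None,
    neg_index_sets: list[np.ndarray] | None = None,
) -> TrainedEnsemble:
    """Fit one RBF-SVM per balanced negative set.

    ``neg_X`` is the full negative pool; each member trains on all positives
    plus its own sampled negatives. Thresholds are calibrated afterwards from
    out-of-member negative scores (see :func:`calibrate_thresholds`).
    """
    pos_X = np.asarray(pos_X, float)
    neg_X = np.asarray(neg_X, float)
    if len(pos_X) == 0 or len(neg_X) == 0:
        raise ValidationError("both classes must be non-empty")
    if neg_index_sets is None:
        neg_index_sets = sample_balanced_negatives(
            neg_X, len(pos_X), config.n_negative_sets, config.seed
        )
    members, data = [], []
    for idx in neg_index_sets:
        X = np.vstack([pos_X, neg_X[idx]])
        y = np.concatenate([np.ones(len(pos_X)), -np.ones(len(idx))])
        clf = make_svc(config)
        clf.fit(X, y)
        members.append(clf)
        data.append((X, y))
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(pos_X.shape[1])
    ]
    ensemble = TrainedEnsemble(
        members=members,
        feature_names=names,
        thresholds={"default": DEFAULT_CUTOFF},
        config=config,
        member_neg_indices=[np.asarray(i) for i in neg_index_sets],
        member_data=data,
        metadata={"seed": config.seed, "config_hash": config.hash()},
    )
    neg_scores = out_of_member_negative_scores(ensemble, neg_X)
    ensemble.thresholds = calibrate_thresholds(neg_scores, config.specificity_levels)
    return ensemble


def out_of_member_negative_scores(ensemble: TrainedEnsemble, neg_X: np.ndarray) -> np.ndarray:
    """Ensemble score for each pool negative using only members that did not
    train on it; negatives seen by every member are dropped."""
    neg_X = np.asarray(neg_X, float)
    n = len(neg_X)
    mask = np.ones((len(ensemble.members), n), dtype=bool)
    for m, idx in enumerate(ensemble.member_neg_indices):
        mask[m, idx] = False
    member_probs = np.empty((len(ensemble.members), n))
    for m, clf in enumerate(ensemble.members):
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        member_probs[m] = clf.predict_proba(neg_X)[:, pos_col]
    counts = mask.sum(axis=0)
    usable = counts > 0
    scores = (member_probs * mask).sum(axis=0)[usable] / counts[usable]
    return scores


def calibrate_thresholds(
    negative_scores: np.ndarray,
    levels: Sequence[float] = SPECIFICITY_LEVELS,
) -> dict[str, float]:
    """Cutoff(s) = nearest-rank s-quantile of held-out negative scores, so the
    fraction of negatives called positive is at most 1 - s. The default level
    is fixed at 0.5. Cutoffs are made non-decreasing in the level."""
    scores = np.asarray(negative_scores, float)
    if scores.size == 0:
        raise ValidationError("no negative scores to calibrate on")
    thresholds = {"default": DEFAULT_CUTOFF}
    prev = -np.inf
    for s in sorted(levels):
        cut = float(np.quantile(scores, s, method="higher"))
        cut = max(cut, prev)
        thresholds[f"{s:.2f}"] = cut
        prev = cut
    return thresholds


def cross_validate(
    pos_X: np.ndarray,
    neg_sets: Sequence[np.ndarray],
    config: TrainConfig,
    repeats: int | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Repeated stratified k-fold cross-validation, one run per negative set.

    Returns a tidy per-(member, repeat, fold) metric table plus the pooled
    out-of-fold scores and labels (usable for threshold calibration). Fold
    assignment is deterministic in ``config.seed``.
    """
    pos_X = np.asarray(pos_X, float)
    repeats = config.repeats if repeats is None else repeats
    records = []
    oof_scores, oof_labels = [], []
    for m, neg in enumerate(neg_sets):
        neg = np.asarray(neg, float)
        X = np.vstack([pos_X, neg])
        y = np.concatenate([np.ones(len(pos_X)), -np.ones(len(neg))])
        if config.folds > min(len(pos_X), len(neg)):
            raise ValidationError("more folds than instances in a class")
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                                  random_state=config.seed + 1000 * r + m)
            for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
                clf = make_svc(config)
                clf.fit(X[train_idx], y[train_idx])
                pos_col = int(np.where(clf.classes_ == 1)[0][0])
                p = clf.predict_proba(X[test_idx])[:, pos_col]
                counts = _metrics.confusion_from_scores(p, y[test_idx], DEFAULT_CUTOFF)
                records.append({
                    "member": m, "repeat": r, "fold": k,
                    "Ac": _metrics.accuracy(counts),
                    "Sn": _metrics.sensitivity(counts),
                    "Sp": _metrics.specificity(counts),
                    "MCC": _metrics.mcc(counts),
                    "AUC": _metrics.roc_auc(p, y[test_idx]),
                })
                if r == 0:
                    oof_scores.append(p)
                    oof_labels.append(y[test_idx])
    table = pd.DataFrame.from_records(records)
    oof = {
        "scores": np.concatenate(oof_scores),
        "labels": np.concatenate(oof_labels),
    }
    return table, oof


def summarize_cv(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each metric over all folds."""
    cols = ["Ac", "Sn", "Sp", "MCC", "AUC"]
    return pd.DataFrame({"mean": table[cols].mean(), "sd": table[cols].std()})


@dataclass
class PredictionResult:
    fragment_index: int
    probability: float
    calls: dict[str, bool]


def predict(ensemble: TrainedEnsemble, X: np.ndarray | pd.DataFrame) -> list[PredictionResult]:
    """Score fragments and call them at every calibrated specificity level.

    A fragment positive at level s is positive at all lower levels because
    cutoffs are non-decreasing in s.
    """
    probs = ensemble.predict_proba(X)
    results = []
    for i, p in enumerate(probs):
        calls = {lvl: bool(p >= cut) for lvl, cut in ensemble.thresholds.items()}
        results.append(PredictionResult(i, float(p), calls))
    return results


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: TrainedEnsemble, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "sumovar-ensemble/1",
        "config": asdict(ensemble.config),
        "feature_names": ensemble.feature_names,
        "thresholds": ensemble.thresholds,
        "metadata": ensemble.metadata,
        "n_members": len(ensemble.members),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    for m, ((X, y), idx) in enumerate(zip(ensemble.member_data,
                                          ensemble.member_neg_indices)):
        np.savez(directory / f"member_{m}.npz", X=X, y=y, neg_indices=idx)


def load_ensemble(directory: str | Path) -> TrainedEnsemble:
    """Reload an ensemble by refitting each member on its stored training
    data — deterministic, and avoids pickled estimators entirely."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    cfg["specificity_levels"] = tuple(cfg["specificity_levels"])
    config = TrainConfig(**cfg)
    members, data, neg_indices = [], [], []
    for m in range(manifest["n_members"]):
        blob = np.load(directory / f"member_{m}.npz")
        clf = make_svc(config)
        clf.fit(blob["X"], blob["y"])
        members.append(clf)
        data.append((blob["X"], blob["y"]))
        neg_indices.append(blob["neg_indices"])
    return TrainedEnsemble(
        members=members,
        feature_names=list(manifest["feature_names"]),
        thresholds={k: float(v) for k, v in manifest["thresholds"].items()},
        config=config,
        member_neg_indices=neg_indices,
        member_data=data,
        metadata=manifest["metadata"],
    )
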
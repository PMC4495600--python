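"""Fragment feature encoders, F-score ranking and forward wrapper selection.

Five encoder families are available: physicochemical properties, k-spaced
amino-acid pair composition (CKSAAP), secondary structure, accessible surface
area and PSSM profiles. The exact feature composition is configurable per
encoder; ranking plus wrapper selection reconciles whatever combination is
chosen. Encoders that need external per-protein annotations (PSSM, structure)
degrade gracefully to sequence-only mode when those inputs are absent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .seqio import (AMINO_ACIDS, PAD, Fragment, FragmentLabel, ParseError,
                    ValidationError)

logger = logging.getLogger(__name__)

#: window offsets for a flank-10 fragment, left to right
def window_offsets(flank: int) -> list[int]:
    return list(range(-flank, flank + 1))


# ---------------------------------------------------------------------------
# Property table
# ---------------------------------------------------------------------------

class PropertyTable:
    """Residue -> vector of named physicochemical property values.

    'X' (padding/unknown) maps to the all-zero vector.
    """

    def __init__(self, values: dict[str, np.ndarray], names: Sequence[str],
                 standardize: bool = False) -> None:
        missing = set(AMINO_ACIDS) - set(values)
        if missing:
            raise ValidationError(f"property table missing residues {sorted(missing)}")
        if len(set(names)) != len(names):
            raise ValidationError("property names must be unique")
        self.names = list(names)
        self._values = {aa: np.asarray(v, dtype=float) for aa, v in values.items()}
        if standardize:
            # z-score each property across the 20 residues so raw scales
            # (mass vs charge) contribute comparably to kernel distances
            arr = np.array([self._values[aa] for aa in AMINO_ACIDS])
            mu, sd = arr.mean(axis=0), arr.std(axis=0)
            sd[sd == 0] = 1.0
            self._values = {aa: (v - mu) / sd for aa, v in self._values.items()}
        self._values[PAD] = np.zeros(len(self.names))

    @classmethod
    def default(cls) -> "PropertyTable":
        with resources.files("sumovar.data").joinpath("physchem.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col="residue")
        return cls({aa: df.loc[aa].to_numpy() for aa in df.index},
                   list(df.columns), standardize=True)

    def vector(self, residue: str) -> np.ndarray:
        try:
            return self._values[residue]
        except KeyError:
            raise ValidationError(f"residue {residue!r} missing from property table")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class PSSMProfile:
    """Per-position substitution scores for one protein (rows x 20)."""

    protein_id: str
    scores: np.ndarray  # shape (sequence length, 20), column order AMINO_ACIDS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError("PSSM must have 20 score columns")


@dataclass
class StructureAnnotation:
    """Per-residue accessible surface area and secondary-structure class."""

    protein_id: str
    asa: np.ndarray      # non-negative, length = sequence length
    ss: str              # string over {H, E, C}, same length

    def __post_init__(self) -> None:
        self.asa = np.asarray(self.asa, dtype=float)
        if len(self.asa) != len(self.ss):
            raise ValidationError("ASA and SS annotations must have equal length")
        if (self.asa < 0).any():
            raise ValidationError("ASA values must be non-negative")
        bad = set(self.ss) - set("HEC")
        if bad:
            raise ValidationError(f"unknown secondary-structure classes {sorted(bad)}")


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSMProfile:
    """Read a PSI-BLAST ASCII-dialect PSSM.

    Lines are scanned for rows of the form ``<index> <residue> <20+ numbers>``;
    header and trailing statistics lines are ignored. Only the first 20 numeric
    columns (the log-odds scores) are kept.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
                try:
                    rows.append([float(x) for x in parts[2:22]])
                except ValueError:
                    continue
    if not rows:
        raise ParseError(f"no PSSM rows found in {path}")
    return PSSMProfile(protein_id or path.stem, np.array(rows))


def read_structure(path: str | Path, protein_id: str | None = None) -> StructureAnnotation:
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    return StructureAnnotation(
        protein_id or Path(path).stem,
        df["asa"].to_numpy(float),
        "".join(df["ss"]),
    )


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def encode_physchem(fragment: Fragment, table: PropertyTable) -> np.ndarray:
    """Concatenate per-position property vectors over the window ('X' -> zeros)."""
    return np.concatenate([table.vector(aa) for aa in fragment.residues])


def physchem_feature_names(flank: int, table: PropertyTable) -> list[str]:
    return [f"pc|{off:+d}|{name}" for off in window_offsets(flank) for name in table.names]


#: fixed order of the 400 residue pairs used by the CKSAAP encoding
AA_PAIRS = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
_PAIR_INDEX = {p: i for i, p in enumerate(AA_PAIRS)}


def encode_cksaap(fragment: Fragment, k_set: Sequence[int] = (0, 1, 2, 3, 4)) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs.

    For each k the 400 pair counts (pairs involving the padding 'X' are
    ignored) are normalized by the number of positions, L - k - 1.
    """
    s = fragment.residues
    L = len(s)
    out = np.zeros(400 * len(k_set))
    for ki, k in enumerate(k_set):
        if k >= L - 1:
            raise ValidationError(f"k={k} too large for fragment length {L}")
        denom = L - k - 1
        base = 400 * ki
        for i in range(denom):
            a, b = s[i], s[i + k + 1]
            if a == PAD or b == PAD:
                continue
            out[base + _PAIR_INDEX[a + b]] += 1.0
        out[base:base + 400] /= denom
    return out


def cksaap_feature_names(k_set: Sequence[int] = (0, 1, 2, 3, 4)) -> list[str]:
    return [f"cksaap|k{k}|{pair}" for k in k_set for pair in AA_PAIRS]


SS_CLASSES = "HEC"


def encode_ss(fragment: Fragment, annotation: StructureAnnotation) -> np.ndarray:
    """One-hot secondary structure per window position; padding -> all-zero."""
    flank = fragment.flank
    out = np.zeros(3 * (2 * flank + 1))
    for j, off in enumerate(window_offsets(flank)):
        pos = fragment.center_pos + off
        if 1 <= pos <= len(annotation.ss):
            out[3 * j + SS_CLASSES.index(annotation.ss[pos - 1])] = 1.0
    return out


def ss_feature_names(flank: int) -> list[str]:
    return [f"ss|{off:+d}|{c}" for off in window_offsets(flank) for c in SS_CLASSES]


def encode_aasa(fragment: Fragment, annotation: StructureAnnotation) -> np.ndarray:
    """Per-position accessible surface area plus the window mean."""
    flank = fragment.flank
    vals = np.zeros(2 * flank + 1)
    inside = []
    for j, off in enumerate(window_offsets(flank)):
        pos = fragment.center_pos + off
        if 1 <= pos <= len(annotation.asa):
            vals[j] = annotation.asa[pos - 1]
            inside.append(vals[j])
    mean = float(np.mean(inside)) if inside else 0.0
    return np.concatenate([vals, [mean]])


def aasa_feature_names(flank: int) -> list[str]:
    return [f"asa|{off:+d}" for off in window_offsets(flank)] + ["asa|mean"]


def encode_pssm(fragment: Fragment, profile: PSSMProfile) -> np.ndarray:
    """Window of PSSM score rows flattened row-major; padding rows are zero."""
    flank = fragment.flank
    out = np.zeros((2 * flank + 1, 20))
    n = profile.scores.shape[0]
    for j, off in enumerate(window_offsets(flank)):
        pos = fragment.center_pos + off
        if 1 <= pos <= n:
            out[j] = profile.scores[pos - 1]
    return out.ravel()


def pssm_feature_names(flank: int) -> list[str]:
    return [f"pssm|{off:+d}|{aa}" for off in window_offsets(flank) for aa in AMINO_ACIDS]


# ---------------------------------------------------------------------------
# Feature matrix assembly
# ---------------------------------------------------------------------------

#: stable registry order for concatenating encoder families
ENCODER_ORDER = ("physchem", "cksaap", "ss", "aasa", "pssm")


@dataclass
class EncoderConfig:
    """Which encoder families to apply and their inputs.

    ``pssm_profiles`` and ``structures`` map protein_id to the corresponding
    annotation objects; fragments from proteins missing an annotation cause
    the encoder family to be skipped for the whole matrix (with a logged
    warning) unless ``strict`` is set, in which case an error is raised.
    """

    families: Sequence[str] = ("physchem", "cksaap")
    property_table: PropertyTable | None = None
    k_set: Sequence[int] = (0, 1, 2, 3, 4)
    pssm_profiles: dict[str, PSSMProfile] = field(default_factory=dict)
    structures: dict[str, StructureAnnotation] = field(default_factory=dict)
    strict: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(ENCODER_ORDER)
        if unknown:
            raise ValidationError(f"unknown encoder families {sorted(unknown)}")
        if self.property_table is None:
            self.property_table = PropertyTable.default()


@dataclass
class FeatureMatrix:
    """Encoded fragments: X (n x p), named columns and +1/-1 labels."""

    X: pd.DataFrame
    y: np.ndarray  # +1 / -1; 0 for unlabeled fragments

    def __post_init__(self) -> None:
        if len(set(self.X.columns)) != self.X.shape[1]:
            raise ValidationError("feature names must be unique")
        if np.isnan(self.X.to_numpy()).any():
            raise ValidationError("feature matrix contains missing values")

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == -1).sum())


_LABEL_TO_Y = {FragmentLabel.POSITIVE: 1, FragmentLabel.NEGATIVE: -1,
               FragmentLabel.UNLABELED: 0}


def assemble(fragments: Sequence[Fragment], config: EncoderConfig | None = None) -> FeatureMatrix:
    """Encode fragments with the configured families, concatenated in the
    stable registry order, and record column provenance in the names."""
    if config is None:
        config = EncoderConfig()
    if not fragments:
        raise ValidationError("no fragments to encode")
    flank = fragments[0].flank

    active = [f for f in ENCODER_ORDER if f in config.families]
    for fam, store in (("pssm", config.pssm_profiles),
                       ("ss", config.structures), ("aasa", config.structures)):
        if fam in active:
            missing = {f.protein_id for f in fragments} - set(store)
            if missing:
                msg = (f"{fam} encoder: no annotation for proteins "
                       f"{sorted(missing)[:5]}...")
                if config.strict:
                    raise ValidationError(msg)
                logger.warning("%s; encoder skipped", msg)
                active = [f for f in active if f != fam]

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for fam in active:
        if fam == "physchem":
            blocks.append(np.array([encode_physchem(f, config.property_table)
                                    for f in fragments]))
            names += physchem_feature_names(flank, config.property_table)
        elif fam == "cksaap":
            blocks.append(np.array([encode_cksaap(f, config.k_set) for f in fragments]))
            names += cksaap_feature_names(config.k_set)
        elif fam == "ss":
            blocks.append(np.array([encode_ss(f, config.structures[f.protein_id])
                                    for f in fragments]))
            names += ss_feature_names(flank)
        elif fam == "aasa":
            blocks.append(np.array([encode_aasa(f, config.structures[f.protein_id])
                                    for f in fragments]))
            names += aasa_feature_names(flank)
        elif fam == "pssm":
            blocks.append(np.array([encode_pssm(f, config.pssm_profiles[f.protein_id])
                                    for f in fragments]))
            names += pssm_feature_names(flank)
    X = pd.DataFrame(np.hstack(blocks), columns=names)
    y = np.array([_LABEL_TO_Y[f.label] for f in fragments])
    return FeatureMatrix(X, y)


# ---------------------------------------------------------------------------
# F-score
# ---------------------------------------------------------------------------

def fscore(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature class-separation F-score.

    F_i = [(mean_i+ - mean_i)^2 + (mean_i- - mean_i)^2] /
          [var_i+ * (unbiased, positives) + var_i- (unbiased, negatives)]

    A feature with zero within-class variance in both classes gets F = 0 when
    the numerator is also 0, and +inf (perfect separator, ranked first)
    otherwise. Requires at least two instances per class.
    """
    A = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y)
    pos, neg = A[y == 1], A[y == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("F-score needs at least two instances per class")
    mean_all = A[(y == 1) | (y == -1)].mean(axis=0)
    num = (pos.mean(axis=0) - mean_all) ** 2 + (neg.mean(axis=0) - mean_all) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    out = np.empty(A.shape[1])
    zero_den = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero_den, np.where(num == 0, 0.0, np.inf), num / np.where(zero_den, 1.0, den))
    return out


def fscore_averaged(matrices: Sequence[FeatureMatrix]) -> pd.Series:
    """Mean of per-set F-scores across balanced training sets.

    All matrices must share the same columns. Infinite per-set scores stay
    infinite in the mean.
    """
    cols = list(matrices[0].X.columns)
    for m in matrices[1:]:
        if list(m.X.columns) != cols:
            raise ValidationError("matrices must share identical columns")
    scores = np.mean([fscore(m.X, m.y) for m in matrices], axis=0)
    return pd.Series(scores, index=cols)


# ---------------------------------------------------------------------------
# Forward wrapper selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionStep:
    feature: str
    fscore: float
    mean_accuracy: float
    kept: bool


@dataclass
class SelectionResult:
    ranked: pd.Series              # F-scores, descending rank order
    retained: list[str]
    trace: list[SelectionStep]

    @property
    def accuracy_trace(self) -> list[float]:
        return [s.mean_accuracy for s in self.trace if s.kept]


#: minimum improvement in mean CV accuracy for a feature to be retained
IMPROVEMENT_TOL = 1e-9


def rank_features(scores: pd.Series) -> pd.Series:
    """Stable descending order by (-F, column name)."""
    order = sorted(scores.index, key=lambda c: (-scores[c], c))
    return scores.loc[order]


def forward_select(
    matrix: FeatureMatrix,
    trainer: Callable[[], object],
    folds: int = 10,
    seed: int = 0,
    scores: pd.Series | None = None,
    max_features: int | None = None,
    repeats: int = 3,
) -> SelectionResult:
    """Forward best-first wrapper selection over the F-score ranking.

    Features are examined in descending (averaged) F-score order; a feature is
    retained iff adding it strictly improves the mean cross-validated accuracy
    (tolerance 1e-9). The accuracy is averaged over ``repeats`` independent
    fold shuffles, mirroring the repeated-CV training design and damping the
    chance acceptance of uninformative features. ``trainer`` is a factory
    returning a fresh classifier with sklearn fit/predict semantics.
    ``max_features`` limits how many top-ranked features are examined (all by
    default).
    """
    if matrix.X.shape[1] < 2:
        raise ValidationError("need at least two features to select from")
    if scores is None:
        scores = pd.Series(fscore(matrix.X, matrix.y), index=matrix.X.columns)
    ranked = rank_features(scores)
    candidates = list(ranked.index)
    if max_features is not None:
        candidates = candidates[:max_features]

    y = matrix.y
    splits = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        splits.extend(skf.split(matrix.X, y))

    def cv_accuracy(cols: list[str]) -> float:
        A = matrix.X[cols].to_numpy()
        accs = []
        for train_idx, test_idx in splits:
            clf = trainer()
            clf.fit(A[train_idx], y[train_idx])
            accs.append(float(np.mean(clf.predict(A[test_idx]) == y[test_idx])))
        return float(np.mean(accs))

    # baseline: majority-class accuracy of the trivial classifier
    best = max(np.mean(y == 1), np.mean(y == -1))
    retained: list[str] = []
    trace: list[SelectionStep] = []
    for feat in candidates:
        acc = cv_accuracy(retained + [feat])
        keep = acc > best + IMPROVEMENT_TOL
        if keep:
            retained.append(feat)
            best = acc
        trace.append(SelectionStep(feat, float(ranked[feat]), acc, keep))
    return SelectionResult(ranked=ranked, retained=retained, trace=trace)
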
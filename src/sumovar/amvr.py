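"""Classification of amino-acid variants by their effect on sumoylation.

A variant is compared between the wild-type and mutant sequence and assigned
one of five types, with the decision rules applied in a fixed order:

1. the variant removes a sumoylated lysine itself            -> Type I(-)
2. the variant creates a lysine that is sumoylated in the
   mutant at that very position                               -> Type I(+)
3. otherwise, every lysine whose window (+-flank) covers the
   variant is inspected: site gained -> II(+); site lost ->
   II(-); site positive before and after (with the window
   sequence necessarily changed)   -> Type III; no change -> no call.

Types are mutually exclusive per (variant, lysine) pair. When several
lysines are affected, the call with the largest probability shift is
reported and all candidates are kept for audit. A fifth type (IV, a change
in the kind of modification) exists in the enum for forward compatibility
but is never emitted.

Two status oracles are supported: a :class:`SitePair` of annotated wild-type
and mutant site sets (annotation-driven, used for curated tables and
ground-truth checks) or a trained predictor (model-driven, thresholded at a
chosen specificity level). Annotated sites take precedence over predictions
when both are supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .features import EncoderConfig, assemble
from .model import TrainedEnsemble
from .seqio import (DEFAULT_FLANK, Evidence, Fragment, FragmentLabel,
                    ProteinRecord, SiteTable, ValidationError, VariantRecord,
                    apply_variant, extract_fragment, parse_variant_token)

logger = logging.getLogger(__name__)


class AMVRType(str, Enum):
    I_PLUS = "I+"
    I_MINUS = "I-"
    II_PLUS = "II+"
    II_MINUS = "II-"
    III = "III"
    IV = "IV"          # defined for forward compatibility, never emitted
    NONE = "none"


#: column order used in sweep reports
SWEEP_TYPES = (AMVRType.I_PLUS, AMVRType.I_MINUS, AMVRType.II_PLUS,
               AMVRType.II_MINUS, AMVRType.III)


@dataclass(frozen=True)
class SitePair:
    """Annotated sumoylated positions before and after the substitution."""

    wt: frozenset[int]
    mut: frozenset[int]

    @classmethod
    def of(cls, wt: Sequence[int], mut: Sequence[int]) -> "SitePair":
        return cls(frozenset(wt), frozenset(mut))


@dataclass(frozen=True)
class SiteCandidate:
    position: int
    wt_on: bool
    mut_on: bool
    wt_probability: float | None = None
    mut_probability: float | None = None

    @property
    def delta(self) -> float:
        if self.wt_probability is None or self.mut_probability is None:
            return float(self.mut_on != self.wt_on)
        return abs(self.mut_probability - self.wt_probability)


@dataclass
class AMVRCall:
    variant: VariantRecord
    type: AMVRType
    affected_site: int | None = None
    wt_probability: float | None = None
    mut_probability: float | None = None
    specificity_level: str = "default"
    evidence: Evidence = Evidence.PREDICTED
    candidates: list[SiteCandidate] = field(default_factory=list)


class SequencePredictor:
    """Adapter scoring arbitrary (sequence, position) pairs with an ensemble.

    Only sequence-derived encoders can be evaluated on mutant sequences, so
    the encoder configuration must not require external per-protein profiles
    unless they cover every scored protein.
    """

    def __init__(self, ensemble: TrainedEnsemble, encoder: EncoderConfig | None = None,
                 flank: int = DEFAULT_FLANK) -> None:
        self.ensemble = ensemble
        self.encoder = encoder or EncoderConfig()
        self.flank = flank

    def probabilities(self, record: ProteinRecord, positions: Sequence[int]) -> dict[int, float]:
        if not positions:
            return {}
        frags = [extract_fragment(record.sequence, p, self.flank,
                                  protein_id=record.id) for p in positions]
        matrix = assemble(frags, self.encoder)
        if list(matrix.X.columns) != self.ensemble.feature_names:
            matrix_X = matrix.X[self.ensemble.feature_names]
        else:
            matrix_X = matrix.X
        probs = self.ensemble.predict_proba(matrix_X)
        return {p: float(pr) for p, pr in zip(positions, probs)}

    def cutoff(self, level: str | float = "default") -> float:
        return self.ensemble.cutoff(level)


Oracle = SitePair | SequencePredictor


def _window_lysines(sequence: str, center: int, flank: int) -> list[int]:
    """1-based positions of 'K' within +-flank of ``center``, excluding it."""
    lo, hi = max(1, center - flank), min(len(sequence), center + flank)
    return [p for p in range(lo, hi + 1)
            if p != center and sequence[p - 1] == "K"]


def _resolve(candidates: list[SiteCandidate]) -> SiteCandidate | None:
    """Pick the strongest changed-or-retained site: largest probability shift,
    then a status change over none, then proximity-independent position order."""
    scored = [c for c in candidates if c.wt_on or c.mut_on]
    if not scored:
        return None
    return sorted(scored, key=lambda c: (-c.delta, not (c.wt_on != c.mut_on),
                                         c.position))[0]


def classify_variant(
    record: ProteinRecord,
    variant: VariantRecord,
    oracle: Oracle,
    flank: int = DEFAULT_FLANK,
    level: str | float = "default",
    annotated: SiteTable | None = None,
) -> AMVRCall:
    """Assign the SUMOAMVR type of one variant (see module docstring).

    ``annotated`` optionally supplies experimentally annotated wild-type sites
    that override model predictions for the wild-type status.
    """
    mut_record = apply_variant(record, variant)
    vpos = variant.position
    kpos = _window_lysines(record.sequence, vpos, flank)

    if isinstance(oracle, SitePair):
        evidence = Evidence.ANNOTATED
        level_key = "default"
        wt_on = {p: p in oracle.wt for p in kpos + [vpos]}
        mut_on = {p: p in oracle.mut for p in kpos + [vpos]}
        wt_p: dict[int, float] = {}
        mut_p: dict[int, float] = {}
    else:
        evidence = Evidence.PREDICTED
        cut = oracle.cutoff(level)
        level_key = "default" if level == "default" else f"{float(level):.2f}"
        wt_query = kpos + ([vpos] if variant.wt_aa == "K" else [])
        mut_query = kpos + ([vpos] if variant.mut_aa == "K" else [])
        wt_p = oracle.probabilities(record, wt_query)
        mut_p = oracle.probabilities(mut_record, mut_query)
        wt_on = {p: wt_p[p] >= cut for p in wt_query}
        mut_on = {p: mut_p[p] >= cut for p in mut_query}
        if annotated is not None:
            for p in wt_query:
                if (record.id, p) in annotated:
                    wt_on[p] = True

    def call(type_, site, cands):
        return AMVRCall(variant=variant, type=type_, affected_site=site,
                        wt_probability=wt_p.get(site), mut_probability=mut_p.get(site),
                        specificity_level=level_key, evidence=evidence,
                        candidates=cands)

    # rule 1: the sumoylated lysine itself is substituted away
    if variant.wt_aa == "K" and variant.mut_aa != "K" and wt_on.get(vpos, False):
        return call(AMVRType.I_MINUS, vpos, [])
    # rule 2: a new lysine appears and is sumoylated in the mutant
    if variant.mut_aa == "K" and variant.wt_aa != "K" and mut_on.get(vpos, False):
        return call(AMVRType.I_PLUS, vpos, [])

    # rule 3: neighbouring lysines
    candidates = [
        SiteCandidate(position=p, wt_on=wt_on.get(p, False), mut_on=mut_on.get(p, False),
                      wt_probability=wt_p.get(p), mut_probability=mut_p.get(p))
        for p in kpos
    ]
    best = _resolve(candidates)
    if best is None:
        return call(AMVRType.NONE, None, candidates)
    if not best.wt_on and best.mut_on:
        type_ = AMVRType.II_PLUS
    elif best.wt_on and not best.mut_on:
        type_ = AMVRType.II_MINUS
    else:
        # site stays positive while its window sequence changed
        type_ = AMVRType.III
    return call(type_, best.position, candidates)


def classify_batch(
    records: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    variants: Sequence[VariantRecord],
    oracle: SequencePredictor | Callable[[ProteinRecord, VariantRecord], SitePair],
    levels: Sequence[str | float] = ("default",),
    flank: int = DEFAULT_FLANK,
    annotated: SiteTable | None = None,
) -> tuple[dict[str, list[AMVRCall]], "SweepReport"]:
    """Classify a variant table at one or more specificity levels.

    ``oracle`` is either a trained predictor or a callable mapping
    (record, variant) to an annotation :class:`SitePair`. Variants whose
    protein is unknown or whose wild-type residue mismatches are skipped with
    a logged warning.
    """
    by_id = (records if isinstance(records, Mapping)
             else {r.id: r for r in records})
    calls: dict[str, list[AMVRCall]] = {}
    for level in levels:
        level_key = "default" if level == "default" else f"{float(level):.2f}"
        out = []
        for v in variants:
            rec = by_id.get(v.protein_id)
            if rec is None:
                logger.warning("unknown protein %s; variant skipped", v.protein_id)
                continue
            this_oracle = oracle if isinstance(oracle, SequencePredictor) else oracle(rec, v)
            try:
                out.append(classify_variant(rec, v, this_oracle, flank=flank,
                                            level=level, annotated=annotated))
            except ValidationError as exc:
                logger.warning("variant %s skipped: %s", v.token, exc)
        calls[level_key] = out
    return calls, sweep_report(calls)


@dataclass
class SweepReport:
    """Counts per SUMOAMVR type at each specificity level (Table-2 layout)."""

    counts: pd.DataFrame   # index: level, columns: type values + totals

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def sweep_report(calls: Mapping[str, Sequence[AMVRCall]]) -> SweepReport:
    rows = {}
    for level, level_calls in calls.items():
        counts = {t.value: 0 for t in SWEEP_TYPES}
        for c in level_calls:
            if c.type in SWEEP_TYPES:
                counts[c.type.value] += 1
        counts["type_I_all"] = counts["I+"] + counts["I-"]
        counts["type_II_all"] = counts["II+"] + counts["II-"]
        counts["all"] = sum(counts[t.value] for t in SWEEP_TYPES)
        rows[level] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "specificity"
    return SweepReport(df)


# ---------------------------------------------------------------------------
# Per-class summaries (Table-6 layout)
# ---------------------------------------------------------------------------

CLASS_LABELS = ("disease", "polymorphism", "unclassified")


@dataclass
class ClassSummary:
    table: pd.DataFrame            # per type x class: count and percentage
    tests: dict[str, _stats.TestResult]  # per type, disease vs polymorphism
    method: str


def class_summary_from_counts(
    counts: pd.DataFrame,
    denominators: Mapping[str, int],
    method: str = "fisher-exact",
) -> ClassSummary:
    """Build a Table-6 style summary from per-type, per-class call counts.

    ``counts`` has one row per type and one column per class label;
    percentages are count / class denominator. Each type gets a 2x2 test of
    disease vs polymorphism membership (Fisher exact by default, Pearson
    chi-square via ``method="pearson-chi2"``).
    """
    for label in counts.columns:
        if denominators.get(label, 0) <= 0:
            raise ValidationError(f"missing or non-positive denominator for {label!r}")
    full = counts.copy()
    full.loc["All"] = counts.sum()
    out = {}
    for label in counts.columns:
        out[f"{label}_num"] = full[label]
        out[f"{label}_pct"] = (100.0 * full[label] / denominators[label]).round(2)
    table = pd.DataFrame(out)
    tests = {}
    test_fn = (_stats.pearson_chi2 if method == "pearson-chi2"
               else _stats.fisher_exact_2x2)
    for type_ in full.index:
        a = int(full.loc[type_, "disease"])
        b = int(full.loc[type_, "polymorphism"])
        t22 = [[a, denominators["disease"] - a],
               [b, denominators["polymorphism"] - b]]
        tests[str(type_)] = test_fn(t22)
    return ClassSummary(table=table, tests=tests, method=method)


def summarize_by_class(
    calls: Sequence[AMVRCall],
    class_denominators: Mapping[str, int],
    method: str = "fisher-exact",
) -> ClassSummary:
    """Aggregate calls into per-type, per-class counts and test each type.

    Calls without a recognized class label count as unclassified.
    """
    counts = pd.DataFrame(0, index=[t.value for t in SWEEP_TYPES],
                          columns=list(CLASS_LABELS))
    for c in calls:
        if c.type not in SWEEP_TYPES:
            continue
        label = c.variant.class_label
        if label not in CLASS_LABELS:
            label = "unclassified"
        counts.loc[c.type.value, label] += 1
    return class_summary_from_counts(counts, class_denominators, method=method)


def write_calls(calls: Sequence[AMVRCall], path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "protein_id": c.variant.protein_id,
            "variant": c.variant.token,
            "type": c.type.value,
            "affected_site": "" if c.affected_site is None else c.affected_site,
            "wt_p": "" if c.wt_probability is None else f"{c.wt_probability:.6f}",
            "mut_p": "" if c.mut_probability is None else f"{c.mut_probability:.6f}",
            "level": c.specificity_level,
            "evidence": c.evidence.value,
            "class_label": c.variant.class_label,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Curated worked examples (shipped as package data)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CuratedRow:
    gene: str
    protein_id: str
    token: str
    site_pos: int
    peptide: str
    group: str


def load_curated_tables(which: Sequence[str] = ("type1", "type2", "type3")) -> list[CuratedRow]:
    rows = []
    for name in which:
        with resources.files("sumovar.data").joinpath(f"curated_{name}.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", dtype={"protein_id": str})
        for r in df.itertuples(index=False):
            rows.append(CuratedRow(r.gene, r.protein_id, r.token,
                                   int(r.site_pos), r.peptide, r.group))
    return rows


def curated_record(row: CuratedRow, flank: int = DEFAULT_FLANK) -> tuple[ProteinRecord, VariantRecord]:
    """Reconstruct a padded pseudo-sequence from a curated local peptide.

    The peptide is centered on the annotated site (left-truncated when the
    site sits near the protein start); positions outside it are 'X'. The
    residue at the variant position is forced to the token's wild-type code,
    which tolerates the occasional peptide/token discrepancy in curated data.
    """
    wt, vpos, mut = parse_variant_token(row.token)
    left = min(flank, row.site_pos - 1)
    start = row.site_pos - left                      # 1-based peptide start
    length = max(start + len(row.peptide) - 1, vpos, row.site_pos)
    seq = ["X"] * length
    for i, aa in enumerate(row.peptide):
        seq[start - 1 + i] = aa
    seq[vpos - 1] = wt
    record = ProteinRecord(id=f"{row.protein_id}:{row.token}", sequence="".join(seq))
    variant = VariantRecord(protein_id=record.id, position=vpos, wt_aa=wt, mut_aa=mut)
    return record, variant


def curated_site_pair(row: CuratedRow) -> SitePair:
    """Annotated before/after site sets implied by the curated group."""
    if row.group in ("I-", "II-"):
        return SitePair.of([row.site_pos], [])
    if row.group in ("I+", "II+"):
        return SitePair.of([], [row.site_pos])
    if row.group == "III":
        return SitePair.of([row.site_pos], [row.site_pos])
    raise ValidationError(f"unknown curated group {row.group!r}")


def classify_curated(rows: Sequence[CuratedRow], flank: int = DEFAULT_FLANK) -> list[AMVRCall]:
    """Annotation-driven classification of curated (variant, site) pairs."""
    calls = []
    for row in rows:
        record, variant = curated_record(row, flank)
        calls.append(classify_variant(record, variant, curated_site_pair(row),
                                      flank=flank))
    return calls


def load_reported_denominators() -> dict:
    with resources.files("sumovar.data").joinpath("denominators.json").open() as fh:
        return json.load(fh)


def load_reported_sweep() -> pd.DataFrame:
    with resources.files("sumovar.data").joinpath("sweep_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="specificity")


def load_reported_class_counts() -> pd.DataFrame:
    with resources.files("sumovar.data").joinpath("class_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="type")
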
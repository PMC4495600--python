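"""Contingency-table tests and motif statistics.

Both Pearson's chi-square and Fisher's exact test are provided (reports
record which was used; the default for 2x2 tables is Fisher). Motif
statistics cover a two-sample-logo style per-(position, residue) enrichment
scan and a motif-x style iterative motif extractor with exact binomial
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .seqio import AMINO_ACIDS, PAD, Fragment, ValidationError


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValidationError("table total must be positive")

    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    dof: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def pearson_chi2(table: ContingencyTable | Sequence, correction: bool = False) -> TestResult:
    """Pearson's chi-square test of independence (no continuity correction by
    default), upper-tail p with df = (r-1)(c-1)."""
    arr = table.array() if isinstance(table, ContingencyTable) else np.asarray(table, float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined with a zero marginal")
    res = sps.chi2_contingency(arr, correction=correction)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="pearson-chi2", dof=int(res.dof))


def fisher_exact_2x2(table: ContingencyTable | Sequence, two_sided: bool = True) -> TestResult:
    """Fisher's exact test for a 2x2 table (two-sided sums over tables with
    probability <= that of the observed table)."""
    arr = table.array() if isinstance(table, ContingencyTable) else np.asarray(table, float)
    if arr.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    odds, p = sps.fisher_exact(arr, alternative="two-sided" if two_sided else "greater")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher-exact")


# ---------------------------------------------------------------------------
# Two-sample logo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentCell:
    position: int          # window offset, center excluded
    residue: str
    fg_freq: float
    bg_freq: float
    statistic: float
    p_value: float
    direction: str         # "enriched" | "depleted"


def _occurrence_counts(fragments: Sequence[Fragment | str], flank: int):
    """Per (offset, residue) occurrence counts and per-offset non-pad totals."""
    counts = np.zeros((2 * flank + 1, 20))
    totals = np.zeros(2 * flank + 1)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for frag in fragments:
        s = frag.residues if isinstance(frag, Fragment) else frag
        for j, aa in enumerate(s):
            if aa == PAD:
                continue
            counts[j, aa_index[aa]] += 1
            totals[j] += 1
    return counts, totals


def two_sample_logo(
    pos_fragments: Sequence[Fragment | str],
    neg_fragments: Sequence[Fragment | str],
    alpha: float = 0.05,
) -> list[EnrichmentCell]:
    """Per-(position, residue) two-proportion z-test of foreground vs
    background occurrence; cells with p < alpha are returned with their
    direction. The center position and the padding 'X' are excluded."""
    if not pos_fragments or not neg_fragments:
        raise ValidationError("both fragment sets must be non-empty")
    first = pos_fragments[0]
    length = len(first.residues if isinstance(first, Fragment) else first)
    flank = length // 2
    fg_counts, fg_totals = _occurrence_counts(pos_fragments, flank)
    bg_counts, bg_totals = _occurrence_counts(neg_fragments, flank)
    cells = []
    for j in range(2 * flank + 1):
        offset = j - flank
        if offset == 0:
            continue
        n1, n2 = fg_totals[j], bg_totals[j]
        if n1 == 0 or n2 == 0:
            continue
        for a, aa in enumerate(AMINO_ACIDS):
            k1, k2 = fg_counts[j, a], bg_counts[j, a]
            p1, p2 = k1 / n1, k2 / n2
            pooled = (k1 + k2) / (n1 + n2)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            if se == 0:
                continue
            z = (p1 - p2) / se
            p = 2 * sps.norm.sf(abs(z))
            if p < alpha:
                cells.append(EnrichmentCell(
                    position=offset, residue=aa, fg_freq=p1, bg_freq=p2,
                    statistic=float(z), p_value=float(p),
                    direction="enriched" if z > 0 else "depleted",
                ))
    return cells


# ---------------------------------------------------------------------------
# motif-x style extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Motif:
    """A pattern over the window: fixed (offset, residue) pairs plus center K."""

    fixed: tuple[tuple[int, str], ...]
    n_matches: int
    p_values: tuple[float, ...]

    def pattern(self, flank: int) -> str:
        chars = ["."] * (2 * flank + 1)
        chars[flank] = "K"
        for off, aa in self.fixed:
            chars[flank + off] = aa
        return "".join(chars)


def _matches(frag: Fragment | str, fixed, flank: int) -> bool:
    s = frag.residues if isinstance(frag, Fragment) else frag
    return all(s[flank + off] == aa for off, aa in fixed)


def motifx(
    pos_fragments: Sequence[Fragment | str],
    background_fragments: Sequence[Fragment | str],
    p_threshold: float = 1e-6,
    min_count: int = 20,
) -> list[Motif]:
    """Iterative most-significant (position, residue) fixing by binomial
    enrichment against the background, recursing on matching subsets until no
    cell passes both thresholds; extracted motifs are removed from the
    foreground and extraction repeats. No heuristic pruning — exact binomial
    p-values throughout."""
    first = pos_fragments[0]
    length = len(first.residues if isinstance(first, Fragment) else first)
    flank = length // 2
    fg = list(pos_fragments)
    bg_all = list(background_fragments)
    motifs: list[Motif] = []
    while fg:
        fixed: list[tuple[int, str]] = []
        pvals: list[float] = []
        cur_fg, cur_bg = fg, bg_all
        while True:
            fg_counts, fg_totals = _occurrence_counts(cur_fg, flank)
            bg_counts, bg_totals = _occurrence_counts(cur_bg, flank)
            best = None
            for j in range(2 * flank + 1):
                offset = j - flank
                if offset == 0 or any(off == offset for off, _ in fixed):
                    continue
                if fg_totals[j] == 0 or bg_totals[j] == 0:
                    continue
                for a, aa in enumerate(AMINO_ACIDS):
                    k = int(fg_counts[j, a])
                    if k < min_count:
                        continue
                    p_bg = bg_counts[j, a] / bg_totals[j]
                    p = float(sps.binom.sf(k - 1, int(fg_totals[j]), p_bg))
                    if p < p_threshold and (best is None or p < best[0]):
                        best = (p, offset, aa)
            if best is None:
                break
            p, offset, aa = best
            fixed.append((offset, aa))
            pvals.append(p)
            cur_fg = [f for f in cur_fg if _matches(f, [(offset, aa)], flank)]
            cur_bg = [f for f in cur_bg if _matches(f, [(offset, aa)], flank)]
        if not fixed:
            break
        motifs.append(Motif(tuple(fixed), len(cur_fg), tuple(pvals)))
        fg = [f for f in fg if not _matches(f, fixed, flank)]
    return motifs
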
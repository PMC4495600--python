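"""Sequence, site and variant I/O plus fragment dataset construction.

Coordinates are 1-based everywhere in the public API, matching the usual
"K386"-style notation; conversion to 0-based indexing happens only inside
helper bodies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

#: canonical one-letter residue alphabet (no padding character)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: padding / unknown residue character
PAD = "X"

DEFAULT_FLANK = 10

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class SumovarError(Exception):
    """Base class for errors raised by this package."""


class ParseError(SumovarError):
    pass


class ValidationError(SumovarError):
    pass


class Evidence(str, Enum):
    ANNOTATED = "annotated"
    PREDICTED = "predicted"


class FragmentLabel(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence keyed by accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set(AMINO_ACIDS + PAD)
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} out of range for {self.id} "
                             f"(length {len(self.sequence)})")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class SiteEntry:
    protein_id: str
    position: int
    evidence: Evidence = Evidence.ANNOTATED


class SiteTable:
    """Set of (protein_id, 1-based position, evidence) sumoylation sites."""

    def __init__(self, entries: Iterable[SiteEntry] = ()) -> None:
        self._by_protein: dict[str, dict[int, Evidence]] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: SiteEntry) -> None:
        self._by_protein.setdefault(entry.protein_id, {})[entry.position] = entry.evidence

    def positions(self, protein_id: str) -> dict[int, Evidence]:
        return dict(self._by_protein.get(protein_id, {}))

    def proteins(self) -> list[str]:
        return sorted(self._by_protein)

    def __contains__(self, key: tuple[str, int]) -> bool:
        pid, pos = key
        return pos in self._by_protein.get(pid, {})

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_protein.values())

    def entries(self) -> list[SiteEntry]:
        return [
            SiteEntry(pid, pos, ev)
            for pid in sorted(self._by_protein)
            for pos, ev in sorted(self._by_protein[pid].items())
        ]


@dataclass(frozen=True)
class VariantRecord:
    """A single amino-acid substitution."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    class_label: str = "unclassified"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"variant at {self.protein_id}:{self.position} does not change the residue"
            )

    @property
    def token(self) -> str:
        return (f"{ONE_TO_THREE.get(self.wt_aa, self.wt_aa)}{self.position}"
                f"{ONE_TO_THREE.get(self.mut_aa, self.mut_aa)}")


@dataclass(frozen=True)
class Fragment:
    """A lysine-centered window of ``2*flank + 1`` residues, 'X'-padded."""

    protein_id: str
    center_pos: int
    residues: str
    label: FragmentLabel = FragmentLabel.UNLABELED

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0:
            raise ValidationError("fragment length must be odd")
        if self.label is not FragmentLabel.UNLABELED and self.center != "K":
            raise ValidationError(
                f"labeled fragment at {self.protein_id}:{self.center_pos} "
                f"is centered on {self.center!r}, not 'K'"
            )

    @property
    def flank(self) -> int:
        return len(self.residues) // 2

    @property
    def center(self) -> str:
        return self.residues[len(self.residues) // 2]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing stop characters (``*``) removed.
    A file whose first non-blank line is not a header raises :class:`ParseError`
    with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header line starting with '>'"
                    )
                break
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Site and variant tables (TSV with header)
# ---------------------------------------------------------------------------

def read_sites(path: str | Path) -> SiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position"}
    if not required <= set(df.columns):
        raise ParseError(f"site table {path} must have columns {sorted(required)}")
    table = SiteTable()
    for row in df.itertuples(index=False):
        ev = Evidence(getattr(row, "evidence", "annotated"))
        table.add(SiteEntry(row.protein_id, int(row.position), ev))
    return table


def write_sites(table: SiteTable, path: str | Path) -> None:
    rows = [(e.protein_id, e.position, e.evidence.value) for e in table.entries()]
    pd.DataFrame(rows, columns=["protein_id", "position", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


_TOKEN_RE = re.compile(r"^([A-Za-z]{3}|[A-Z])\s*(\d+)\s*([A-Za-z]{3}|[A-Z])$")


def parse_variant_token(token: str) -> tuple[str, int, str]:
    """Parse a substitution token such as ``Lys386Asn`` into ``(K, 386, N)``.

    Both sides accept three-letter codes with a one-letter fallback (mixed
    tokens such as ``Lys477T`` occur in curated data).
    """
    m = _TOKEN_RE.match(token.strip().replace(" ", ""))
    if not m:
        raise ValidationError(f"cannot parse variant token {token!r}")
    out = []
    for code in (m.group(1), m.group(3)):
        if len(code) == 3:
            aa = THREE_TO_ONE.get(code.capitalize())
            if aa is None:
                raise ValidationError(f"unknown residue code {code!r} in token {token!r}")
        else:
            aa = code.upper()
            if aa not in AMINO_ACIDS:
                raise ValidationError(f"unknown residue code {code!r} in token {token!r}")
        out.append(aa)
    return out[0], int(m.group(2)), out[1]


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV: either a ``token`` column or wt/position/mut columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    variants = []
    for row in df.itertuples(index=False):
        if hasattr(row, "token") and row.token:
            wt, pos, mut = parse_variant_token(row.token)
        else:
            wt, pos, mut = row.wt_aa, int(row.position), row.mut_aa
        variants.append(
            VariantRecord(
                protein_id=row.protein_id,
                position=int(pos),
                wt_aa=wt,
                mut_aa=mut,
                class_label=getattr(row, "class_label", "") or "unclassified",
                annotation=getattr(row, "annotation", ""),
            )
        )
    return variants


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        (v.protein_id, v.token, v.wt_aa, v.position, v.mut_aa, v.class_label, v.annotation)
        for v in variants
    ]
    pd.DataFrame(
        rows,
        columns=["protein_id", "token", "wt_aa", "position", "mut_aa",
                 "class_label", "annotation"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence manipulation
# ---------------------------------------------------------------------------

def apply_variant(record: ProteinRecord, variant: VariantRecord) -> ProteinRecord:
    """Return a copy of ``record`` with the substitution applied.

    Raises :class:`ValidationError` if the wild-type residue does not match.
    """
    observed = record.residue(variant.position)
    if observed != variant.wt_aa:
        raise ValidationError(
            f"wild-type mismatch at {record.id}:{variant.position}: "
            f"expected {variant.wt_aa!r}, sequence has {observed!r}"
        )
    seq = record.sequence
    i = variant.position - 1
    return replace(record, sequence=seq[:i] + variant.mut_aa + seq[i + 1:])


def extract_fragment(
    sequence: str,
    pos: int,
    flank: int = DEFAULT_FLANK,
    *,
    protein_id: str = "",
    label: FragmentLabel = FragmentLabel.UNLABELED,
) -> Fragment:
    """Extract the ``2*flank + 1``-mer centered at 1-based ``pos``.

    Positions falling outside the sequence are filled with the padding
    character 'X'.
    """
    if not 1 <= pos <= len(sequence):
        raise IndexError(f"position {pos} out of range (length {len(sequence)})")
    i = pos - 1
    left = sequence[max(0, i - flank):i]
    right = sequence[i + 1:i + 1 + flank]
    residues = (PAD * (flank - len(left)) + left + sequence[i]
                + right + PAD * (flank - len(right)))
    return Fragment(protein_id=protein_id, center_pos=pos, residues=residues, label=label)


def build_dataset(
    records: Sequence[ProteinRecord],
    site_table: SiteTable,
    flank: int = DEFAULT_FLANK,
) -> list[Fragment]:
    """Build labeled fragments: positives at annotated lysines, negatives at
    every other lysine of the same (experimentally investigated) proteins.

    Proteins without any annotated site contribute nothing. Annotated
    positions that are not lysine are skipped with a logged warning.
    """
    fragments: list[Fragment] = []
    for rec in records:
        annotated = site_table.positions(rec.id)
        if not annotated:
            continue
        valid_sites = set()
        for pos in sorted(annotated):
            if pos > len(rec.sequence) or rec.residue(pos) != "K":
                logger.warning(
                    "annotated site %s:%d is not a lysine; skipped", rec.id, pos
                )
                continue
            valid_sites.add(pos)
        for i, aa in enumerate(rec.sequence, start=1):
            if aa != "K":
                continue
            label = (FragmentLabel.POSITIVE if i in valid_sites
                     else FragmentLabel.NEGATIVE)
            fragments.append(
                extract_fragment(rec.sequence, i, flank, protein_id=rec.id, label=label)
            )
    return fragments


def fragment_identity(a: Fragment | str, b: Fragment | str) -> float:
    """Fraction of identical aligned positions; the padding 'X' never matches."""
    sa = a.residues if isinstance(a, Fragment) else a
    sb = b.residues if isinstance(b, Fragment) else b
    if len(sa) != len(sb):
        raise ValidationError("fragments must have equal length")
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != PAD)
    return matches / len(sa)


def reduce_redundancy(
    fragments: Sequence[Fragment],
    max_identity: float = 0.3,
) -> list[Fragment]:
    """Greedy order-dependent redundancy filter.

    A fragment is dropped if its pairwise identity with any already retained
    fragment exceeds ``max_identity``. This is a documented stand-in for
    clustering whole datasets with an external tool; only the identity cutoff
    semantics are preserved.
    """
    retained: list[Fragment] = []
    for frag in fragments:
        if all(fragment_identity(frag, kept) <= max_identity for kept in retained):
            retained.append(frag)
    return retained
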
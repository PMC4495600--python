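"""Synthetic proteomes, site annotations, profiles and variant sets.

Positive lysine fragments are planted with the canonical context (a large
aliphatic hydrophobic residue at -1 and glutamate at +2) at a configurable
fidelity q against a background of ordinary lysines, and variant sets are
constructed so each requested effect type is guaranteed by design, with the
ground truth recorded. Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amvr import SitePair
from .features import PSSMProfile, StructureAnnotation
from .seqio import (AMINO_ACIDS, DEFAULT_FLANK, Evidence, ProteinRecord,
                    SiteEntry, SiteTable, ValidationError, VariantRecord)

#: residues accepted at the -1 position of the consensus context
HYDROPHOBIC = "LVIMF"

VARIANT_TYPES = ("I+", "I-", "II+", "II-", "III", "none")


@dataclass
class SynthConfig:
    n_proteins: int = 50
    min_length: int = 80
    max_length: int = 300
    n_positive_sites: int = 120
    motif_fidelity: float = 0.9    # probability a planted site carries the full context
    background_freqs: Mapping[str, float] | None = None  # uniform when None
    n_latent_contexts: int = 40    # non-K positions with a motif-ready context
    n_near_miss_sites: int = 40    # lysines one substitution away from the context
    variant_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I-": 20, "I+": 10, "II-": 20, "II+": 10,
                                 "III": 10, "none": 10})
    class_mixing: tuple[float, float, float] = (0.35, 0.5, 0.15)
    flank: int = DEFAULT_FLANK
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_fidelity <= 1.0:
            raise ValidationError("motif fidelity must lie in [0, 1]")
        if self.min_length < 2 * self.flank + 1:
            # enforce a window-sized length floor
            self.min_length = 2 * self.flank + 1
        if any(v < 0 for v in self.variant_counts.values()):
            raise ValidationError("variant counts must be non-negative")

    def freq_vector(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(20, 1 / 20)
        v = np.array([self.background_freqs.get(aa, 0.0) for aa in AMINO_ACIDS])
        if v.sum() <= 0:
            raise ValidationError("background frequencies sum to zero")
        return v / v.sum()


@dataclass
class ProteomeTruth:
    """Bookkeeping of everything planted into a synthetic proteome."""

    planted_sites: list[tuple[str, int]] = field(default_factory=list)
    motif_sites: list[tuple[str, int]] = field(default_factory=list)   # subset with full context
    latent_contexts: list[tuple[str, int]] = field(default_factory=list)
    near_miss_sites: list[tuple[str, int]] = field(default_factory=list)
    config: dict = field(default_factory=dict)


@dataclass
class VariantTruth:
    variant: VariantRecord
    intended_type: str
    site_pair: SitePair
    anchor_site: int | None


@dataclass
class VariantSet:
    variants: list[VariantRecord]
    truth: list[VariantTruth]
    shortfall: dict[str, int]      # requested-minus-delivered per type, if any

    def site_pair_oracle(self):
        """Callable (record, variant) -> SitePair for annotation-driven runs."""
        pairs = {(t.variant.protein_id, t.variant.position, t.variant.mut_aa): t.site_pair
                 for t in self.truth}

        def oracle(record, variant):
            return pairs[(variant.protein_id, variant.position, variant.mut_aa)]

        return oracle


def _random_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length, p=freqs))


def generate_proteome(config: SynthConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[list[ProteinRecord], SiteTable, ProteomeTruth]:
    """Generate records, a site table of planted positives and the truth.

    Planted positive lysines carry the -1 hydrophobic / +2 glutamate context
    with probability ``motif_fidelity``; every other lysine is background.
    Latent contexts (motif-ready non-K positions) and near-miss sites (K with
    the -1 residue but a broken +2) are planted for variant construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = config.freq_vector()
    seqs: dict[str, list[str]] = {}
    lengths = rng.integers(config.min_length, config.max_length + 1,
                           size=config.n_proteins)
    for i, L in enumerate(lengths):
        seqs[f"SYN{i:04d}"] = _random_sequence(rng, int(L), freqs)

    truth = ProteomeTruth(config=asdict(config))
    flank = config.flank
    used: dict[str, list[int]] = {pid: [] for pid in seqs}

    def reserve(pid: str, pos: int, margin: int = 6) -> bool:
        if any(abs(pos - p) <= margin for p in used[pid]):
            return False
        used[pid].append(pos)
        return True

    def random_slot() -> tuple[str, int] | None:
        for _ in range(2000):
            pid = f"SYN{rng.integers(config.n_proteins):04d}"
            L = len(seqs[pid])
            if L < 2 * flank + 1:
                continue
            pos = int(rng.integers(flank + 1, L - flank + 1))
            if reserve(pid, pos):
                return pid, pos
        return None

    def plant_context(seq: list[str], pos: int, rng) -> None:
        seq[pos - 2] = rng.choice(list(HYDROPHOBIC))   # -1
        seq[pos + 1] = "E"                             # +2

    site_table = SiteTable()
    for _ in range(config.n_positive_sites):
        slot = random_slot()
        if slot is None:
            raise ValidationError("proteome too small for requested sites")
        pid, pos = slot
        seqs[pid][pos - 1] = "K"
        if rng.random() < config.motif_fidelity:
            plant_context(seqs[pid], pos, rng)
            truth.motif_sites.append((pid, pos))
        truth.planted_sites.append((pid, pos))
        site_table.add(SiteEntry(pid, pos, Evidence.ANNOTATED))

    for _ in range(config.n_latent_contexts):
        slot = random_slot()
        if slot is None:
            break
        pid, pos = slot
        non_k = [aa for aa in AMINO_ACIDS if aa != "K"]
        seqs[pid][pos - 1] = str(rng.choice(non_k))
        plant_context(seqs[pid], pos, rng)
        truth.latent_contexts.append((pid, pos))

    for _ in range(config.n_near_miss_sites):
        slot = random_slot()
        if slot is None:
            break
        pid, pos = slot
        seqs[pid][pos - 1] = "K"
        seqs[pid][pos - 2] = str(rng.choice(list(HYDROPHOBIC)))
        non_e = [aa for aa in AMINO_ACIDS if aa != "E"]
        seqs[pid][pos + 1] = str(rng.choice(non_e))
        truth.near_miss_sites.append((pid, pos))

    records = [ProteinRecord(pid, "".join(s)) for pid, s in sorted(seqs.items())]
    return records, site_table, truth


def generate_variants(records: Sequence[ProteinRecord],
                      site_table: SiteTable,
                      truth: ProteomeTruth,
                      config: SynthConfig,
                      rng: np.random.Generator | None = None) -> VariantSet:
    """Construct variants guaranteeing each requested type by design.

    I(-): K->R at a planted site. I(+): X->K inside a latent motif context.
    II(-): destroy the +2 glutamate of a motif-carrying planted site.
    II(+): complete a near-miss context (+2 -> E). III: a within-window
    substitution of a planted site preserving the -1/+2 context. none: a
    substitution with no lysine in reach. Any shortfall of eligible anchors
    is reported, never silent.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    by_id = {r.id: r for r in records}
    variants: list[VariantRecord] = []
    truths: list[VariantTruth] = []
    shortfall: dict[str, int] = {}

    def planted_for(pid):
        return frozenset(site_table.positions(pid))

    def label() -> str:
        return str(rng.choice(["disease", "polymorphism", "unclassified"],
                              p=config.class_mixing))

    def emit(pid, pos, wt, mut, intended, pair, anchor):
        v = VariantRecord(pid, pos, wt, mut, class_label=label())
        variants.append(v)
        truths.append(VariantTruth(v, intended, pair, anchor))

    def take(pool, n):
        pool = list(pool)
        idx = rng.permutation(len(pool))[:n]
        return [pool[i] for i in idx]

    counts = dict(config.variant_counts)

    # I(-): remove a planted site directly
    n = counts.get("I-", 0)
    anchors = take(truth.planted_sites, n)
    shortfall_n = n - len(anchors)
    for pid, pos in anchors:
        wt_sites = planted_for(pid)
        emit(pid, pos, "K", "R", "I-",
             SitePair(wt_sites, wt_sites - {pos}), pos)
    if shortfall_n:
        shortfall["I-"] = shortfall_n

    # I(+): create a lysine inside a latent context
    n = counts.get("I+", 0)
    anchors = take(truth.latent_contexts, n)
    if n - len(anchors):
        shortfall["I+"] = n - len(anchors)
    for pid, pos in anchors:
        wt_sites = planted_for(pid)
        wt = by_id[pid].residue(pos)
        emit(pid, pos, wt, "K", "I+",
             SitePair(wt_sites, wt_sites | {pos}), pos)

    # II(-): break the +2 glutamate of a motif-carrying site
    n = counts.get("II-", 0)
    used_sites = {(t.variant.protein_id, t.anchor_site) for t in truths}
    eligible = [s for s in truth.motif_sites if s not in used_sites]
    anchors = take(eligible, n)
    if n - len(anchors):
        shortfall["II-"] = n - len(anchors)
    for pid, pos in anchors:
        wt_sites = planted_for(pid)
        vpos = pos + 2
        wt = by_id[pid].residue(vpos)           # 'E' by construction
        emit(pid, vpos, wt, "A", "II-",
             SitePair(wt_sites, wt_sites - {pos}), pos)

    # II(+): complete a near-miss context
    n = counts.get("II+", 0)
    anchors = take(truth.near_miss_sites, n)
    if n - len(anchors):
        shortfall["II+"] = n - len(anchors)
    for pid, pos in anchors:
        wt_sites = planted_for(pid)
        vpos = pos + 2
        wt = by_id[pid].residue(vpos)           # non-E by construction
        emit(pid, vpos, wt, "E", "II+",
             SitePair(wt_sites, wt_sites | {pos}), pos)

    # III: change the window without touching the site, -1 or +2
    n = counts.get("III", 0)
    used_sites = {(t.variant.protein_id, t.anchor_site) for t in truths}
    eligible = [s for s in truth.motif_sites if s not in used_sites]
    anchors = take(eligible, n)
    if n - len(anchors):
        shortfall["III"] = n - len(anchors)
    for pid, pos in anchors:
        wt_sites = planted_for(pid)
        vpos = pos + 5
        wt = by_id[pid].residue(vpos)
        choices = [aa for aa in AMINO_ACIDS if aa not in (wt, "K")]
        emit(pid, vpos, wt, str(rng.choice(choices)), "III",
             SitePair(wt_sites, wt_sites), pos)

    # none: no lysine within reach of the variant
    n = counts.get("none", 0)
    found = 0
    for _ in range(5000):
        if found >= n:
            break
        rec = by_id[f"SYN{rng.integers(config.n_proteins):04d}"]
        vpos = int(rng.integers(1, len(rec.sequence) + 1))
        lo, hi = max(1, vpos - config.flank), min(len(rec.sequence), vpos + config.flank)
        window = rec.sequence[lo - 1:hi]
        wt = rec.residue(vpos)
        if "K" in window or wt == "K":
            continue
        choices = [aa for aa in AMINO_ACIDS if aa not in (wt, "K")]
        emit(rec.id, vpos, wt, str(rng.choice(choices)), "none",
             SitePair(planted_for(rec.id), planted_for(rec.id)), None)
        found += 1
    if n - found:
        shortfall["none"] = n - found

    return VariantSet(variants, truths, shortfall)


# ---------------------------------------------------------------------------
# Fabricated external profiles
# ---------------------------------------------------------------------------

_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted, fabricated\n"
    "            " + "   ".join(AMINO_ACIDS) + "\n"
)


def fabricate_profiles(records: Sequence[ProteinRecord],
                       out_dir: str | Path,
                       seed: int = 0) -> tuple[dict[str, PSSMProfile],
                                               dict[str, StructureAnnotation]]:
    """Write format-valid PSSM ASCII files and per-residue structure TSVs.

    Values are random but reproducible from the seed; the point is schema
    validity for exercising the readers and encoders, not biological realism.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    (out_dir / "pssm").mkdir(parents=True, exist_ok=True)
    (out_dir / "structure").mkdir(parents=True, exist_ok=True)
    profiles, structures = {}, {}
    for rec in records:
        n = len(rec.sequence)
        scores = rng.integers(-8, 9, size=(n, 20))
        profiles[rec.id] = PSSMProfile(rec.id, scores.astype(float))
        with open(out_dir / "pssm" / f"{rec.id}.pssm", "w") as fh:
            fh.write(_PSSM_HEADER)
            for i, aa in enumerate(rec.sequence, start=1):
                row = " ".join(f"{v:3d}" for v in scores[i - 1])
                extra = " ".join("0" for _ in range(20))
                fh.write(f"{i:5d} {aa}  {row}  {extra}\n")
            fh.write("\n")
        asa = np.round(rng.uniform(0, 250, size=n), 2)
        ss = "".join(rng.choice(list("HEC"), size=n))
        structures[rec.id] = StructureAnnotation(rec.id, asa, ss)
        with open(out_dir / "structure" / f"{rec.id}.tsv", "w") as fh:
            fh.write("position\tasa\tss\n")
            for i in range(n):
                fh.write(f"{i + 1}\t{asa[i]}\t{ss[i]}\n")
    return profiles, structures


def write_truth(variant_set: VariantSet, path: str | Path) -> None:
    payload = {
        "shortfall": variant_set.shortfall,
        "variants": [
            {
                "protein_id": t.variant.protein_id,
                "token": t.variant.token,
                "class_label": t.variant.class_label,
                "intended_type": t.intended_type,
                "anchor_site": t.anchor_site,
                "wt_sites": sorted(t.site_pair.wt),
                "mut_sites": sorted(t.site_pair.mut),
            }
            for t in variant_set.truth
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
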
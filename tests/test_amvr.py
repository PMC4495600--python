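from collections import Counter

import numpy as np
import pandas as pd
import pytest

from sumovar import amvr, synthetic
from sumovar.amvr import AMVRType, SequencePredictor, SitePair
from sumovar.seqio import (ProteinRecord, SiteEntry, SiteTable,
                           ValidationError, VariantRecord)


class TestClassifyVariantAnnotated:
    def test_site_removed_is_type_I_minus(self):
        # K386 annotated, Lys386Asn removes it
        rec = ProteinRecord("P04637x", "A" * 375 + "STSRHKKLMFKTEGPDSD")
        v = VariantRecord("P04637x", 386, "K", "N")
        call = amvr.classify_variant(rec, v, SitePair.of([386], []))
        assert call.type is AMVRType.I_MINUS
        assert call.affected_site == 386
        assert call.evidence.value == "annotated"

    def test_site_gained_is_type_I_plus(self):
        rec = ProteinRecord("Q", "A" * 20 + "Q" + "A" * 20)
        v = VariantRecord("Q", 21, "Q", "K")
        call = amvr.classify_variant(rec, v, SitePair.of([], [21]))
        assert call.type is AMVRType.I_PLUS
        assert call.affected_site == 21

    def test_neighbor_site_lost_is_type_II_minus(self):
        # variant 4 residues downstream of an annotated lysine kills it
        rec = ProteinRecord("P", "IEPSKPAATRKRRWSAPESRK")
        v = VariantRecord("P", 15, "S", "A")
        call = amvr.classify_variant(rec, v, SitePair.of([11], []))
        assert call.type is AMVRType.II_MINUS
        assert call.affected_site == 11

    def test_neighbor_site_gained_is_type_II_plus(self):
        rec = ProteinRecord("P", "AAAAAAAAAAKAATAAAAAAA")
        v = VariantRecord("P", 13, "A", "E")
        call = amvr.classify_variant(rec, v, SitePair.of([], [11]))
        assert call.type is AMVRType.II_PLUS

    def test_site_retained_is_type_III(self):
        # F385A with K386 sumoylated before and after
        rec = ProteinRecord("P04637x", "A" * 375 + "STSRHKKLMFKTEGPDSD")
        v = VariantRecord("P04637x", 385, "F", "A")
        call = amvr.classify_variant(rec, v, SitePair.of([386], [386]))
        assert call.type is AMVRType.III
        assert call.affected_site == 386

    def test_distant_lysine_is_none(self):
        rec = ProteinRecord("P", "K" + "A" * 30)
        v = VariantRecord("P", 16, "A", "G")  # 15 residues from the only K
        call = amvr.classify_variant(rec, v, SitePair.of([1], [1]))
        assert call.type is AMVRType.NONE
        assert call.affected_site is None

    def test_wild_type_mismatch_raises(self):
        rec = ProteinRecord("P", "MKAE")
        with pytest.raises(ValidationError):
            amvr.classify_variant(rec, VariantRecord("P", 2, "R", "Q"),
                                  SitePair.of([], []))

    def test_rule_order_I_minus_before_II(self):
        # variant removes its own annotated site AND sits near another site:
        # rule 1 wins
        rec = ProteinRecord("P", "AAAAKAAAAAKAAAAAAAAAA")
        v = VariantRecord("P", 11, "K", "R")
        call = amvr.classify_variant(rec, v, SitePair.of([5, 11], [5]))
        assert call.type is AMVRType.I_MINUS
        assert call.affected_site == 11


class TestCuratedTables:
    def test_type1_counts(self):
        rows = amvr.load_curated_tables(["type1"])
        assert len(rows) == 59
        counts = Counter(c.type.value for c in amvr.classify_curated(rows))
        assert counts == {"I-": 55, "I+": 4}

    def test_type2_counts(self):
        rows = amvr.load_curated_tables(["type2"])
        counts = Counter(c.type.value for c in amvr.classify_curated(rows))
        assert counts == {"II-": 5}

    def test_type3_counts(self):
        rows = amvr.load_curated_tables(["type3"])
        counts = Counter(c.type.value for c in amvr.classify_curated(rows))
        assert counts == {"III": 2}

    def test_curated_record_reconstruction(self):
        row = next(r for r in amvr.load_curated_tables(["type1"])
                   if r.token == "Lys386Asn")
        rec, variant = amvr.curated_record(row)
        assert rec.sequence[385] == "K"
        assert variant.position == 386
        # the peptide context is laid down around the site
        assert "STSRHKKLMF" in rec.sequence


class TestClassifyBatch:
    def test_annotation_driven_agreement_with_truth(self, synth_proteome):
        cfg, records, sites, truth = synth_proteome
        vs = synthetic.generate_variants(records, sites, truth, cfg)
        calls, report = amvr.classify_batch(records, vs.variants,
                                            vs.site_pair_oracle())
        truth_by_key = {(t.variant.protein_id, t.variant.position,
                         t.variant.mut_aa): t.intended_type for t in vs.truth}
        for call in calls["default"]:
            key = (call.variant.protein_id, call.variant.position,
                   call.variant.mut_aa)
            assert call.type.value == truth_by_key[key]

    def test_empty_variants_zero_report(self, synth_proteome):
        _, records, _, _ = synth_proteome
        calls, report = amvr.classify_batch(records, [], lambda r, v: None)
        assert report.counts.loc["default", "all"] == 0

    def test_unknown_protein_skipped(self, caplog):
        records = [ProteinRecord("P", "MKAE")]
        variants = [VariantRecord("NOPE", 2, "K", "R")]
        calls, _ = amvr.classify_batch(records, variants, lambda r, v: SitePair.of([], []))
        assert calls["default"] == []

    def test_model_driven_recovery(self, synth_proteome, small_ensemble):
        cfg, records, sites, truth = synth_proteome
        encoder, ensemble = small_ensemble
        vs = synthetic.generate_variants(records, sites, truth, cfg)
        predictor = SequencePredictor(ensemble, encoder, cfg.flank)
        calls, _ = amvr.classify_batch(records, vs.variants, predictor)
        truth_by_key = {(t.variant.protein_id, t.variant.position,
                         t.variant.mut_aa): t.intended_type for t in vs.truth}
        hits = Counter()
        totals = Counter()
        for call in calls["default"]:
            key = (call.variant.protein_id, call.variant.position,
                   call.variant.mut_aa)
            intended = truth_by_key[key]
            totals[intended] += 1
            hits[intended] += call.type.value == intended
        assert hits["II-"] / totals["II-"] >= 0.8
        assert hits["none"] == totals["none"]

    def test_raising_level_never_increases_totals(self, synth_proteome,
                                                  small_ensemble):
        cfg, records, sites, truth = synth_proteome
        encoder, ensemble = small_ensemble
        vs = synthetic.generate_variants(records, sites, truth, cfg)
        predictor = SequencePredictor(ensemble, encoder, cfg.flank)
        levels = ["default", 0.70, 0.80, 0.90, 0.95]
        _, report = amvr.classify_batch(records, vs.variants, predictor,
                                        levels=levels)
        strict = report.counts.loc[["0.70", "0.80", "0.90", "0.95"]]
        # total and Type I counts are provably monotone in the cutoff; II/III
        # individually are not (a changed site can drop out, leaving an
        # unchanged neighbour to carry the call), so only the former are
        # asserted strictly
        for col in ("all", "type_I_all", "I+", "I-"):
            assert (strict[col].diff().dropna() <= 0).all(), col


class TestSummaries:
    def test_reported_class_percentages(self):
        counts = amvr.load_reported_class_counts()
        denoms = amvr.load_reported_denominators()
        summary = amvr.class_summary_from_counts(counts, denoms)
        assert summary.table.loc["All", "disease_pct"] == 4.83
        assert summary.table.loc["All", "polymorphism_pct"] == 9.58

    def test_percentage_cells_match_division(self):
        # recompute every printed percentage; two cells in the source table
        # were rounded inconsistently, hence the 0.011 slop
        printed = {
            ("I+", "disease_pct"): 0.28, ("I+", "polymorphism_pct"): 0.36,
            ("I-", "disease_pct"): 0.16, ("I-", "polymorphism_pct"): 0.31,
            ("II+", "disease_pct"): 0.64, ("II+", "polymorphism_pct"): 1.11,
            ("II-", "disease_pct"): 0.66, ("II-", "polymorphism_pct"): 1.19,
            ("III", "disease_pct"): 3.09, ("III", "polymorphism_pct"): 6.61,
        }
        counts = amvr.load_reported_class_counts()
        denoms = amvr.load_reported_denominators()
        summary = amvr.class_summary_from_counts(counts, denoms)
        for (row, col), want in printed.items():
            assert abs(summary.table.loc[row, col] - want) <= 0.011

    def test_summary_tests_present_per_type(self):
        counts = amvr.load_reported_class_counts()
        denoms = amvr.load_reported_denominators()
        summary = amvr.class_summary_from_counts(counts, denoms,
                                                 method="pearson-chi2")
        assert set(summary.tests) == {"I+", "I-", "II+", "II-", "III", "All"}
        assert summary.method == "pearson-chi2"
        assert 0.05 <= summary.tests["I+"].p_value <= 0.11

    def test_summarize_by_class_from_calls(self):
        variants = [VariantRecord("P", 2, "K", "R", class_label="disease"),
                    VariantRecord("P", 2, "K", "Q", class_label="mystery")]
        calls = [amvr.AMVRCall(variant=v, type=AMVRType.I_MINUS)
                 for v in variants]
        summary = amvr.summarize_by_class(
            calls, {"disease": 10, "polymorphism": 10, "unclassified": 10})
        assert summary.table.loc["I-", "disease_num"] == 1
        assert summary.table.loc["I-", "unclassified_num"] == 1  # unknown label
        assert summary.table.loc["I-", "polymorphism_num"] == 0

    def test_write_calls(self, tmp_path):
        v = VariantRecord("P", 2, "K", "R", class_label="disease")
        calls = [amvr.AMVRCall(variant=v, type=AMVRType.I_MINUS,
                               affected_site=2, wt_probability=0.9,
                               mut_probability=0.1)]
        amvr.write_calls(calls, tmp_path / "calls.tsv")
        df = pd.read_csv(tmp_path / "calls.tsv", sep="\t")
        assert df.loc[0, "type"] == "I-"
        assert df.loc[0, "variant"] == "Lys2Arg"
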
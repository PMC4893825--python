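"""Consequence engine: coordinate mapping, predicates, gating, SV terms."""

import pytest

from conseq.engine import (N_PREDICATES, assign_consequences,
                           assign_sv_consequences, map_to_transcript)
from conseq.models import RunStatistics
from conseq.variants import Variant, VariantAllele


def _snv(pos, ref, alt, chrom="chrT"):
    v = Variant(chrom=chrom, start=pos, end=pos, ref_allele=ref,
                alt_alleles=[alt])
    return VariantAllele(v, alt, 0)


class TestMapToTranscript:
    def test_forward_coding_snv_projection(self, store):
        # TX1: exon 11-50 + 61-100, CDS 21-90; genomic 25 -> cDNA 15, CDS 5,
        # protein 2
        t = store.transcript_by_id("TX1")
        b = map_to_transcript(_snv(25, "C", "T"), t, store)
        assert b.cdna_interval == (15, 15)
        assert b.cds_interval == (5, 5)
        assert b.protein_interval == (2, 2)
        assert b.exon_number == "1/2"
        assert b.intron_number is None

    def test_outside_span_yields_distance_only(self, store):
        t = store.transcript_by_id("TX1")
        b = map_to_transcript(_snv(5, "A", "C"), t, store)
        assert b.cdna_interval is None and b.cds_interval is None
        assert b.distance == 6

    def test_minus_strand_cds_position(self, store):
        # TX2 CDS genomic 9052-9250 on the minus strand: genomic 9250 is CDS 1
        t = store.transcript_by_id("TX2")
        b = map_to_transcript(_snv(9250, "N", "A"), t, store)
        assert b.cds_interval == (1, 1)

    def test_fully_intronic_span_has_intron_index_only(self, store):
        t = store.transcript_by_id("TX2")
        b = map_to_transcript(_snv(9150, "N", "A"), t, store)
        assert b.cdna_interval is None
        assert b.intron_number == "1/1"


class TestAssignConsequences:
    def test_missense_with_codon_case_convention(self, store):
        t = store.transcript_by_id("TX1")
        res = assign_consequences(_snv(25, "C", "T"), t, store)
        assert res.terms == ["missense_variant"]
        assert (res.ref_codons, res.alt_codons) == ("gCc", "gTc")
        assert (res.ref_aa, res.alt_aa) == ("A", "V")

    def test_donor_snv_gates_out_coding_predicates(self, store):
        t = store.transcript_by_id("TX1")
        stats = RunStatistics(p=N_PREDICATES)
        res = assign_consequences(_snv(52, "T", "C"), t, store, stats=stats)
        assert res.terms == ["splice_donor_variant"]
        assert stats.predicate_evaluations_skipped > 0

    def test_downstream_with_distance(self, store):
        t = store.transcript_by_id("TX1")
        res = assign_consequences(_snv(300, "G", "A"), t, store)
        assert res.terms == ["downstream_gene_variant"]
        assert res.coords.distance == 200

    def test_splice_region_coexists_with_coding_term(self, store):
        t = store.transcript_by_id("TX1")
        res = assign_consequences(_snv(49, "T", "C"), t, store)
        assert set(res.terms) == {"splice_region_variant", "missense_variant"}

    def test_synonymous_always_assigned_when_aa_unchanged(self, store):
        """Every coding SNV leaving the protein unchanged carries
        synonymous_variant (or stop_retained_variant at the stop codon)."""
        for tid in ("TX1", "TX2", "TXA", "TXB"):
            t = store.transcript_by_id(tid)
            seen = 0
            for pos in range(t.start, t.end + 1):
                ref = store.genome.sequence(t.chrom, pos, pos)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    res = assign_consequences(_snv(pos, ref, alt), t, store)
                    if res.ref_aa is not None and res.ref_aa == res.alt_aa:
                        seen += 1
                        assert ("synonymous_variant" in res.terms
                                or "stop_retained_variant" in res.terms)
            assert seen > 0, tid

    def test_truth_table_agreement(self, store, fixture_variants, truth_rows):
        """The engine reproduces the generated truth table exactly."""
        for (vid, alt, feat_id), expected in truth_rows.items():
            v = fixture_variants[vid]
            allele = VariantAllele(v, alt, v.alt_alleles.index(alt))
            if feat_id == "-":
                feats = store.query_overlaps(v)
                assert len(feats) == 0, vid
                res = assign_consequences(allele, None, store)
            else:
                match = [f for f in store.query_overlaps(v).all
                         if f.id == feat_id]
                assert match, (vid, feat_id)
                res = assign_consequences(allele, match[0], store)
            assert set(res.terms) == expected, (vid, alt, feat_id)

    def test_intergenic_when_no_feature(self, store):
        res = assign_consequences(_snv(500, "A", "C", chrom="chrU"), None, store)
        assert res.terms == ["intergenic_variant"]


class TestGatingSoundness:
    def test_gates_change_work_not_results(self, store, fixture_variants):
        """Identical terms with gates on/off; strictly fewer evaluations on."""
        on = RunStatistics(p=N_PREDICATES)
        off = RunStatistics(p=N_PREDICATES)
        for v in fixture_variants.values():
            feats = store.query_overlaps(v)
            for stats in (on, off):
                stats.n += len(v.alt_alleles)
                stats.f += len(feats)
            for i, alt in enumerate(v.alt_alleles):
                allele = VariantAllele(v, alt, i)
                for feat in feats.all:
                    a = assign_consequences(allele, feat, store, stats=on,
                                            gates=True)
                    b = assign_consequences(allele, feat, store, stats=off,
                                            gates=False)
                    assert a.terms == b.terms
        assert on.predicate_evaluations < off.predicate_evaluations
        assert off.predicate_evaluations_skipped == 0
        on.check(), off.check()


class TestStructuralVariants:
    def _sv(self, start, end, sv_type, chrom="chrT"):
        v = Variant(chrom=chrom, start=start, end=end, ref_allele="N",
                    alt_alleles=[f"<{sv_type}>"], is_structural=True,
                    sv_type=sv_type)
        return v

    def test_deletion_containing_transcript_ablates(self, store):
        t = store.transcript_by_id("TX3")
        assert assign_sv_consequences(
            self._sv(14900, 15500, "DEL"), t) == ["transcript_ablation"]

    def test_partial_duplication_elongates(self, store):
        t = store.transcript_by_id("TXO1")
        assert assign_sv_consequences(
            self._sv(3550, 3700, "DUP"), t) == ["feature_elongation"]

    def test_partial_deletion_truncates_and_marks_cds(self, store):
        t = store.transcript_by_id("TX1")
        assert assign_sv_consequences(self._sv(85, 120, "DEL"), t) == [
            "feature_truncation", "coding_sequence_variant"]

    def test_flank_only_sv_is_up_or_downstream(self, store):
        t = store.transcript_by_id("TXA")
        assert assign_sv_consequences(
            self._sv(35000, 35100, "DEL"), t) == ["downstream_gene_variant"]

    def test_non_structural_variant_rejected(self, store):
        t = store.transcript_by_id("TX1")
        v = Variant(chrom="chrT", start=25, end=25, ref_allele="C",
                    alt_alleles=["T"])
        with pytest.raises(ValueError):
            assign_sv_consequences(v, t)


class TestRunStatistics:
    def test_counter_bound_holds_on_fixture(self, store, fixture_variants):
        stats = RunStatistics(p=N_PREDICATES)
        for v in fixture_variants.values():
            feats = store.query_overlaps(v)
            stats.n += len(v.alt_alleles)
            stats.f += len(feats)
            for i, alt in enumerate(v.alt_alleles):
                allele = VariantAllele(v, alt, i)
                for feat in feats.all:
                    assign_consequences(allele, feat, store, stats=stats)
        stats.check()
        total = stats.predicate_evaluations + stats.predicate_evaluations_skipped
        assert total <= stats.n * stats.f * stats.p
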
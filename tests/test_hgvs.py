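"""HGVS generation, 3' normalisation, and input parsing."""

import pytest

from conseq.hgvs import (HgvsError, UnsupportedNotationError, hgvs_c, hgvs_g,
                         hgvs_p, parse_hgvs_input)
from conseq.variants import Variant, VariantAllele


def _allele(chrom, start, end, ref, alt):
    v = Variant(chrom=chrom, start=start, end=end, ref_allele=ref,
                alt_alleles=[alt])
    return VariantAllele(v, alt, 0)


class TestHgvsG:
    def test_snv_direct_format(self, store):
        a = _allele("chrT", 25, 25, "C", "T")
        assert hgvs_g(a, genome=store.genome).description == "chrT:g.25C>T"

    def test_deletion_shifts_to_3prime_of_homopolymer(self, store):
        # genome ...T A A A C... at 100-104: deleting the A at 101 is
        # equivalently the A at 103, the 3'-most representation
        a = _allele("chrT", 101, 101, "A", "-")
        assert hgvs_g(a, genome=store.genome).description == "chrT:g.103del"

    def test_insertion_into_run_is_duplication(self, store):
        a = _allele("chrT", 103, 102, "-", "A")
        assert hgvs_g(a, genome=store.genome).description == "chrT:g.103dup"

    def test_identity_allele(self, store):
        a = _allele("chrT", 25, 25, "C", "C")
        assert hgvs_g(a, genome=store.genome).description == "chrT:g.25C="

    def test_structural_variant_unsupported(self, store):
        v = Variant(chrom="chrT", start=100, end=400, ref_allele="N",
                    alt_alleles=["<DEL>"], is_structural=True, sv_type="DEL")
        with pytest.raises(UnsupportedNotationError):
            hgvs_g(VariantAllele(v, "<DEL>", 0), genome=store.genome)


class TestHgvsC:
    def test_coding_snv(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 25, 25, "C", "T")
        assert hgvs_c(a, t, store).description == "TX1.1:c.5C>T"

    def test_5prime_utr_negative_position(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 18, 18, "A", "G")
        assert hgvs_c(a, t, store).description == "TX1.1:c.-3A>G"

    def test_3prime_utr_star_position(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 93, 93, "T", "G")
        assert hgvs_c(a, t, store).description == "TX1.1:c.*3T>G"

    def test_intronic_offset_from_donor(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 52, 52, "T", "C")
        assert hgvs_c(a, t, store).description == "TX1.1:c.30+2T>C"

    def test_intronic_offset_from_acceptor(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 59, 59, "A", "G")
        assert hgvs_c(a, t, store).description == "TX1.1:c.31-2A>G"

    def test_deletion_shifts_3prime_in_cdna_tract(self, store):
        # cDNA AAAA tract at c.7-10: any single-base deletion names c.10
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 27, 27, "A", "-")
        assert hgvs_c(a, t, store).description == "TX1.1:c.10del"

    def test_minus_strand_shift_moves_to_lower_genomic(self, store):
        # TX2 carries the same cDNA tract; transcript 3' is genomic left
        t = store.transcript_by_id("TX2")
        for gpos in (9241, 9242, 9243, 9244):
            a = _allele("chrT", gpos, gpos, "T", "-")
            assert hgvs_c(a, t, store).description == "TX2.1:c.10del"

    def test_non_coding_uses_n_level(self, store):
        t = store.transcript_by_id("TX3")
        ref = store.genome.sequence("chrT", 15100, 15100)
        alt = "A" if ref != "A" else "C"
        desc = hgvs_c(_allele("chrT", 15100, 15100, ref, alt), t, store)
        assert desc.level == "n"
        assert desc.description.startswith("TX3.1:n.100")

    def test_versioned_accession_always_present(self, store, fixture_variants):
        for tid in ("TX1", "TX2", "TXO1", "TXO2"):
            t = store.transcript_by_id(tid)
            a = _allele("chrT", t.cds_genomic_start + 4, t.cds_genomic_start + 4,
                        store.genome.sequence("chrT", t.cds_genomic_start + 4,
                                              t.cds_genomic_start + 4), "-")
            assert hgvs_c(a, t, store).description.startswith(f"{tid}.1:")


class TestHgvsP:
    def test_missense_three_letter(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 25, 25, "C", "T")
        assert hgvs_p(a, t, store).description == "TX1.1:p.Ala2Val"

    def test_synonymous_equals_sign(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 29, 29, "A", "G")
        assert hgvs_p(a, t, store).description == "TX1.1:p.Lys3="

    def test_nonsense_named_ter(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 77, 77, "T", "A")  # TTA codon 16 -> TAA
        assert hgvs_p(a, t, store).description == "TX1.1:p.Leu16Ter"

    def test_frameshift_reports_new_stop_distance(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 25, 25, "C", "-")
        desc = hgvs_p(a, t, store).description
        assert "fsTer" in desc
        # verify the distance against an independent re-translation
        from conseq.store import translate_cds
        cds = store.cds_sequence(t)
        cdna = store.spliced_sequence(t)
        mutant = cds[:4] + cds[5:] + cdna[t.cdna_coding_end:]
        prot = translate_cds(mutant)
        first_diff = next(i for i, (x, y) in enumerate(
            zip(translate_cds(cds), prot)) if x != y)
        stop_dist = prot[first_diff:].index("*") + 1
        assert desc.endswith(f"fsTer{stop_dist}")

    def test_stop_lost_extension(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 90, 90, "A", "C")
        desc = hgvs_p(a, t, store).description
        # 3'UTR reads CAT TAA...: Cys and His added, new stop 2 codons on
        assert desc == "TX1.1:p.Ter20CysextTer2"

    def test_start_lost_is_unknown_effect(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 22, 22, "T", "C")
        assert hgvs_p(a, t, store).description == "TX1.1:p.Met1?"

    def test_inframe_deletion(self, store):
        t = store.transcript_by_id("TX1")
        v = Variant(chrom="chrT", start=27, end=29, ref_allele="AAA",
                    alt_alleles=["-"])
        desc = hgvs_p(VariantAllele(v, "-", 0), t, store).description
        assert desc == "TX1.1:p.Lys3del"

    def test_non_coding_effect_is_absent(self, store):
        t = store.transcript_by_id("TX1")
        a = _allele("chrT", 55, 55, "T", "A")  # intronic
        assert hgvs_p(a, t, store) is None


class TestRoundTrip:
    def test_coding_snvs_round_trip_through_c_notation(self, store):
        """parse_hgvs_input(hgvs_c(v, T)) recovers every coding SNV."""
        n = 0
        for tid in ("TX1", "TX2", "TXO1", "TXO2", "TXA", "TXB"):
            t = store.transcript_by_id(tid)
            ccs, cce = t.cds_genomic_start, t.cds_genomic_end
            for pos in range(ccs, cce + 1, 7):
                if t.cds_position(pos) is None:
                    continue
                ref = store.genome.sequence(t.chrom, pos, pos)
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    a = _allele(t.chrom, pos, pos, ref, alt)
                    back = parse_hgvs_input(
                        hgvs_c(a, t, store).description, store)
                    assert (back.chrom, back.start, back.end, back.ref_allele,
                            back.alt_alleles) == (t.chrom, pos, pos, ref, [alt])
                    n += 1
        assert n > 300

    def test_g_notation_round_trip(self, store):
        a = _allele("chrT", 25, 25, "C", "T")
        back = parse_hgvs_input(hgvs_g(a, genome=store.genome).description,
                                store)
        assert (back.start, back.ref_allele, back.alt_alleles) == (25, "C", ["T"])


class TestThreePrimeMaximality:
    def _equivalent_del_starts(self, seq, i, length):
        """All 0-based starts whose deletion yields the same sequence."""
        target = seq[:i] + seq[i + length:]
        return [j for j in range(len(seq) - length + 1)
                if seq[:j] + seq[j + length:] == target]

    def test_reported_genomic_deletion_is_maximal(self, store):
        # brute force over the T AAA C run at 100-104
        seq = store.genome.sequence("chrT", 95, 110)
        a = _allele("chrT", 101, 101, "A", "-")
        desc = hgvs_g(a, genome=store.genome).description
        pos = int(desc.split("g.")[1].replace("del", ""))
        starts = self._equivalent_del_starts(seq, 101 - 95, 1)
        assert pos - 95 == max(starts)

    def test_reported_cdna_deletion_is_maximal(self, store):
        for tid in ("TX1", "TX2"):
            t = store.transcript_by_id(tid)
            cdna = store.spliced_sequence(t)
            # the engineered AAAA tract sits at cDNA 57-60 (c.7-10)
            for c0 in range(56, 60):
                gpos = t.genomic_position(c0 + 1)
                ref = store.genome.sequence(t.chrom, gpos, gpos)
                a = _allele(t.chrom, gpos, gpos, ref, "-")
                desc = hgvs_c(a, t, store).description
                reported = int(desc.split("c.")[1].replace("del", ""))
                cdna_idx = reported + t.cdna_coding_start - 1  # 1-based cDNA
                starts = self._equivalent_del_starts(cdna, c0, 1)
                assert cdna_idx - 1 == max(starts), (tid, c0)


class TestParseHgvsInput:
    def test_unknown_transcript_is_resolution_error(self, store):
        with pytest.raises(HgvsError, match="unknown transcript"):
            parse_hgvs_input("NOPE.1:c.5C>T", store)

    def test_protein_level_unsupported(self, store):
        with pytest.raises(UnsupportedNotationError):
            parse_hgvs_input("TX1.1:p.Ala2Val", store)

    def test_version_mismatch_resolves_on_accession(self, store, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="conseq.hgvs"):
            v = parse_hgvs_input("TX1.9:c.5C>T", store)
        assert v.start == 25
        assert any("version mismatch" in r.message for r in caplog.records)

    def test_utr_and_intron_positions(self, store):
        assert parse_hgvs_input("TX1.1:c.-3A>G", store).start == 18
        assert parse_hgvs_input("TX1.1:c.*3T>G", store).start == 93
        assert parse_hgvs_input("TX1.1:c.30+2T>C", store).start == 52

    def test_minus_strand_alleles_complemented(self, store):
        v = parse_hgvs_input("TX2.1:c.5C>T", store)
        assert (v.start, v.ref_allele, v.alt_alleles) == (9246, "G", ["A"])
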
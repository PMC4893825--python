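"""Cache build, overlap queries, sequences, and translation."""

import json

import pytest

from conseq.cache import CacheBuildError, build_cache
from conseq.models import Interval, KnownVariant, MotifFeature, Transcript
from conseq.store import AnnotationStore, translate_cds
from conseq.variants import Variant

GFF_HEADER = "##gff-version 3\n"


def _write_fasta(path, chroms):
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n{seq}\n")


class TestBuildCache:
    def test_single_bin_single_transcript(self, tmp_path):
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "ACGT" * 2500})
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF_HEADER
                       + "c1\tx\tgene\t100\t400\t.\t+\t.\tID=g1\n"
                       + "c1\tx\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1\n"
                       + "c1\tx\texon\t100\t400\t.\t+\t.\tID=t1.e1;Parent=t1\n")
        manifest = build_cache(gff, fasta, tmp_path / "cache")
        assert manifest["counts"]["transcripts"] == 1
        assert manifest["chroms"]["c1"]["bins"] == [0]

    def test_bin_spanning_feature_deduplicated_on_query(self, tmp_path):
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "A" * 1_100_000})
        gff = tmp_path / "a.gff3"
        gff.write_text(
            GFF_HEADER
            + "c1\tx\tgene\t999900\t1000100\t.\t+\t.\tID=g1\n"
            + "c1\tx\tmRNA\t999900\t1000100\t.\t+\t.\tID=t1;Parent=g1\n"
            + "c1\tx\texon\t999900\t1000100\t.\t+\t.\tID=t1.e1;Parent=t1\n")
        manifest = build_cache(gff, fasta, tmp_path / "cache")
        assert manifest["chroms"]["c1"]["bins"] == [0, 1]
        store = AnnotationStore(tmp_path / "cache")
        v = Variant(chrom="c1", start=999_999, end=1_000_001,
                    ref_allele="AAA", alt_alleles=["-"])
        hits = store.query_overlaps(v, flank=0)
        assert [t.id for t in hits.transcripts] == ["t1"]

    def test_empty_annotation_yields_empty_manifest(self, tmp_path):
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "ACGT" * 100})
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF_HEADER)
        manifest = build_cache(gff, fasta, tmp_path / "cache")
        assert manifest["counts"]["transcripts"] == 0
        assert manifest["chroms"]["c1"]["bins"] == []

    def test_exon_outside_chromosome_is_build_error(self, tmp_path):
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "ACGT" * 10})
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF_HEADER
                       + "c1\tx\tgene\t1\t900\t.\t+\t.\tID=g1\n"
                       + "c1\tx\tmRNA\t1\t900\t.\t+\t.\tID=t1;Parent=g1\n"
                       + "c1\tx\texon\t1\t900\t.\t+\t.\tID=t1.e1;Parent=t1\n")
        with pytest.raises(CacheBuildError, match="t1"):
            build_cache(gff, fasta, tmp_path / "cache")

    def test_phase_inconsistency_is_build_error(self, tmp_path):
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "ACGT" * 100})
        gff = tmp_path / "a.gff3"
        gff.write_text(
            GFF_HEADER
            + "c1\tx\tgene\t1\t60\t.\t+\t.\tID=g1\n"
            + "c1\tx\tmRNA\t1\t60\t.\t+\t.\tID=t1;Parent=g1\n"
            + "c1\tx\texon\t1\t60\t.\t+\t.\tID=t1.e1;Parent=t1\n"
            + "c1\tx\tCDS\t10\t30\t.\t+\t2\tID=t1.c1;Parent=t1\n")
        with pytest.raises(CacheBuildError, match="phase"):
            build_cache(gff, fasta, tmp_path / "cache")


class TestQueryOverlaps:
    def _snv(self, pos, chrom="chrT"):
        return Variant(chrom=chrom, start=pos, end=pos, ref_allele="A",
                       alt_alleles=["C"])

    def test_snv_inside_exon_returns_transcript(self, store):
        hits = store.query_overlaps(self._snv(25))
        assert "TX1" in [t.id for t in hits.transcripts]

    def test_flank_boundary_inclusive_at_5000(self, store):
        # TXA/TXB end at 30200
        at_5000 = store.query_overlaps(self._snv(35200))
        beyond = store.query_overlaps(self._snv(35201))
        assert {"TXA", "TXB"} <= {t.id for t in at_5000.transcripts}
        assert not beyond.transcripts

    def test_chromosome_without_features_is_empty(self, store):
        hits = store.query_overlaps(self._snv(500, chrom="chrU"))
        assert len(hits) == 0

    def test_absent_chromosome_warns_once(self, cache_dir):
        s = AnnotationStore(cache_dir)
        s.query_overlaps(self._snv(5, chrom="chrZZ"))
        s.query_overlaps(self._snv(6, chrom="chrZZ"))
        assert len(s.warnings) == 1

    def test_matches_brute_force_scan(self, store, fixture_variants):
        """Tree-backed query equals a linear scan over all features."""
        features = [f for f in store._scan_all()
                    if not isinstance(f, KnownVariant)]
        for v in fixture_variants.values():
            got = {(type(f).__name__, f.id)
                   for f in store.query_overlaps(v, flank=5000).all}
            s, e = v.span()
            expected = set()
            for f in features:
                if f.chrom != v.chrom:
                    continue
                if isinstance(f, Transcript):
                    if f.start - 5000 <= e and f.end + 5000 >= s:
                        expected.add(("Transcript", f.id))
                elif v.is_insertion_site:
                    if f.start <= s and e <= f.end:
                        expected.add((type(f).__name__, f.id))
                elif f.overlaps(s, e):
                    expected.add((type(f).__name__, f.id))
            assert got == expected, v.id

    def test_memoization_is_behaviourally_invisible(self, cache_dir,
                                                    fixture_variants):
        memo = AnnotationStore(cache_dir, memoize=True)
        plain = AnnotationStore(cache_dir, memoize=False)
        for v in fixture_variants.values():
            a = [(type(f).__name__, f.id) for f in memo.query_overlaps(v).all]
            b = [(type(f).__name__, f.id) for f in plain.query_overlaps(v).all]
            assert a == b
        assert memo.bins_loaded < plain.bins_loaded

    def test_insertion_requires_containment(self, store):
        # MOT1 spans 18101-18108; insertion between 18108 and 18109 is outside
        inside = Variant(chrom="chrT", start=18105, end=18104,
                         ref_allele="-", alt_alleles=["A"])
        edge = Variant(chrom="chrT", start=18109, end=18108,
                       ref_allele="-", alt_alleles=["A"])
        assert [m.id for m in store.query_overlaps(inside).motifs] == ["MOT1"]
        assert not store.query_overlaps(edge).motifs


class TestSequences:
    def test_spliced_forward_single_exon_is_genomic_substring(self, store):
        t = store.transcript_by_id("TX5")
        assert store.spliced_sequence(t) == store.genome.sequence(
            "chrT", 22001, 22100)

    def test_spliced_minus_strand_reverse_complements(self, tmp_path):
        t = Transcript(id="m", chrom="c1", strand=-1,
                       exons=[Interval(1, 6)])
        fasta = tmp_path / "g.fa"
        _write_fasta(fasta, {"c1": "AACCGG"})
        gff = tmp_path / "a.gff3"
        gff.write_text(GFF_HEADER)
        build_cache(gff, fasta, tmp_path / "cache")
        store = AnnotationStore(tmp_path / "cache")
        assert store.spliced_sequence(t) == "CCGGTT"

    def test_two_exon_splice_skips_intron(self, store):
        t = store.transcript_by_id("TX1")
        cdna = store.spliced_sequence(t)
        assert len(cdna) == 80
        assert cdna == (store.genome.sequence("chrT", 11, 50)
                        + store.genome.sequence("chrT", 61, 100))

    def test_cds_is_contiguous_substring_of_cdna(self, store):
        for tid in ("TX1", "TX2", "TXO1", "TXO2", "TXA", "TXB"):
            t = store.transcript_by_id(tid)
            assert store.cds_sequence(t) in store.spliced_sequence(t)

    def test_spliced_length_equals_exon_sum(self, store):
        for f in store._scan_all():
            if isinstance(f, Transcript):
                assert len(store.spliced_sequence(f)) == f.length


class TestTranslate:
    def test_standard_table(self):
        assert translate_cds("ATGGCCTGA") == "MA*"

    def test_vertebrate_mito_stops_and_trp(self):
        # AGA/AGG are stops under the vertebrate mito table; TGA is Trp
        assert translate_cds("ATGAGATGA", table=2) == "M*W"
        assert translate_cds("ATGAGGTAA", table=2) == "M**"
        assert translate_cds("ATGTGAAAA", table=2) == "MWK"

    def test_selenocysteine_renders_u(self):
        assert translate_cds("ATGTGA", selenocysteine=(2,)) == "MU"

    def test_trailing_incomplete_codon_dropped(self):
        assert translate_cds("ATGGC") == "M"

    def test_non_acgtn_raises(self):
        with pytest.raises(ValueError):
            translate_cds("ATGXYZ")

    def test_n_codon_is_x(self):
        assert translate_cds("ATGNNN") == "MX"
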
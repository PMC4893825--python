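"""VCF parsing, allele normalisation, and QC."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from conseq.variants import (QCReport, VcfReader, WarningsLog, minimise_alleles,
                             qc_check, read_vcf, Variant)

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _parse(body: str):
    return read_vcf(io.StringIO(VCF_HEADER + body), WarningsLog())


class TestReadVcf:
    def test_snv_identity_mapping(self):
        (v,) = _parse("1\t100\t.\tC\tT\t.\t.\t.\n")
        assert (v.chrom, v.start, v.end, v.ref_allele, v.alt_alleles) == (
            "1", 100, 100, "C", ["T"])
        assert not v.is_structural

    def test_deletion_anchor_stripped(self):
        (v,) = _parse("1\t100\t.\tTA\tT\t.\t.\t.\n")
        assert (v.start, v.end, v.ref_allele, v.alt_alleles) == (
            101, 101, "A", ["-"])

    def test_insertion_start_is_end_plus_one(self):
        (v,) = _parse("1\t100\t.\tT\tTG\t.\t.\t.\n")
        assert (v.start, v.end, v.ref_allele, v.alt_alleles) == (
            101, 100, "-", ["G"])
        assert v.is_insertion_site

    def test_multiallelic_kept_on_one_variant(self):
        (v,) = _parse("1\t100\t.\tC\tT,G\t.\t.\t.\n")
        assert v.alt_alleles == ["T", "G"]

    def test_symbolic_sv_with_end(self):
        (v,) = _parse("1\t100\tsv1\tN\t<DEL>\t.\t.\tSVTYPE=DEL;END=230\n")
        assert v.is_structural and v.sv_type == "DEL"
        assert (v.start, v.end) == (100, 230)

    def test_long_plain_allele_is_structural(self):
        (v,) = _parse(f"1\t100\t.\tA\tA{'G' * 60}\t.\t.\t.\n")
        assert v.is_structural and v.sv_type == "INS"

    def test_malformed_line_skipped_and_logged(self):
        warnings = WarningsLog()
        variants = read_vcf(io.StringIO(
            VCF_HEADER
            + "1\tnot_a_number\t.\tC\tT\t.\t.\t.\n"
            + "1\t200\t.\tC\tT\t.\t.\t.\n"), warnings)
        assert [v.start for v in variants] == [200]
        assert len(warnings) == 1
        assert warnings.records[0][1] == "MALFORMED_LINE"

    def test_missing_required_column_is_fatal(self):
        stream = io.StringIO("#CHROM\tPOS\tID\tREF\n1\t1\t.\tC\n")
        with pytest.raises(ValueError, match="required columns"):
            read_vcf(stream, WarningsLog())

    def test_input_order_preserved(self):
        body = "".join(f"1\t{100 + i}\t.\tC\tT\t.\t.\t.\n" for i in range(25))
        variants = _parse(body)
        assert [v.input_index for v in variants] == list(range(25))


class TestRoundTrip:
    def test_internal_to_vcf_to_internal_identity(self, fixture_dir,
                                                  fixture_variants):
        """Re-serialising parsed fixture variants and re-parsing reproduces
        identical (chrom, start, end, ref, alts)."""
        lines = [VCF_HEADER.rstrip("\n")]
        for v in fixture_variants.values():
            lines.append("\t".join(v.raw_vcf_fields))
        reread = read_vcf(io.StringIO("\n".join(lines) + "\n"), WarningsLog())
        assert len(reread) == len(fixture_variants)
        for new, old in zip(reread, fixture_variants.values()):
            assert new.key() == old.key()


class TestMinimiseAlleles:
    @pytest.mark.parametrize("given,expected", [
        ((100, "AC", "AG"), (101, "C", "G")),
        ((100, "TACGT", "TAAGT"), (102, "C", "A")),
        ((100, "A", "A"), (100, "-", "-")),
        ((100, "CAAA", "C"), (101, "AAA", "-")),
        ((100, "C", "CTA"), (101, "-", "TA")),
    ])
    def test_stripping_examples(self, given, expected):
        assert minimise_alleles(*given) == expected

    @given(start=st.integers(1, 10**6),
           ref=st.text(alphabet="ACGT", min_size=1, max_size=8),
           alt=st.text(alphabet="ACGT", min_size=1, max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, start, ref, alt):
        once = minimise_alleles(start, ref, alt)
        assert minimise_alleles(*once) == once


class TestQC:
    def test_matching_reference_passes(self, store):
        v = Variant(chrom="chrT", start=25, end=25, ref_allele="C",
                    alt_alleles=["T"])
        assert qc_check(v, store.genome).ok

    def test_reference_mismatch_flagged(self, store):
        v = Variant(chrom="chrT", start=25, end=25, ref_allele="G",
                    alt_alleles=["T"])
        assert qc_check(v, store.genome).codes == {QCReport.REF_MISMATCH}

    def test_length_mismatch_flagged(self):
        v = Variant(chrom="chrT", start=100, end=100, ref_allele="AC",
                    alt_alleles=["A"])
        assert QCReport.LENGTH_MISMATCH in qc_check(v).codes

    def test_bad_allele_characters_flagged(self):
        v = Variant(chrom="chrT", start=100, end=100, ref_allele="C",
                    alt_alleles=["Z"])
        assert QCReport.BAD_ALLELE_CHARS in qc_check(v).codes

    def test_coordinate_order_flagged(self):
        v = Variant(chrom="chrT", start=120, end=100, ref_allele="C",
                    alt_alleles=["T"])
        assert QCReport.COORD_ORDER in qc_check(v).codes

    def test_qc_degrades_without_genome(self):
        v = Variant(chrom="chrT", start=25, end=25, ref_allele="G",
                    alt_alleles=["T"])
        assert qc_check(v, None).ok  # coordinate-only checks
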
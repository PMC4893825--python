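"""Writers, prioritisation, and the filter language."""

import io
import json

import pytest

from conseq.engine import OverlapResult, assign_consequences
from conseq.filters import (FilterSyntaxError, apply_filter, parse_filter,
                            per_gene, pick_one)
from conseq.output import (CSQ_FIELDS, result_to_row, write_json, write_tab,
                           write_vcf)
from conseq.pipeline import annotate_variant, AnnotateConfig
from conseq.registry import default_registry
from conseq.models import RunStatistics
from conseq.variants import Variant, VariantAllele, WarningsLog


@pytest.fixture(scope="module")
def registry():
    return default_registry()


def _results_for(store, variant, flank=5000):
    feats = store.query_overlaps(variant, flank=flank)
    out = []
    for i, alt in enumerate(variant.alt_alleles):
        allele = VariantAllele(variant, alt, i)
        for f in (feats.all or [None]):
            out.append(assign_consequences(allele, f, store, flank=flank))
    return out


@pytest.fixture(scope="module")
def cardinality_results(store):
    """The isolated 2-alt x 2-transcript probe at chrT:30050."""
    v = Variant(chrom="chrT", start=30050, end=30050, ref_allele="C",
                alt_alleles=["G", "T"], id="vcard")
    return v, _results_for(store, v)


class TestCardinality:
    def test_one_row_per_allele_per_feature(self, cardinality_results):
        v, results = cardinality_results
        assert len(results) == 4
        pairs = {(r.allele.allele, r.feature.id) for r in results}
        assert pairs == {("G", "TXA"), ("G", "TXB"),
                         ("T", "TXA"), ("T", "TXB")}

    def test_tab_writer_emits_four_rows(self, cardinality_results, registry):
        _, results = cardinality_results
        sink = io.StringIO()
        write_tab(results, sink, registry=registry)
        rows = [l for l in sink.getvalue().splitlines()
                if l and not l.startswith("#")]
        assert len(rows) == 4

    def test_vcf_writer_emits_four_csq_blocks(self, cardinality_results,
                                              registry):
        v, results = cardinality_results
        sink = io.StringIO()
        write_vcf([(v, results)], sink, registry=registry)
        data = [l for l in sink.getvalue().splitlines()
                if l and not l.startswith("#")]
        assert len(data) == 1
        info = data[0].split("\t")[7]
        csq = [f for f in info.split(";") if f.startswith("CSQ=")][0]
        blocks = csq[4:].split(",")
        assert len(blocks) == 4
        # every block matches the field count declared in the header
        header = next(l for l in sink.getvalue().splitlines()
                      if l.startswith("##INFO=<ID=CSQ"))
        declared = header.split("Format: ")[1].rstrip('">').split("|")
        assert declared == CSQ_FIELDS
        for b in blocks:
            assert len(b.split("|")) == len(CSQ_FIELDS)

    def test_json_writer_nests_by_feature_class(self, cardinality_results,
                                                registry):
        v, results = cardinality_results
        sink = io.StringIO()
        write_json([(v, results)], sink, registry=registry)
        obj = json.loads(sink.getvalue())
        assert len(obj["transcript_consequences"]) == 4
        assert obj["most_severe_consequence"] == "missense_variant"
        assert obj["allele_string"] == "C/G/T"


class TestPick:
    def test_canonical_outranks_severity(self, cardinality_results, registry):
        _, results = cardinality_results
        g_results = [r for r in results if r.allele.allele == "G"]
        # TXA (canonical) carries intron_variant, TXB (non-canonical) missense
        best = pick_one(g_results, registry)
        assert best.feature.id == "TXA"
        assert best.terms == ["intron_variant"]

    def test_severity_breaks_ties_without_canonical(self, store, registry):
        v = Variant(chrom="chrT", start=30050, end=30050, ref_allele="C",
                    alt_alleles=["G"])
        allele = VariantAllele(v, "G", 0)
        txb = store.transcript_by_id("TXB")
        missense = assign_consequences(allele, txb, store)
        intronic = OverlapResult(allele=allele, feature=txb,
                                 terms=["intron_variant"])
        assert pick_one([intronic, missense], registry) is missense

    def test_transcript_id_is_final_tiebreak(self, store, registry):
        v = Variant(chrom="chrT", start=30050, end=30050, ref_allele="C",
                    alt_alleles=["G"])
        allele = VariantAllele(v, "G", 0)
        txb = store.transcript_by_id("TXB")
        a = OverlapResult(allele=allele, feature=txb, terms=["intron_variant"])
        b = OverlapResult(allele=allele, feature=txb, terms=["intron_variant"])
        assert pick_one([b, a], registry) in (a, b)

    def test_per_gene_keeps_one_per_gene(self, cardinality_results, registry):
        _, results = cardinality_results
        g_results = [r for r in results if r.allele.allele == "G"]
        picked = per_gene(g_results, registry)
        assert sorted(r.feature.gene_id for r in picked) == ["GA", "GB"]

    def test_pick_requires_results(self, registry):
        with pytest.raises(ValueError):
            pick_one([], registry)


def _fake_result(terms, extras, registry, feature=None):
    v = Variant(chrom="chrT", start=1, end=1, ref_allele="A",
                alt_alleles=["C"])
    return OverlapResult(allele=VariantAllele(v, "C", 0), feature=feature,
                         terms=terms, extras=extras)


class TestFilterLanguage:
    def test_consequence_is(self, store, registry):
        results = [
            _fake_result(["missense_variant"], {}, registry),
            _fake_result(["intron_variant"], {}, registry),
        ]
        expr = parse_filter("Consequence is missense_variant")
        assert apply_filter(expr, results, registry) == [results[0]]

    def test_sift_or_polyphen_example(self, registry):
        rows = [
            _fake_result(["missense_variant"], {"SIFT": "deleterious"}, registry),
            _fake_result(["missense_variant"],
                         {"PolyPhen": "probably_damaging"}, registry),
            _fake_result(["missense_variant"], {"SIFT": "tolerated"}, registry),
        ]
        expr = parse_filter(
            "SIFT is deleterious OR PolyPhen is probably_damaging")
        assert apply_filter(expr, rows, registry) == rows[:2]

    def test_population_frequency_example(self, registry):
        kept = _fake_result([], {"AFR": "0.2", "EUR": "0.01"}, registry)
        kept.terms = ["intergenic_variant"]
        dropped = _fake_result(["intergenic_variant"],
                               {"AFR": "0.2", "EUR": "0.2"}, registry)
        expr = parse_filter("AFR >0.1 AND EUR <0.05")
        assert apply_filter(expr, [kept, dropped], registry) == [kept]

    def test_gene_list_and_matches_example(self, store, registry, tmp_path):
        gene_file = tmp_path / "gene_list.txt"
        gene_file.write_text("GA\nGX\n")
        txa = store.transcript_by_id("TXA")
        txb = store.transcript_by_id("TXB")
        r1 = _fake_result(["intron_variant"],
                          {"Phenotype": "breast cancer"}, registry, feature=txa)
        r2 = _fake_result(["intron_variant"],
                          {"Phenotype": "breast cancer"}, registry, feature=txb)
        r3 = _fake_result(["intron_variant"], {}, registry, feature=txa)
        expr = parse_filter(f"Gene in {gene_file} AND Phenotype matches cancer")
        assert apply_filter(expr, [r1, r2, r3], registry) == [r1]

    def test_and_composition_equals_sequential_application(self, registry):
        rows = [_fake_result(["intergenic_variant"],
                             {"AFR": str(a), "EUR": str(e)}, registry)
                for a in (0.05, 0.2) for e in (0.01, 0.2)]
        combined = apply_filter(parse_filter("AFR >0.1 AND EUR <0.05"),
                                rows, registry)
        sequential = apply_filter(
            parse_filter("EUR <0.05"),
            apply_filter(parse_filter("AFR >0.1"), rows, registry), registry)
        assert combined == sequential

    def test_exists_and_unknown_field(self, registry):
        with_field = _fake_result(["intergenic_variant"], {"CADD": "12"},
                                  registry)
        without = _fake_result(["intergenic_variant"], {}, registry)
        expr = parse_filter("CADD exists")
        assert apply_filter(expr, [with_field, without], registry) == [with_field]
        none = parse_filter("NoSuchField is x")
        assert apply_filter(none, [with_field], registry) == []

    @pytest.mark.parametrize("bad", [
        "", "AND", "SIFT", "SIFT frobnicates x", "A is b AND",
    ])
    def test_syntax_errors_reported(self, bad):
        with pytest.raises(FilterSyntaxError):
            parse_filter(bad)

    def test_numeric_comparison_on_non_numeric_is_false(self, registry):
        row = _fake_result(["intergenic_variant"], {"AFR": "lots"}, registry)
        expr = parse_filter("AFR >0.1")
        assert apply_filter(expr, [row], registry) == []


class TestRowRepresentation:
    def test_missense_row_fields(self, store, registry):
        v = Variant(chrom="chrT", start=25, end=25, ref_allele="C",
                    alt_alleles=["T"], id="v_mis")
        cfg = AnnotateConfig(input="", cache="")
        results = annotate_variant(v, store, cfg, registry,
                                   RunStatistics(), WarningsLog())
        row = result_to_row(
            next(r for r in results
                 if r.feature is not None and r.feature.id == "TX1"), registry)
        assert row["Consequence"] == "missense_variant"
        assert row["IMPACT"] == "MODERATE"
        assert row["Codons"] == "gCc/gTc"
        assert row["Amino_acids"] == "A/V"
        assert row["CDS_position"] == "5"
        assert row["Protein_position"] == "2"
        assert row["HGVSc"] == "TX1.1:c.5C>T"
        assert row["HGVSp"] == "TX1.1:p.Ala2Val"
        assert row["Existing_variation"] == "rsK1"
        assert row["GMAF"] == "T:0.02"
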
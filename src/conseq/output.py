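"""Result writers: tab-delimited, VCF (CSQ INFO field), and JSON.

All writers work from a flat row representation of each
:class:`~conseq.engine.OverlapResult` (``result_to_row``), which is also the
namespace the filter language evaluates against.  Headers record the tool
and cache versions and the command line; no timestamps are written, so
repeated runs over the same input are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .engine import OverlapResult
from .models import MotifFeature, RegulatoryFeature, Transcript
from .registry import Registry, default_registry, most_severe

__all__ = [
    "TAB_COLUMNS", "CSQ_FIELDS", "result_to_row", "write_tab", "write_vcf",
    "write_json", "SummaryStats",
]

TAB_COLUMNS = [
    "Uploaded_variation", "Location", "Allele", "Consequence", "IMPACT",
    "SYMBOL", "Gene", "Feature", "Feature_type", "BIOTYPE", "EXON", "INTRON",
    "HGVSc", "HGVSp", "HGVSg", "cDNA_position", "CDS_position",
    "Protein_position", "Amino_acids", "Codons", "Existing_variation",
    "DISTANCE", "STRAND", "FLAGS", "GMAF", "CLIN_SIG", "SOMATIC", "PUBMED",
    "MOTIF_NAME", "MOTIF_POS", "MOTIF_SCORE_CHANGE", "HIGH_INF_POS",
    "CELL_TYPE",
]

#: Default CSQ block fields, declared in the VCF header so consumers never guess.
CSQ_FIELDS = [
    "Allele", "Consequence", "IMPACT", "SYMBOL", "Gene", "Feature",
    "BIOTYPE", "EXON", "INTRON", "HGVSc", "HGVSp", "cDNA_position",
    "CDS_position", "Protein_position", "Amino_acids", "Codons",
    "Existing_variation", "DISTANCE", "STRAND", "FLAGS",
]

_MISSING = "-"


def _interval_str(iv: Optional[tuple[int, int]]) -> str:
    if iv is None:
        return _MISSING
    lo, hi = iv
    return str(lo) if lo == hi else f"{lo}-{hi}"


def result_to_row(res: OverlapResult,
                  registry: Optional[Registry] = None) -> dict[str, str]:
    """Flatten one result into the output/filter namespace."""
    registry = registry or default_registry()
    v = res.variant
    row: dict[str, str] = {c: _MISSING for c in TAB_COLUMNS}
    row["Uploaded_variation"] = (
        v.id or f"{v.chrom}_{v.start}_{v.ref_allele}/{res.allele.allele}")
    row["Location"] = v.location
    row["Allele"] = res.allele.allele
    row["Consequence"] = ",".join(res.terms)
    row["IMPACT"] = res.impact(registry)
    feat = res.feature
    if isinstance(feat, Transcript):
        row["SYMBOL"] = feat.gene_symbol or _MISSING
        row["Gene"] = feat.gene_id or _MISSING
        row["Feature"] = feat.accession
        row["Feature_type"] = "Transcript"
        row["BIOTYPE"] = feat.biotype
        row["STRAND"] = str(feat.strand)
        flags = []
        if feat.flags.get("canonical"):
            flags.append("canonical")
        if feat.flags.get("ccds"):
            flags.append(f"CCDS={feat.flags['ccds']}")
        if feat.flags.get("tsl"):
            flags.append(f"TSL={feat.flags['tsl']}")
        if feat.flags.get("appris"):
            flags.append(f"APPRIS={feat.flags['appris']}")
        if flags:
            row["FLAGS"] = ",".join(flags)
    elif isinstance(feat, RegulatoryFeature):
        row["Feature"] = feat.id
        row["Feature_type"] = "RegulatoryFeature"
        row["BIOTYPE"] = feat.feature_type
        if feat.cell_types:
            row["CELL_TYPE"] = ",".join(feat.cell_types)
    elif isinstance(feat, MotifFeature):
        row["Feature"] = feat.id
        row["Feature_type"] = "MotifFeature"
        row["MOTIF_NAME"] = feat.motif_name
        row["STRAND"] = str(feat.strand)
    else:
        row["Feature_type"] = "Intergenic"

    c = res.coords
    row["EXON"] = c.exon_number or _MISSING
    row["INTRON"] = c.intron_number or _MISSING
    row["cDNA_position"] = _interval_str(c.cdna_interval)
    row["CDS_position"] = _interval_str(c.cds_interval)
    row["Protein_position"] = _interval_str(c.protein_interval)
    if c.distance is not None:
        row["DISTANCE"] = str(c.distance)
    if res.ref_aa is not None:
        row["Amino_acids"] = (res.ref_aa if res.ref_aa == res.alt_aa
                              else f"{res.ref_aa}/{res.alt_aa}")
    if res.ref_codons is not None:
        row["Codons"] = f"{res.ref_codons}/{res.alt_codons}"
    if res.hgvs_c:
        row["HGVSc"] = res.hgvs_c
    if res.hgvs_p:
        row["HGVSp"] = res.hgvs_p
    if res.hgvs_g:
        row["HGVSg"] = res.hgvs_g

    if res.colocated:
        ids = [co.record.id for co in res.colocated]
        row["Existing_variation"] = ",".join(ids)
        for co in res.colocated:
            rec = co.record
            if rec.gmaf is not None and row["GMAF"] == _MISSING:
                gm = f"{rec.gmaf_allele}:{rec.gmaf}" if rec.gmaf_allele else str(rec.gmaf)
                row["GMAF"] = gm
            for pop, freq in rec.pop_freqs.items():
                row.setdefault(pop, str(freq))
                if row.get(pop, _MISSING) == _MISSING:
                    row[pop] = str(freq)
            if rec.clin_sig and row["CLIN_SIG"] == _MISSING:
                row["CLIN_SIG"] = ",".join(rec.clin_sig)
            if rec.somatic:
                row["SOMATIC"] = "1"
            if rec.pubmed_ids and row["PUBMED"] == _MISSING:
                row["PUBMED"] = ",".join(rec.pubmed_ids)
        if not all(co.allele_match for co in res.colocated):
            row["ALLELE_MISMATCH"] = "1"

    if res.motif_impact is not None:
        mi = res.motif_impact
        row["MOTIF_POS"] = str(mi.motif_position)
        row["MOTIF_SCORE_CHANGE"] = f"{mi.delta:.4f}"
        row["HIGH_INF_POS"] = "Y" if mi.informative else "N"

    for k, val in res.extras.items():
        row[k] = str(val)
    return row


def _header_lines(cache_manifest: Optional[dict], command_line: str) -> list[str]:
    lines = [f"## conseq version {__version__}"]
    if cache_manifest:
        lines.append(
            f"## Cache: species={cache_manifest.get('species')} "
            f"schema={cache_manifest.get('schema_version')} "
            f"bin_size={cache_manifest.get('bin_size')}")
    if command_line:
        lines.append(f"## Command line: {command_line}")
    return lines


def write_tab(results: list[OverlapResult], sink, *,
              registry: Optional[Registry] = None,
              cache_manifest: Optional[dict] = None,
              command_line: str = "") -> None:
    """One row per OverlapResult with a fixed, documented column order.

    Fields outside the fixed columns (custom tracks, plugins, population
    frequencies) are serialised as ``key=value`` pairs in a final Extra
    column.
    """
    registry = registry or default_registry()
    for line in _header_lines(cache_manifest, command_line):
        sink.write(line + "\n")
    sink.write("#" + "\t".join(TAB_COLUMNS + ["Extra"]) + "\n")
    for res in results:
        row = result_to_row(res, registry)
        extra = ";".join(
            f"{k}={row[k]}" for k in sorted(row) if k not in TAB_COLUMNS)
        sink.write("\t".join([row[c] for c in TAB_COLUMNS]
                             + [extra or _MISSING]) + "\n")


# ---------------------------------------------------------------------------
# VCF output

_CSQ_ESCAPES = {"%": "%25", "|": "%7C", ",": "%2C", ";": "%3B", "=": "%3D",
                " ": "%20"}


def _csq_escape(value: str) -> str:
    for raw, esc in _CSQ_ESCAPES.items():
        value = value.replace(raw, esc)
    return value


def write_vcf(variant_results: list[tuple], sink, *,
              input_headers: Optional[list[str]] = None,
              csq_fields: Optional[list[str]] = None,
              registry: Optional[Registry] = None,
              cache_manifest: Optional[dict] = None,
              command_line: str = "") -> None:
    """Echo input VCF records with a CSQ INFO field.

    ``variant_results`` is a list of (Variant, [OverlapResult, ...]) in
    output order.  Annotation blocks are comma-separated, fields within a
    block pipe-separated in the order declared in the CSQ header line;
    reserved characters inside fields are percent-escaped.
    """
    registry = registry or default_registry()
    csq_fields = csq_fields or CSQ_FIELDS
    headers = list(input_headers or [])
    if not headers or not headers[0].startswith("##fileformat"):
        headers.insert(0, "##fileformat=VCFv4.2")
    body_header = [h for h in headers if h.startswith("#") and not h.startswith("##")]
    meta = [h for h in headers if h.startswith("##")]
    for line in meta:
        sink.write(line + "\n")
    for line in _header_lines(cache_manifest, command_line):
        sink.write("##conseq=" + line.lstrip("# ") + "\n")
    sink.write(
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
        'annotations from conseq. Format: ' + "|".join(csq_fields) + '">\n')
    if body_header:
        sink.write(body_header[-1] + "\n")
    else:
        sink.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")

    for variant, results in variant_results:
        fields = list(variant.raw_vcf_fields or _synthesise_vcf_fields(variant))
        while len(fields) < 8:
            fields.append(".")
        blocks = []
        for res in results:
            row = result_to_row(res, registry)
            blocks.append("|".join(
                _csq_escape(row.get(f, _MISSING).replace(_MISSING, "")
                            if row.get(f, _MISSING) == _MISSING
                            else row.get(f, ""))
                for f in csq_fields))
        if blocks:
            csq = "CSQ=" + ",".join(blocks)
            fields[7] = csq if fields[7] in (".", "") else fields[7] + ";" + csq
        sink.write("\t".join(fields) + "\n")


def _synthesise_vcf_fields(v) -> list[str]:
    """Minimal VCF columns for variants that did not arrive as VCF."""
    if v.ref_allele == "-" or any(a == "-" for a in v.alt_alleles):
        # re-anchor the internal representation
        pos = v.start - 1
        ref = "N" + ("" if v.ref_allele == "-" else v.ref_allele)
        alts = ["N" + ("" if a == "-" else a) for a in v.alt_alleles]
    else:
        pos, ref, alts = v.start, v.ref_allele, list(v.alt_alleles)
    return [v.chrom, str(pos), v.id or ".", ref, ",".join(alts), ".", ".", "."]


# ---------------------------------------------------------------------------
# JSON output


def write_json(variant_results: list[tuple], sink, *,
               registry: Optional[Registry] = None) -> None:
    """One JSON object per input variant, consequences nested per class."""
    registry = registry or default_registry()
    for variant, results in variant_results:
        obj = {
            "id": variant.id,
            "seq_region_name": variant.chrom,
            "start": variant.start,
            "end": variant.end,
            "allele_string": "/".join(variant.alleles),
            "input_index": variant.input_index,
        }
        all_terms = [t for r in results for t in r.terms]
        if all_terms:
            obj["most_severe_consequence"] = most_severe(all_terms, registry)
        buckets = {
            "Transcript": "transcript_consequences",
            "RegulatoryFeature": "regulatory_feature_consequences",
            "MotifFeature": "motif_feature_consequences",
            "Intergenic": "intergenic_consequences",
        }
        colocated: dict[str, dict] = {}
        for res in results:
            entry: dict = {
                "variant_allele": res.allele.allele,
                "consequence_terms": res.terms,
                "impact": res.impact(registry),
            }
            c = res.coords
            feat = res.feature
            if isinstance(feat, Transcript):
                entry.update({
                    "transcript_id": feat.accession, "gene_id": feat.gene_id,
                    "gene_symbol": feat.gene_symbol, "biotype": feat.biotype,
                    "strand": feat.strand,
                })
                for key, iv in (("cdna", c.cdna_interval),
                                ("cds", c.cds_interval),
                                ("protein", c.protein_interval)):
                    if iv:
                        entry[f"{key}_start"], entry[f"{key}_end"] = iv
                if res.ref_aa is not None:
                    entry["amino_acids"] = (
                        res.ref_aa if res.ref_aa == res.alt_aa
                        else f"{res.ref_aa}/{res.alt_aa}")
                if res.ref_codons is not None:
                    entry["codons"] = f"{res.ref_codons}/{res.alt_codons}"
            elif feat is not None:
                entry["feature_id"] = feat.id
            if c.distance is not None:
                entry["distance"] = c.distance
            for key, val in (("hgvsc", res.hgvs_c), ("hgvsp", res.hgvs_p),
                             ("hgvsg", res.hgvs_g)):
                if val:
                    entry[key] = val
            if res.motif_impact is not None:
                mi = res.motif_impact
                entry.update({
                    "motif_pos": mi.motif_position,
                    "motif_score_change": round(mi.delta, 4),
                    "high_inf_pos": mi.informative,
                })
            if res.extras:
                entry["extras"] = dict(res.extras)
            obj.setdefault(buckets[res.feature_type], []).append(entry)
            for co in res.colocated:
                rec = co.record
                colocated[rec.id] = {
                    "id": rec.id, "start": rec.start, "end": rec.end,
                    "allele_string": "/".join([rec.ref_allele, *rec.alt_alleles]),
                    "allele_match": co.allele_match,
                    **({"gmaf": rec.gmaf, "gmaf_allele": rec.gmaf_allele}
                       if rec.gmaf is not None else {}),
                    **({"frequencies": rec.pop_freqs} if rec.pop_freqs else {}),
                    **({"clin_sig": list(rec.clin_sig)} if rec.clin_sig else {}),
                    **({"somatic": True} if rec.somatic else {}),
                    **({"pubmed": list(rec.pubmed_ids)} if rec.pubmed_ids else {}),
                }
        if colocated:
            obj["colocated_variants"] = [colocated[k] for k in sorted(colocated)]
        sink.write(json.dumps(obj, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass
class SummaryStats:
    """Run-level tallies written alongside the primary output."""

    variants_processed: int = 0
    variants_filtered: int = 0  # QC failures + runtime-filtered variants
    results_written: int = 0
    per_term: dict[str, int] = field(default_factory=dict)
    per_biotype: dict[str, int] = field(default_factory=dict)
    per_chrom: dict[str, int] = field(default_factory=dict)

    def count_result(self, res: OverlapResult) -> None:
        self.results_written += 1
        for t in res.terms:
            self.per_term[t] = self.per_term.get(t, 0) + 1
        if isinstance(res.feature, Transcript):
            b = res.feature.biotype
            self.per_biotype[b] = self.per_biotype.get(b, 0) + 1
        chrom = res.variant.chrom
        self.per_chrom[chrom] = self.per_chrom.get(chrom, 0) + 1

    def to_dict(self) -> dict:
        return {
            "variants_processed": self.variants_processed,
            "variants_filtered": self.variants_filtered,
            "results_written": self.results_written,
            "consequences": dict(sorted(self.per_term.items())),
            "biotypes": dict(sorted(self.per_biotype.items())),
            "chromosomes": dict(sorted(self.per_chrom.items())),
        }

    def write(self, sink) -> None:
        json.dump(self.to_dict(), sink, indent=1, sort_keys=True)
        sink.write("\n")
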
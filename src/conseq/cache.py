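"""Build the on-disk annotation cache.

The cache is a directory of megabase-binned JSON-lines files plus a copied,
faidx-indexed genome FASTA and a ``manifest.json`` recording the schema
version, bin size, source checksums, and per-chromosome bin lists:

    <cache>/manifest.json
    <cache>/genome.fa[.fai]
    <cache>/<chrom>/<bin>.jsonl

Each bin file holds one JSON object per feature (transcripts, regulatory
features, motif placements, known variants).  A feature spanning a bin
boundary is written into every bin it overlaps and deduplicated by id at
query time.  The format is deliberately implementation-neutral so caches can
be inspected or produced by other tooling.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path

import gffutils
import pyfaidx

from .models import Interval, KnownVariant, MotifFeature, RegulatoryFeature, Transcript
from .motifs import parse_jaspar
from .variants import VcfReader, WarningsLog

__all__ = ["build_cache", "BIN_SIZE", "SCHEMA_VERSION", "CacheBuildError"]

log = logging.getLogger(__name__)

BIN_SIZE = 1_000_000
SCHEMA_VERSION = 1
DEFAULT_MITO_CHROMS = ("MT", "chrM", "M")

TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "miRNA", "lnc_RNA", "lincRNA", "ncRNA",
    "processed_transcript", "pseudogene", "snoRNA", "snRNA", "rRNA", "tRNA",
}
REGULATORY_TYPES = {
    "promoter", "enhancer", "open_chromatin_region", "CTCF_binding_site",
    "regulatory_region",
}
MOTIF_TYPE = "TF_binding_site"


class CacheBuildError(ValueError):
    """Raised when the annotation inputs are internally inconsistent."""


def _bins(start: int, end: int, bin_size: int) -> range:
    return range((start - 1) // bin_size, (end - 1) // bin_size + 1)


def _attr(feature, *names, default=None):
    for n in names:
        if n in feature.attributes:
            vals = feature.attributes[n]
            if vals:
                return vals[0]
    return default


def _attr_list(feature, *names) -> list[str]:
    val = _attr(feature, *names)
    if val is None:
        return []
    return [v for v in val.split(",") if v]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _open_gff_db(path: Path):
    try:
        return gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return None


def _load_transcripts(annotation: Path, chrom_lengths: dict[str, int],
                      canonical_attr: str) -> list[Transcript]:
    db = _open_gff_db(annotation)
    if db is None:
        return []
    genes: dict[str, dict] = {}
    for g in db.features_of_type("gene"):
        gid = _attr(g, "gene_id", "ID", default=g.id)
        genes[g.id] = {
            "id": gid,
            "symbol": _attr(g, "Name", "gene_name", "gene_symbol", default=gid),
        }

    transcripts: list[Transcript] = []
    for ft in db.all_features():
        if ft.featuretype not in TRANSCRIPT_TYPES:
            continue
        tid = _attr(ft, "transcript_id", "ID", default=ft.id)
        chrom = ft.seqid
        if chrom not in chrom_lengths:
            raise CacheBuildError(
                f"transcript {tid}: chromosome {chrom!r} absent from FASTA")
        strand = 1 if ft.strand != "-" else -1
        exon_ivs, cds_pieces = [], []
        for child in db.children(ft.id):
            if child.featuretype == "exon":
                exon_ivs.append((child.start, child.end))
            elif child.featuretype == "CDS":
                cds_pieces.append((child.start, child.end, child.frame))
        if not exon_ivs:
            exon_ivs = [(ft.start, ft.end)]
        exon_ivs.sort()
        length = chrom_lengths[chrom]
        for s, e in exon_ivs:
            if s < 1 or e > length:
                raise CacheBuildError(
                    f"transcript {tid}: exon {s}-{e} outside chromosome "
                    f"{chrom} (length {length})")
        if strand == -1:
            exon_ivs = exon_ivs[::-1]

        cds_start = cds_end = None
        if cds_pieces:
            cds_start = min(s for s, _, _ in cds_pieces)
            cds_end = max(e for _, e, _ in cds_pieces)
            _check_phases(tid, cds_pieces, strand)

        parent = _attr(ft, "Parent", "gene_id")
        gene = genes.get(parent, {"id": parent or "", "symbol": parent or ""})
        biotype = _attr(
            ft, "biotype", "transcript_biotype", "transcript_type",
            default=None,
        )
        if biotype is None:
            if ft.featuretype in ("miRNA", "lnc_RNA", "lincRNA", "ncRNA"):
                biotype = {"lnc_RNA": "lncRNA", "lincRNA": "lncRNA"}.get(
                    ft.featuretype, ft.featuretype)
            else:
                biotype = "protein_coding" if cds_pieces else "processed_transcript"

        flags: dict = {}
        tags = _attr_list(ft, canonical_attr, "tag")
        if any(t in ("canonical", "Ensembl_canonical") for t in tags):
            flags["canonical"] = True
        ccds = _attr(ft, "ccds_id", "ccdsid")
        if ccds:
            flags["ccds"] = ccds
        tsl = _attr(ft, "transcript_support_level", "tsl")
        if tsl:
            flags["tsl"] = tsl
        appris = _attr(ft, "appris")
        if appris:
            flags["appris"] = appris

        mature = None
        mature_attr = _attr(ft, "mature")
        if mature_attr:
            ms, me = mature_attr.split("-")
            mature = Interval(int(ms), int(me))

        version = int(_attr(ft, "version", default="1"))
        transcripts.append(Transcript(
            id=tid, chrom=chrom, strand=strand,
            exons=[Interval(s, e) for s, e in exon_ivs],
            gene_id=gene["id"], gene_symbol=gene["symbol"], version=version,
            cds_genomic_start=cds_start, cds_genomic_end=cds_end,
            biotype=biotype, flags=flags, mature_mirna=mature,
        ))
    return transcripts


def _check_phases(tid: str, cds_pieces: list[tuple[int, int, str]],
                  strand: int) -> None:
    """Validate declared CDS phases against cumulative coding length."""
    ordered = sorted(cds_pieces, key=lambda p: p[0], reverse=(strand == -1))
    done = 0
    for s, e, frame in ordered:
        expected = (3 - done % 3) % 3
        if frame not in (".", None, "") and int(frame) != expected:
            raise CacheBuildError(
                f"transcript {tid}: CDS piece {s}-{e} declares phase {frame}, "
                f"expected {expected}")
        done += e - s + 1


def _load_regulatory(path: Path, matrices: dict) -> tuple[
        list[RegulatoryFeature], list[MotifFeature]]:
    db = _open_gff_db(path)
    regulatory, motif_feats = [], []
    if db is None:
        return regulatory, motif_feats
    for ft in db.all_features():
        fid = _attr(ft, "ID", default=ft.id)
        if ft.featuretype == MOTIF_TYPE:
            name = _attr(ft, "motif_name", default=fid)
            if name not in matrices:
                raise CacheBuildError(
                    f"motif feature {fid}: no matrix {name!r} in PWM file")
            motif_feats.append(MotifFeature(
                id=fid, motif_name=name, chrom=ft.seqid,
                interval=Interval(ft.start, ft.end),
                strand=1 if ft.strand != "-" else -1,
                pwm=matrices[name],
            ))
        elif ft.featuretype in REGULATORY_TYPES:
            regulatory.append(RegulatoryFeature(
                id=fid, chrom=ft.seqid, interval=Interval(ft.start, ft.end),
                feature_type=ft.featuretype,
                cell_types=tuple(_attr_list(ft, "cell_types", "cell_type")),
            ))
    return regulatory, motif_feats


def _load_known(path: Path) -> list[KnownVariant]:
    known = []
    reader = VcfReader(path, warnings=WarningsLog())
    for v in reader:
        info = {}
        if v.raw_vcf_fields and len(v.raw_vcf_fields) >= 8:
            from .variants import _parse_info
            info = _parse_info(v.raw_vcf_fields[7])
        gmaf_allele, gmaf = "", None
        if "GMAF" in info:
            val = info["GMAF"]
            if ":" in val:
                gmaf_allele, freq = val.split(":", 1)
            else:
                freq = val
            gmaf = float(freq)
        pop_freqs = {
            k[3:]: float(val) for k, val in info.items() if k.startswith("AF_")
        }
        known.append(KnownVariant(
            id=v.id or f"var_{v.chrom}_{v.start}",
            chrom=v.chrom, start=v.start, end=v.end,
            ref_allele=v.ref_allele, alt_alleles=tuple(v.alt_alleles),
            gmaf_allele=gmaf_allele, gmaf=gmaf, pop_freqs=pop_freqs,
            clin_sig=tuple(info.get("CLNSIG", "").split(",")) if info.get("CLNSIG") else (),
            somatic="SOMATIC" in info,
            pubmed_ids=tuple(info.get("PMID", "").split(",")) if info.get("PMID") else (),
        ))
    return known


# -- serialisation ----------------------------------------------------------


def _feature_record(obj) -> dict:
    if isinstance(obj, Transcript):
        return {
            "class": "transcript", "id": obj.id, "version": obj.version,
            "gene_id": obj.gene_id, "gene_symbol": obj.gene_symbol,
            "chrom": obj.chrom, "strand": obj.strand,
            "exons": [[e.start, e.end] for e in obj.exons],
            "cds": ([obj.cds_genomic_start, obj.cds_genomic_end]
                    if obj.is_coding else None),
            "biotype": obj.biotype, "flags": obj.flags,
            "mature": ([obj.mature_mirna.start, obj.mature_mirna.end]
                       if obj.mature_mirna else None),
            "sec": list(obj.selenocysteine_positions),
        }
    if isinstance(obj, RegulatoryFeature):
        return {
            "class": "regulatory", "id": obj.id, "chrom": obj.chrom,
            "start": obj.start, "end": obj.end,
            "feature_type": obj.feature_type,
            "cell_types": list(obj.cell_types),
        }
    if isinstance(obj, MotifFeature):
        return {
            "class": "motif", "id": obj.id, "motif_name": obj.motif_name,
            "chrom": obj.chrom, "start": obj.start, "end": obj.end,
            "strand": obj.strand, "pwm": obj.pwm,
        }
    if isinstance(obj, KnownVariant):
        return {
            "class": "known", "id": obj.id, "chrom": obj.chrom,
            "start": obj.start, "end": obj.end, "ref": obj.ref_allele,
            "alts": list(obj.alt_alleles), "gmaf_allele": obj.gmaf_allele,
            "gmaf": obj.gmaf, "pop_freqs": obj.pop_freqs,
            "clin_sig": list(obj.clin_sig), "somatic": obj.somatic,
            "pubmed": list(obj.pubmed_ids),
        }
    raise TypeError(f"unserialisable feature {type(obj)!r}")


def build_cache(annotation, genome_fasta, out, *, regulatory=None, motifs=None,
                known_variants=None, selenocysteine=None,
                bin_size: int = BIN_SIZE, canonical_attr: str = "tag",
                species: str = "custom",
                mito_chroms=DEFAULT_MITO_CHROMS) -> dict:
    """Build a cache directory from a GFF3/GTF + FASTA pair.

    Optional inputs: a regulatory GFF (promoter/enhancer/TF_binding_site
    records), a JASPAR-style PWM file for the motif records, a known-variant
    VCF (reserved INFO keys GMAF, AF_*, CLNSIG, SOMATIC, PMID), and a
    selenocysteine sidecar TSV (transcript_id <TAB> protein_position) since
    GTF dialects have no standard Sec annotation.  Returns the manifest.
    """
    annotation = Path(annotation)
    genome_fasta = Path(genome_fasta)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    fasta_copy = out / "genome.fa"
    shutil.copyfile(genome_fasta, fasta_copy)
    fa = pyfaidx.Fasta(str(fasta_copy))
    chrom_lengths = {name: len(fa[name]) for name in fa.keys()}

    transcripts = _load_transcripts(annotation, chrom_lengths, canonical_attr)
    if not transcripts:
        log.warning("annotation %s yielded no transcripts", annotation)

    if selenocysteine:
        sec: dict[str, list[int]] = {}
        with open(selenocysteine) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tid, pos = line.split("\t")
                sec.setdefault(tid, []).append(int(pos))
        for t in transcripts:
            if t.id in sec:
                t.selenocysteine_positions = tuple(sorted(sec[t.id]))

    regulatory_feats: list[RegulatoryFeature] = []
    motif_feats: list[MotifFeature] = []
    if regulatory:
        matrices = parse_jaspar(motifs) if motifs else {}
        regulatory_feats, motif_feats = _load_regulatory(Path(regulatory), matrices)
    known = _load_known(Path(known_variants)) if known_variants else []

    bins: dict[tuple[str, int], list[dict]] = {}
    for feat in [*transcripts, *regulatory_feats, *motif_feats, *known]:
        rec = _feature_record(feat)
        start = feat.start
        end = feat.end
        for b in _bins(start, end, bin_size):
            bins.setdefault((feat.chrom, b), []).append(rec)

    for (chrom, b), records in sorted(bins.items()):
        d = out / chrom
        d.mkdir(exist_ok=True)
        with open(d / f"{b}.jsonl", "w") as fh:
            for rec in records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    chroms = {
        name: {
            "length": chrom_lengths[name],
            "bins": sorted(b for (c, b) in bins if c == name),
        }
        for name in chrom_lengths
    }
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "species": species,
        "bin_size": bin_size,
        "fasta": "genome.fa",
        "chroms": chroms,
        "mito_chroms": list(mito_chroms),
        "counts": {
            "transcripts": len(transcripts),
            "regulatory": len(regulatory_feats),
            "motifs": len(motif_feats),
            "known_variants": len(known),
        },
        "checksums": {
            "annotation": _sha256(annotation),
            "fasta": _sha256(genome_fasta),
        },
        "build": {
            "annotation": str(annotation),
            "canonical_attr": canonical_attr,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
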
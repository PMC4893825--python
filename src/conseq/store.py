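"""Serve the region-binned annotation cache.

:class:`AnnotationStore` loads megabase bins lazily and memoizes them, so
consecutive input buffers touching the same region never reread the disk.
It also owns random-access genome sequence (via pyfaidx), memoized spliced
cDNA/CDS sequences per transcript, and codon-table-aware translation
(standard, vertebrate mitochondrial, and annotated selenocysteines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pyfaidx
from Bio.Data import CodonTable
from intervaltree import IntervalTree

from .models import Interval, KnownVariant, MotifFeature, RegulatoryFeature, Transcript
from .variants import Variant, norm_chrom

__all__ = ["AnnotationStore", "Genome", "OverlapFeatures", "translate_cds",
           "STANDARD_TABLE", "VERTEBRATE_MITO_TABLE"]

STANDARD_TABLE = 1
VERTEBRATE_MITO_TABLE = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_MAPS = {t: _codon_map(t) for t in (STANDARD_TABLE, VERTEBRATE_MITO_TABLE)}


def translate_cds(cds: str, table: int = STANDARD_TABLE,
                  selenocysteine: tuple[int, ...] = ()) -> str:
    """Translate a CDS; trailing incomplete codons are dropped.

    ``selenocysteine`` lists protein positions whose TGA codon encodes U
    rather than a stop.  Codons containing N translate to X.  Characters
    outside ACGTN raise ``ValueError``.
    """
    cds = cds.upper()
    bad = set(cds) - set("ACGTN")
    if bad:
        raise ValueError(f"CDS contains non-ACGTN characters: {sorted(bad)}")
    mapping = _CODON_MAPS[table]
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        pos = i // 3 + 1
        if codon == "TGA" and pos in selenocysteine:
            protein.append("U")
        elif "N" in codon:
            protein.append("X")
        else:
            protein.append(mapping[codon])
    return "".join(protein)


def has_incomplete_terminal_codon(cds: str) -> bool:
    return len(cds) % 3 != 0


class Genome:
    """Random-access genome sequence with chromosome-name tolerance."""

    def __init__(self, fasta_path):
        self._fa = pyfaidx.Fasta(str(fasta_path))
        self._names = {norm_chrom(n): n for n in self._fa.keys()}

    def resolve(self, chrom: str) -> str:
        if chrom in self._fa:
            return chrom
        key = norm_chrom(chrom)
        if key in self._names:
            return self._names[key]
        raise KeyError(f"chromosome {chrom!r} not in genome")

    def __contains__(self, chrom: str) -> bool:
        try:
            self.resolve(chrom)
            return True
        except KeyError:
            return False

    def length(self, chrom: str) -> int:
        return len(self._fa[self.resolve(chrom)])

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, uppercase."""
        name = self.resolve(chrom)
        if start < 1 or end > len(self._fa[name]) or start > end:
            raise ValueError(
                f"sequence request {chrom}:{start}-{end} outside chromosome")
        return str(self._fa[name][start - 1:end]).upper()


@dataclass
class OverlapFeatures:
    """Features returned by an overlap query, grouped by class."""

    transcripts: list[Transcript] = field(default_factory=list)
    regulatory: list[RegulatoryFeature] = field(default_factory=list)
    motifs: list[MotifFeature] = field(default_factory=list)

    @property
    def all(self) -> list:
        return [*self.transcripts, *self.regulatory, *self.motifs]

    def __len__(self) -> int:
        return len(self.all)


class _Bin:
    __slots__ = ("tree", "features")

    def __init__(self):
        self.tree = IntervalTree()
        self.features = []


def _materialise(rec: dict):
    cls = rec["class"]
    if cls == "transcript":
        return Transcript(
            id=rec["id"], chrom=rec["chrom"], strand=rec["strand"],
            exons=[Interval(s, e) for s, e in rec["exons"]],
            gene_id=rec["gene_id"], gene_symbol=rec["gene_symbol"],
            version=rec["version"],
            cds_genomic_start=rec["cds"][0] if rec["cds"] else None,
            cds_genomic_end=rec["cds"][1] if rec["cds"] else None,
            biotype=rec["biotype"], flags=rec["flags"],
            mature_mirna=Interval(*rec["mature"]) if rec["mature"] else None,
            selenocysteine_positions=tuple(rec["sec"]),
        )
    if cls == "regulatory":
        return RegulatoryFeature(
            id=rec["id"], chrom=rec["chrom"],
            interval=Interval(rec["start"], rec["end"]),
            feature_type=rec["feature_type"],
            cell_types=tuple(rec["cell_types"]),
        )
    if cls == "motif":
        return MotifFeature(
            id=rec["id"], motif_name=rec["motif_name"], chrom=rec["chrom"],
            interval=Interval(rec["start"], rec["end"]), strand=rec["strand"],
            pwm=rec["pwm"],
        )
    if cls == "known":
        return KnownVariant(
            id=rec["id"], chrom=rec["chrom"], start=rec["start"],
            end=rec["end"], ref_allele=rec["ref"],
            alt_alleles=tuple(rec["alts"]), gmaf_allele=rec["gmaf_allele"],
            gmaf=rec["gmaf"], pop_freqs=rec["pop_freqs"],
            clin_sig=tuple(rec["clin_sig"]), somatic=rec["somatic"],
            pubmed_ids=tuple(rec["pubmed"]),
        )
    raise ValueError(f"unknown feature class {cls!r}")


class AnnotationStore:
    """Read-side interface over a built cache directory."""

    def __init__(self, cache_dir, memoize: bool = True):
        self.cache_dir = Path(cache_dir)
        manifest_path = self.cache_dir / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(
                f"no cache manifest at {manifest_path}; run build-cache first")
        with open(manifest_path) as fh:
            self.manifest = json.load(fh)
        self.bin_size: int = self.manifest["bin_size"]
        self.genome = Genome(self.cache_dir / self.manifest["fasta"])
        self._chroms = {norm_chrom(c): c for c in self.manifest["chroms"]}
        self._mito = {norm_chrom(c) for c in self.manifest["mito_chroms"]}
        self.memoize = memoize
        self._bins: dict[tuple[str, int], _Bin] = {}
        self.bins_loaded = 0
        self.warnings: list[str] = []
        self._warned_chroms: set[str] = set()
        self._seq_cache: dict[tuple[str, str], str] = {}
        self._transcript_index: dict[str, Transcript] | None = None
        self._known_index: dict[str, KnownVariant] | None = None

    # -- bins --------------------------------------------------------------

    def resolve_chrom(self, chrom: str) -> str | None:
        if chrom in self.manifest["chroms"]:
            return chrom
        return self._chroms.get(norm_chrom(chrom))

    def is_mito(self, chrom: str) -> bool:
        return norm_chrom(chrom) in self._mito

    def codon_table_for(self, chrom: str) -> int:
        return VERTEBRATE_MITO_TABLE if self.is_mito(chrom) else STANDARD_TABLE

    def _load_bin(self, chrom: str, index: int) -> _Bin:
        key = (chrom, index)
        if self.memoize and key in self._bins:
            return self._bins[key]
        bin_ = _Bin()
        path = self.cache_dir / chrom / f"{index}.jsonl"
        if path.exists():
            with open(path) as fh:
                for line in fh:
                    feat = _materialise(json.loads(line))
                    bin_.features.append(feat)
                    bin_.tree.addi(feat.start, feat.end + 1, feat)
            self.bins_loaded += 1
        if self.memoize:
            self._bins[key] = bin_
        return bin_

    def _query_bins(self, chrom: str, start: int, end: int):
        """Features whose intervals intersect [start, end], deduplicated."""
        cached = self.resolve_chrom(chrom)
        if cached is None:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                self.warnings.append(
                    f"chromosome {chrom!r} absent from cache; "
                    "variants there are annotated as intergenic")
            return []
        lo = max(1, start)
        seen: set[tuple[str, str]] = set()
        out = []
        for b in range((lo - 1) // self.bin_size, (max(end, lo) - 1) // self.bin_size + 1):
            bin_ = self._load_bin(cached, b)
            for iv in bin_.tree.overlap(lo, end + 1):
                feat = iv.data
                key = (feat.__class__.__name__, feat.id)
                if key in seen:
                    continue
                seen.add(key)
                out.append(feat)
        out.sort(key=lambda f: (f.start, f.end, f.id))
        return out

    # -- queries -----------------------------------------------------------

    def query_overlaps(self, variant: Variant, flank: int = 5000) -> OverlapFeatures:
        """Every transcript within ``flank`` of the variant plus every
        regulatory/motif feature it directly overlaps.

        Insertions (start = end + 1) overlap only features containing the
        insertion point, i.e. both flanking bases.
        """
        s, e = variant.span()
        result = OverlapFeatures()
        for feat in self._query_bins(variant.chrom, s - flank, e + flank):
            if isinstance(feat, Transcript):
                if feat.start - flank <= e and feat.end + flank >= s:
                    result.transcripts.append(feat)
            elif isinstance(feat, (RegulatoryFeature, MotifFeature)):
                if variant.is_insertion_site:
                    if feat.start <= s and e <= feat.end:
                        getattr(result, "regulatory" if isinstance(
                            feat, RegulatoryFeature) else "motifs").append(feat)
                elif feat.overlaps(s, e):
                    getattr(result, "regulatory" if isinstance(
                        feat, RegulatoryFeature) else "motifs").append(feat)
        return result

    def query_known(self, variant: Variant) -> list[KnownVariant]:
        s, e = variant.span()
        return [f for f in self._query_bins(variant.chrom, s, e)
                if isinstance(f, KnownVariant) and f.overlaps(s, e)]

    def _scan_all(self):
        for chrom, meta in self.manifest["chroms"].items():
            for b in meta["bins"]:
                yield from self._load_bin(chrom, b).features

    def transcript_by_id(self, tid: str) -> Transcript | None:
        """Lookup by stable id, tolerating a trailing ``.version``."""
        if self._transcript_index is None:
            self._transcript_index = {}
            for feat in self._scan_all():
                if isinstance(feat, Transcript):
                    self._transcript_index.setdefault(feat.id, feat)
                    self._transcript_index.setdefault(feat.accession, feat)
        if tid in self._transcript_index:
            return self._transcript_index[tid]
        base = tid.rsplit(".", 1)[0]
        return self._transcript_index.get(base)

    def known_by_id(self, vid: str) -> KnownVariant | None:
        if self._known_index is None:
            self._known_index = {}
            for feat in self._scan_all():
                if isinstance(feat, KnownVariant):
                    self._known_index.setdefault(feat.id, feat)
        return self._known_index.get(vid)

    # -- sequences ---------------------------------------------------------

    def spliced_sequence(self, transcript: Transcript) -> str:
        """cDNA: exons concatenated 5'→3', reverse-complemented on minus."""
        key = ("cdna", transcript.accession)
        if key not in self._seq_cache:
            parts = []
            for exon in transcript.exons:
                seq = self.genome.sequence(transcript.chrom, exon.start, exon.end)
                parts.append(seq if transcript.strand == 1 else reverse_complement(seq))
            self._seq_cache[key] = "".join(parts)
        return self._seq_cache[key]

    def cds_sequence(self, transcript: Transcript) -> str:
        key = ("cds", transcript.accession)
        if key not in self._seq_cache:
            if not transcript.is_coding:
                raise ValueError(f"{transcript.id} is non-coding")
            cdna = self.spliced_sequence(transcript)
            self._seq_cache[key] = cdna[
                transcript.cdna_coding_start - 1:transcript.cdna_coding_end]
        return self._seq_cache[key]

    def translate(self, transcript: Transcript) -> str:
        key = ("protein", transcript.accession)
        if key not in self._seq_cache:
            self._seq_cache[key] = translate_cds(
                self.cds_sequence(transcript),
                table=self.codon_table_for(transcript.chrom),
                selenocysteine=transcript.selenocysteine_positions,
            )
        return self._seq_cache[key]
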
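"""Co-located known variants and user-supplied custom annotation tracks.

Known variants live in the annotation cache as a third feature class,
ingested from a VCF whose reserved INFO keys carry frequency and clinical
attributes:

    GMAF=T:0.02      global minor allele and frequency
    AF_AFR=0.2       per-population frequencies (any AF_<POP> key)
    CLNSIG=...       comma-separated clinical significance terms
    SOMATIC          flag
    PMID=1234,5678   PubMed ids

Custom tracks are BED / GFF / VCF files declared as ``name=path=format`` (an
optional ``,exact`` suffix on VCF tracks requires allele identity, not just
positional overlap).  Overlapping record names accumulate in the result's
``extras`` under the track name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .models import KnownVariant
from .variants import Variant, VcfReader, WarningsLog, minimise_alleles, norm_chrom

__all__ = ["Colocated", "find_colocated", "filter_common", "CustomTrack",
           "custom_overlap", "parse_track_spec", "COMMON_FREQ_DEFAULT"]

log = logging.getLogger(__name__)

COMMON_FREQ_DEFAULT = 0.01


@dataclass(frozen=True)
class Colocated:
    """A known variant at the same position as an input variant."""

    record: KnownVariant
    allele_match: bool  # False: position-only match (mismatch flag)


def _minimal(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    return minimise_alleles(start, ref, alt)


def find_colocated(variant: Variant, store) -> list[Colocated]:
    """Known variants at the identical chrom/start/end.

    Allele compatibility requires a shared reference allele and at least one
    shared alternative allele after minimisation; position-only matches are
    returned flagged as mismatches.
    """
    out = []
    for k in store.query_known(variant):
        if (norm_chrom(k.chrom) != norm_chrom(variant.chrom)
                or k.start != variant.start or k.end != variant.end):
            continue
        v_min = {_minimal(variant.start, variant.ref_allele, a)
                 for a in variant.alt_alleles}
        k_min = {_minimal(k.start, k.ref_allele, a) for a in k.alt_alleles}
        match = (k.ref_allele == variant.ref_allele
                 and bool(v_min & k_min))
        out.append(Colocated(record=k, allele_match=match))
    return out


def filter_common(results: list, threshold: float = COMMON_FREQ_DEFAULT) -> list:
    """Drop all results of variants co-located with a common known variant.

    "Common" means any co-located record with global minor allele frequency
    strictly greater than ``threshold`` (default 1 %).
    """
    def is_common(res) -> bool:
        return any(c.record.gmaf is not None and c.record.gmaf > threshold
                   for c in res.colocated)

    common_variants = {res.variant.key() for res in results if is_common(res)}
    return [res for res in results if res.variant.key() not in common_variants]


# ---------------------------------------------------------------------------
# Custom tracks


@dataclass
class _TrackRecord:
    start: int
    end: int
    name: str
    ref: str = ""
    alts: tuple[str, ...] = ()


@dataclass
class CustomTrack:
    """One user-declared annotation track, loaded lazily into memory."""

    name: str
    path: str
    format: str  # bed / gff / vcf
    exact: bool = False
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _loaded: bool = field(default=False, repr=False)

    def _load(self) -> None:
        if self._loaded:
            return
        self._loaded = True
        fmt = self.format.lower()
        if fmt == "bed":
            self._load_bed()
        elif fmt in ("gff", "gff3", "gtf"):
            self._load_gff()
        elif fmt == "vcf":
            self._load_vcf()
        else:
            raise ValueError(f"track {self.name}: unsupported format {self.format!r}")

    def _add(self, chrom: str, rec: _TrackRecord) -> None:
        self._trees.setdefault(norm_chrom(chrom), IntervalTree()).addi(
            rec.start, rec.end + 1, rec)

    def _load_bed(self) -> None:
        with open(self.path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                try:
                    chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                except (IndexError, ValueError):
                    log.warning("track %s line %d unparseable; skipped",
                                self.name, ln)
                    continue
                name = fields[3] if len(fields) > 3 else f"{chrom}:{start0}-{end0}"
                self._add(chrom, _TrackRecord(start0 + 1, end0, name))

    def _load_gff(self) -> None:
        with open(self.path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    log.warning("track %s line %d unparseable; skipped",
                                self.name, ln)
                    continue
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    log.warning("track %s line %d unparseable; skipped",
                                self.name, ln)
                    continue
                name = None
                if len(fields) > 8:
                    for item in fields[8].replace("; ", ";").split(";"):
                        if "=" in item:
                            k, v = item.split("=", 1)
                        elif " " in item.strip():
                            k, v = item.strip().split(" ", 1)
                            v = v.strip('"')
                        else:
                            continue
                        if k.strip() in ("ID", "Name", "gene_id"):
                            name = v
                            break
                name = name or f"{fields[0]}:{start}-{end}"
                self._add(fields[0], _TrackRecord(start, end, name))

    def _load_vcf(self) -> None:
        warnings = WarningsLog()
        for v in VcfReader(self.path, warnings=warnings):
            rec = _TrackRecord(v.start, max(v.end, v.start), v.id or v.location,
                               ref=v.ref_allele, alts=tuple(v.alt_alleles))
            self._add(v.chrom, rec)
        for ln, code, msg in warnings.records:
            log.warning("track %s line %d: %s; skipped", self.name, ln, msg)

    def hits(self, variant: Variant) -> list[str]:
        self._load()
        tree = self._trees.get(norm_chrom(variant.chrom))
        if tree is None:
            return []
        s, e = variant.span()
        out = []
        for iv in sorted(tree.overlap(s, e + 1)):
            rec = iv.data
            if self.exact:
                if not (rec.start == variant.start and rec.end == variant.end
                        and rec.ref == variant.ref_allele
                        and set(rec.alts) & set(variant.alt_alleles)):
                    continue
            out.append(rec.name)
        return out


def parse_track_spec(spec: str) -> CustomTrack:
    """Parse a ``name=path=format[,exact]`` track declaration."""
    parts = spec.split("=")
    if len(parts) != 3:
        raise ValueError(f"track spec {spec!r} is not name=path=format[,exact]")
    name, path, fmt = parts
    exact = False
    if fmt.endswith(",exact"):
        fmt, exact = fmt[:-6], True
    return CustomTrack(name=name, path=path, format=fmt, exact=exact)


def custom_overlap(variant: Variant, tracks: list[CustomTrack]) -> dict[str, str]:
    """extras entries for every track record overlapping the variant."""
    extras = {}
    for track in tracks:
        names = track.hits(variant)
        if names:
            extras[track.name] = ",".join(names)
    return extras
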
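"""Core annotation feature models.

All genomic coordinates are 1-based fully-closed.  A transcript's exons are
stored in *transcript* order (5'→3' along the transcript), so for a minus
strand transcript the first exon has the highest genomic coordinates.
cDNA/CDS/protein positions are 1-based positions in the spliced transcript,
coding sequence, and peptide respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Interval",
    "Transcript",
    "RegulatoryFeature",
    "MotifFeature",
    "KnownVariant",
    "RunStatistics",
]


@dataclass(frozen=True)
class Interval:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class Transcript:
    """A transcript model: exon structure, optional CDS, strand, biotype.

    ``exons`` are genomic intervals in transcript order.  ``cds_genomic_start``
    / ``cds_genomic_end`` are genomic bounds of translation (start < end
    regardless of strand), absent for non-coding biotypes.
    """

    id: str
    chrom: str
    strand: int  # +1 / -1
    exons: list[Interval]
    gene_id: str = ""
    gene_symbol: str = ""
    version: int = 1
    cds_genomic_start: Optional[int] = None
    cds_genomic_end: Optional[int] = None
    biotype: str = "protein_coding"
    flags: dict = field(default_factory=dict)  # canonical, ccds, tsl, appris
    mature_mirna: Optional[Interval] = None
    selenocysteine_positions: tuple[int, ...] = ()  # protein positions

    def __post_init__(self):
        if self.strand not in (1, -1):
            raise ValueError(f"{self.id}: strand must be +1/-1")
        if not self.exons:
            raise ValueError(f"{self.id}: transcript needs at least one exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.id}: exons overlap")
        expected = genomic if self.strand == 1 else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError(f"{self.id}: exons not in transcript order")
        if (self.cds_genomic_start is None) != (self.cds_genomic_end is None):
            raise ValueError(f"{self.id}: partial CDS bounds")
        if self.is_coding:
            if not (self.start <= self.cds_genomic_start
                    <= self.cds_genomic_end <= self.end):
                raise ValueError(f"{self.id}: CDS outside transcript span")

    # -- basic geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_genomic_start is not None

    @property
    def accession(self) -> str:
        return f"{self.id}.{self.version}"

    @property
    def introns(self) -> list[Interval]:
        """Introns in transcript order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == 1:
                out.append(Interval(a.end + 1, b.start - 1))
            else:
                out.append(Interval(b.end + 1, a.start - 1))
        return out

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start

    # -- coordinate projection --------------------------------------------

    def cdna_position(self, gpos: int) -> Optional[int]:
        """Spliced cDNA position of genomic position, None if intronic/outside."""
        offset = 0
        for exon in self.exons:
            if exon.start <= gpos <= exon.end:
                if self.strand == 1:
                    return offset + (gpos - exon.start) + 1
                return offset + (exon.end - gpos) + 1
            offset += len(exon)
        return None

    def genomic_position(self, cdna_pos: int) -> int:
        """Inverse of :meth:`cdna_position`."""
        if cdna_pos < 1 or cdna_pos > self.length:
            raise ValueError(f"{self.id}: cDNA position {cdna_pos} out of range")
        offset = 0
        for exon in self.exons:
            if cdna_pos <= offset + len(exon):
                within = cdna_pos - offset - 1
                if self.strand == 1:
                    return exon.start + within
                return exon.end - within
            offset += len(exon)
        raise AssertionError("unreachable")

    @property
    def cdna_coding_start(self) -> Optional[int]:
        """cDNA position of the first coding base (transcript orientation)."""
        if not self.is_coding:
            return None
        g = self.cds_genomic_start if self.strand == 1 else self.cds_genomic_end
        return self.cdna_position(g)

    @property
    def cdna_coding_end(self) -> Optional[int]:
        if not self.is_coding:
            return None
        g = self.cds_genomic_end if self.strand == 1 else self.cds_genomic_start
        return self.cdna_position(g)

    def cds_position(self, gpos: int) -> Optional[int]:
        """1-based CDS position of a genomic position, None outside the CDS."""
        if not self.is_coding:
            return None
        c = self.cdna_position(gpos)
        if c is None:
            return None
        if c < self.cdna_coding_start or c > self.cdna_coding_end:
            return None
        return c - self.cdna_coding_start + 1

    def cds_length(self) -> int:
        if not self.is_coding:
            return 0
        return self.cdna_coding_end - self.cdna_coding_start + 1

    def exon_number(self, start: int, end: int) -> Optional[str]:
        """"i/n"-style index of exon(s) overlapped by a genomic span."""
        hits = [i + 1 for i, e in enumerate(self.exons) if e.overlaps(start, end)]
        if not hits:
            return None
        n = len(self.exons)
        if len(hits) == 1:
            return f"{hits[0]}/{n}"
        return f"{min(hits)}-{max(hits)}/{n}"

    def intron_number(self, start: int, end: int) -> Optional[str]:
        introns = self.introns
        hits = [i + 1 for i, iv in enumerate(introns) if iv.overlaps(start, end)]
        if not hits:
            return None
        n = len(introns)
        if len(hits) == 1:
            return f"{hits[0]}/{n}"
        return f"{min(hits)}-{max(hits)}/{n}"


@dataclass
class RegulatoryFeature:
    id: str
    chrom: str
    interval: Interval
    feature_type: str = "regulatory_region"  # promoter, enhancer, ...
    cell_types: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.interval.overlaps(start, end)


@dataclass
class MotifFeature:
    """A transcription-factor binding motif placement with its PWM.

    ``pwm`` is a list of per-position probability columns, each a dict over
    A/C/G/T summing to 1 after pseudocounting; column i corresponds to motif
    position i+1 in motif (strand) orientation.
    """

    id: str
    motif_name: str
    chrom: str
    interval: Interval
    strand: int
    pwm: list[dict[str, float]]

    def __post_init__(self):
        if len(self.interval) != len(self.pwm):
            raise ValueError(
                f"{self.id}: interval length {len(self.interval)} != "
                f"PWM width {len(self.pwm)}"
            )

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.interval.overlaps(start, end)


@dataclass
class KnownVariant:
    """A catalogued variant with frequency/clinical annotation (internal coords)."""

    id: str
    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    gmaf_allele: str = ""
    gmaf: Optional[float] = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    clin_sig: tuple[str, ...] = ()
    somatic: bool = False
    pubmed_ids: tuple[str, ...] = ()

    def __post_init__(self):
        for f in [self.gmaf, *self.pop_freqs.values()]:
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"{self.id}: frequency {f} outside [0,1]")

    def overlaps(self, start: int, end: int) -> bool:
        return start <= self.end and end >= self.start


@dataclass
class RunStatistics:
    """Counters for one annotation run.

    ``n`` input variant alleles, ``f`` overlapped features, ``p`` registered
    predicates; predicate evaluation counters track the work the pre-predicate
    gates save (evaluated + skipped can never exceed n*f*p).
    """

    n: int = 0
    f: int = 0
    p: int = 0
    predicate_evaluations: int = 0
    predicate_evaluations_skipped: int = 0

    def check(self) -> None:
        total = self.predicate_evaluations + self.predicate_evaluations_skipped
        if total > self.n * self.f * self.p:
            raise AssertionError("predicate counters exceed n*f*p bound")
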
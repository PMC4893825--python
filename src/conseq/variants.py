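"""Input variants: parsing, normalisation, and quality control.

Internal representation
-----------------------
Coordinates are 1-based fully-closed.  Anchor bases required by VCF around
unbalanced substitutions are stripped at parse time, so a 1-bp deletion
``TA>T`` at POS 100 becomes ``start=101, end=101, ref=A, alt=-`` and an
insertion ``T>TG`` becomes ``start=101, end=100, ref=-, alt=G`` (insertions
use the ``start = end + 1`` convention).  ``-`` denotes the empty allele.

Indels are deliberately *not* left-aligned: input coordinates are preserved
so that output coordinates match the input file, and transcript-relative
HGVS descriptions are right-normalised separately.  Use an external
normaliser (e.g. ``bcftools norm``) beforehand if left alignment is wanted.

Variants whose affected span or inserted length exceeds 50 bp, or that carry
SVTYPE/END keys or symbolic alleles, are treated as structural.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Variant",
    "VariantAllele",
    "QCReport",
    "WarningsLog",
    "VcfReader",
    "read_vcf",
    "minimise_alleles",
    "qc_check",
    "norm_chrom",
    "SV_LENGTH_THRESHOLD",
]

SV_LENGTH_THRESHOLD = 50
_ALLELE_RE = re.compile(r"^([ACGTN]+|-)$")
_SYMBOLIC_RE = re.compile(r"^<([^<>]+)>$")
_SV_TYPES = {"DEL", "DUP", "INS", "CNV"}


def norm_chrom(name: str) -> str:
    """Chromosome name normalised for cross-source matching (drops "chr")."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class Variant:
    """A genomic location with reference and alternative alleles."""

    chrom: str
    start: int
    end: int
    ref_allele: str
    alt_alleles: list[str]
    id: Optional[str] = None
    input_index: int = -1
    is_structural: bool = False
    sv_type: Optional[str] = None  # DEL / DUP / INS / CNV
    raw_vcf_fields: Optional[list[str]] = None  # original columns, for echo
    input_line: Optional[int] = None

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]

    @property
    def location(self) -> str:
        if self.start == self.end:
            return f"{self.chrom}:{self.start}"
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def is_insertion_site(self) -> bool:
        return self.start == self.end + 1

    def span(self) -> tuple[int, int]:
        """Genomic span used for overlap queries (insertion: flanking pair)."""
        if self.is_insertion_site:
            return self.end, self.start
        return self.start, self.end

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.ref_allele,
                tuple(self.alt_alleles))


@dataclass(frozen=True)
class VariantAllele:
    """One alternative allele of a variant: the unit of annotation."""

    variant: Variant
    allele: str
    allele_index: int  # 0-based index into variant.alt_alleles

    @property
    def ref(self) -> str:
        return self.variant.ref_allele

    @property
    def ref_len(self) -> int:
        return 0 if self.ref == "-" else len(self.ref)

    @property
    def alt_len(self) -> int:
        return 0 if self.allele == "-" else len(self.allele)

    @property
    def is_snv(self) -> bool:
        return self.ref_len == 1 and self.alt_len == 1

    @property
    def length_change(self) -> int:
        return self.alt_len - self.ref_len


def alleles(variant: Variant) -> list[VariantAllele]:
    return [VariantAllele(variant, a, i)
            for i, a in enumerate(variant.alt_alleles)]


@dataclass
class QCReport:
    """Coded QC failures for one variant; empty means it may be annotated."""

    variant: Variant
    failures: list[tuple[str, str]] = field(default_factory=list)

    REF_MISMATCH = "REF_MISMATCH"
    LENGTH_MISMATCH = "LENGTH_MISMATCH"
    BAD_ALLELE_CHARS = "BAD_ALLELE_CHARS"
    COORD_ORDER = "COORD_ORDER"

    @property
    def codes(self) -> set[str]:
        return {c for c, _ in self.failures}

    @property
    def ok(self) -> bool:
        return not self.failures

    def add(self, code: str, message: str) -> None:
        self.failures.append((code, message))


class WarningsLog:
    """Collects (line number, code, message) records; optional file sink."""

    def __init__(self, path=None):
        self.path = path
        self.records: list[tuple[int, str, str]] = []

    def warn(self, line_no: int, code: str, message: str) -> None:
        self.records.append((line_no, code, message))

    def write(self) -> None:
        if self.path is None:
            return
        with open(self.path, "w") as fh:
            for line_no, code, msg in self.records:
                fh.write(f"{line_no}\t{code}\t{msg}\n")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# VCF reading


def _open_text(source):
    if hasattr(source, "read"):
        return source, False
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb")), True
    return open(path), True


def _parse_info(text: str) -> dict[str, str]:
    info: dict[str, str] = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            info[k] = v
        else:
            info[item] = ""
    return info


def _strip_anchor(pos: int, ref: str, alts: list[str]):
    """Strip the shared leading VCF anchor base, if present, into the
    internal representation.  Returns (start, end, ref, alts)."""
    shared = (
        len(ref) >= 1
        and all(a and a[0] == ref[0] for a in alts)
        and (len(ref) > 1 or any(len(a) > 1 for a in alts))
    )
    if shared:
        ref2 = ref[1:] or "-"
        alts2 = [a[1:] or "-" for a in alts]
        start = pos + 1
        end = pos + (len(ref) - 1) if ref2 != "-" else pos
        return start, end, ref2, alts2
    return pos, pos + len(ref) - 1, ref, list(alts)


class VcfReader:
    """Iterate Variant records from a VCF 4.x stream or path.

    Malformed data lines are skipped and logged to ``warnings``; a #CHROM
    header missing required columns is a fatal ``ValueError``.  Multi-allelic
    records keep all alternative alleles on one Variant.
    """

    REQUIRED = ["#CHROM", "POS", "ID", "REF", "ALT"]

    def __init__(self, source, warnings: Optional[WarningsLog] = None):
        self._fh, self._owned = _open_text(source)
        self.warnings = warnings if warnings is not None else WarningsLog()
        self.header_lines: list[str] = []
        self._line_no = 0
        self._index = 0

    def __iter__(self) -> Iterator[Variant]:
        try:
            for line in self._fh:
                self._line_no += 1
                line = line.rstrip("\n").rstrip("\r")
                if not line:
                    continue
                if line.startswith("##"):
                    self.header_lines.append(line)
                    continue
                if line.startswith("#"):
                    self.header_lines.append(line)
                    cols = line.split("\t")
                    if cols[: len(self.REQUIRED)] != self.REQUIRED:
                        raise ValueError(
                            "VCF column header missing required columns "
                            f"(line {self._line_no}): {line!r}"
                        )
                    continue
                v = self._parse_line(line)
                if v is not None:
                    yield v
        finally:
            if self._owned:
                self._fh.close()

    def _skip(self, code: str, message: str) -> None:
        self.warnings.warn(self._line_no, code, message)

    def _parse_line(self, line: str) -> Optional[Variant]:
        fields = re.split(r"\t|\s+", line) if "\t" not in line else line.split("\t")
        if len(fields) < 5:
            self._skip("MALFORMED_LINE", f"expected >=5 columns, got {len(fields)}")
            return None
        chrom, pos_s, vid, ref, alt_s = fields[:5]
        try:
            pos = int(pos_s)
        except ValueError:
            self._skip("MALFORMED_LINE", f"non-integer POS {pos_s!r}")
            return None
        if pos < 1 or not ref or alt_s in ("", "."):
            self._skip("MALFORMED_LINE", "empty or invalid REF/ALT/POS")
            return None
        ref = ref.upper()
        alts_in = [a.upper() for a in alt_s.split(",")]
        info = _parse_info(fields[7]) if len(fields) >= 8 else {}

        sv_type = None
        symbolic = [a for a in alts_in if _SYMBOLIC_RE.match(a)]
        if symbolic or "SVTYPE" in info:
            sv_type = info.get("SVTYPE")
            if sv_type is None and symbolic:
                sv_type = _SYMBOLIC_RE.match(symbolic[0]).group(1).split(":")[0]
            if sv_type is not None:
                sv_type = {"DUP:TANDEM": "DUP"}.get(sv_type, sv_type)
                if sv_type not in _SV_TYPES:
                    self._skip("MALFORMED_LINE", f"unsupported SVTYPE {sv_type!r}")
                    return None
            try:
                end = int(info["END"]) if "END" in info else pos + len(ref) - 1
            except ValueError:
                self._skip("MALFORMED_LINE", f"non-integer END {info.get('END')!r}")
                return None
            variant = Variant(
                chrom=chrom, start=pos, end=end, ref_allele=ref,
                alt_alleles=alts_in, id=None if vid == "." else vid,
                input_index=self._index, is_structural=True, sv_type=sv_type,
                raw_vcf_fields=fields, input_line=self._line_no,
            )
            self._index += 1
            return variant

        bad = [a for a in alts_in if not _ALLELE_RE.match(a)]
        if bad or not _ALLELE_RE.match(ref):
            self._skip("MALFORMED_LINE", f"invalid allele characters in {line!r}")
            return None
        start, end, ref2, alts2 = _strip_anchor(pos, ref, alts_in)
        span = 0 if ref2 == "-" else len(ref2)
        longest_ins = max((0 if a == "-" else len(a)) for a in alts2)
        structural = span > SV_LENGTH_THRESHOLD or longest_ins > SV_LENGTH_THRESHOLD
        sv_type = None
        if structural:
            change = longest_ins - span
            sv_type = "DEL" if change < 0 else "INS" if change > 0 else None
        variant = Variant(
            chrom=chrom, start=start, end=end, ref_allele=ref2,
            alt_alleles=alts2, id=None if vid == "." else vid,
            input_index=self._index, is_structural=structural, sv_type=sv_type,
            raw_vcf_fields=fields, input_line=self._line_no,
        )
        self._index += 1
        return variant


def read_vcf(source, warnings: Optional[WarningsLog] = None) -> list[Variant]:
    """Read all variants from a VCF path/stream, in input order."""
    return list(VcfReader(source, warnings=warnings))


# ---------------------------------------------------------------------------
# Allele minimisation and QC


def minimise_alleles(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce (ref, alt) to minimal representation by stripping shared bases.

    5' shared bases are stripped first (advancing ``start`` by one per base),
    then 3' shared bases.  Identical alleles reduce to the degenerate
    ``("-", "-")`` pair, which callers should flag for QC.  Disabled by
    default in the pipeline; enable with ``minimise=True``.
    """
    r = "" if ref == "-" else ref
    a = "" if alt == "-" else alt
    if r == a:
        return start, "-", "-"
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        start += 1
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    return start, r or "-", a or "-"


def qc_check(variant: Variant, genome=None) -> QCReport:
    """Validate a variant; returns all failures, never raises.

    ``genome`` is any object with a ``sequence(chrom, start, end)`` method
    (e.g. the annotation store's genome); without it the reference-match
    check is skipped and QC degrades to coordinate-only checks.
    """
    report = QCReport(variant)
    v = variant
    if v.start > v.end + 1:
        report.add(QCReport.COORD_ORDER,
                   f"start {v.start} beyond end {v.end}+1")
        return report
    for allele in [v.ref_allele, *v.alt_alleles]:
        if not (_ALLELE_RE.match(allele)
                or (v.is_structural and _SYMBOLIC_RE.match(allele))):
            report.add(QCReport.BAD_ALLELE_CHARS,
                       f"allele {allele!r} has characters outside ACGTN/-")
    if not v.is_structural:
        if v.ref_allele == "-":
            if not v.is_insertion_site:
                report.add(QCReport.LENGTH_MISMATCH,
                           "empty reference allele requires start = end + 1")
        elif v.end - v.start + 1 != len(v.ref_allele):
            report.add(
                QCReport.LENGTH_MISMATCH,
                f"reference allele length {len(v.ref_allele)} does not match "
                f"span {v.start}-{v.end}",
            )
    if (genome is not None and not v.is_structural and v.ref_allele != "-"
            and QCReport.LENGTH_MISMATCH not in report.codes
            and QCReport.BAD_ALLELE_CHARS not in report.codes):
        try:
            expected = genome.sequence(v.chrom, v.start, v.end).upper()
        except (KeyError, ValueError):
            expected = None
        if expected is not None and expected != v.ref_allele:
            report.add(
                QCReport.REF_MISMATCH,
                f"input reference {v.ref_allele} != genome {expected} at "
                f"{v.location}",
            )
    return report


def read_identifier_lines(source) -> list[str]:
    """Identifier input: one variant ID per line."""
    fh, owned = _open_text(source)
    try:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    finally:
        if owned:
            fh.close()
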
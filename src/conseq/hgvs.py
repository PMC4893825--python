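"""HGVS nomenclature: generation and parsing.

Descriptions are produced at genomic (g.), coding (c.), non-coding (n.) and
protein (p.) levels.  Indels in repetitive sequence are reported at the most
3' position possible *relative to the described sequence*: transcript
orientation for c./n. (which on a minus-strand transcript means the lowest
genomic coordinate), and the forward genomic strand for g..  Insertions that
duplicate the immediately 5'-adjacent sequence are written as ``dup``.
Deleted/duplicated bases are omitted from del/dup descriptions (position-only
form), which keeps descriptions stable under reference edits.

Reference accessions are always versioned; transcripts lacking a version are
assigned version 1 at cache build.

Parsing supports g./c./n. substitutions, deletions, duplications and
insertions (p. input is out of scope), projecting c. coordinates — including
UTR and intronic offset positions — through the transcript exon structure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

from Bio.SeqUtils import seq3

from .models import Transcript
from .store import AnnotationStore, reverse_complement, translate_cds
from .variants import Variant, VariantAllele

__all__ = [
    "HgvsDescription", "HgvsError", "UnsupportedNotationError",
    "ResolutionError", "hgvs_g", "hgvs_c", "hgvs_p", "parse_hgvs_input",
]

log = logging.getLogger(__name__)


class HgvsError(ValueError):
    pass


class UnsupportedNotationError(HgvsError):
    pass


class ResolutionError(HgvsError):
    pass


@dataclass(frozen=True)
class HgvsDescription:
    reference_accession: str
    level: str  # g / c / n / p
    description: str

    def __str__(self) -> str:
        return self.description


# ---------------------------------------------------------------------------
# 3' shifting primitives (0-based string coordinates)


def shift_deletion(seq: str, i: int, length: int) -> int:
    """Rightmost equivalent start of deleting seq[i:i+length]."""
    while i + length < len(seq) and seq[i + length] == seq[i]:
        i += 1
    return i

def shift_insertion(seq: str, i: int, ins: str) -> tuple[int, str]:
    """Rightmost equivalent placement of inserting ``ins`` after seq[i].

    ``i`` may be -1 for an insertion before the first base.  Returns the new
    anchor index and the rotated inserted sequence.
    """
    while i + 1 < len(seq) and seq[i + 1] == ins[0]:
        ins = ins[1:] + ins[0]
        i += 1
    return i, ins


def is_duplication(seq: str, i: int, ins: str) -> bool:
    """True when inserting ``ins`` after seq[i] duplicates seq[i-len+1:i+1]."""
    lo = i - len(ins) + 1
    return lo >= 0 and seq[lo:i + 1] == ins


# ---------------------------------------------------------------------------
# g. level


def hgvs_g(allele: VariantAllele, chrom_accession: Optional[str] = None,
           genome=None) -> HgvsDescription:
    """Genomic-level description; positions 3'-shifted on the forward strand."""
    v = allele.variant
    if v.is_structural:
        raise UnsupportedNotationError("structural variants have no HGVS support")
    acc = chrom_accession or v.chrom
    ref = "" if v.ref_allele == "-" else v.ref_allele
    alt = "" if allele.allele == "-" else allele.allele

    if len(ref) == 1 and len(alt) == 1:
        body = (f"{v.start}{ref}=" if ref == alt
                else f"{v.start}{ref}>{alt}")
        return HgvsDescription(acc, "g", f"{acc}:g.{body}")

    if ref and not alt:  # deletion
        start = v.start
        if genome is not None:
            ctx_end = min(genome.length(v.chrom), v.end + len(ref) + 200)
            ctx = genome.sequence(v.chrom, v.start, ctx_end)
            start = v.start + shift_deletion(ctx, 0, len(ref))
        end = start + len(ref) - 1
        body = f"{start}del" if len(ref) == 1 else f"{start}_{end}del"
        return HgvsDescription(acc, "g", f"{acc}:g.{body}")

    if alt and not ref:  # insertion
        anchor = v.end  # insertion after this base
        ins = alt
        if genome is not None:
            lo = max(1, anchor - len(ins) - 200)
            hi = min(genome.length(v.chrom), anchor + len(ins) + 200)
            ctx = genome.sequence(v.chrom, lo, hi)
            i, ins = shift_insertion(ctx, anchor - lo, ins)
            if is_duplication(ctx, i, ins):
                d_lo = lo + i - len(ins) + 1
                d_hi = lo + i
                body = (f"{d_lo}dup" if len(ins) == 1
                        else f"{d_lo}_{d_hi}dup")
                return HgvsDescription(acc, "g", f"{acc}:g.{body}")
            anchor = lo + i
        body = f"{anchor}_{anchor + 1}ins{ins}"
        return HgvsDescription(acc, "g", f"{acc}:g.{body}")

    # delins
    if v.start == v.end:
        body = f"{v.start}delins{alt}"
    else:
        body = f"{v.start}_{v.end}delins{alt}"
    return HgvsDescription(acc, "g", f"{acc}:g.{body}")


# ---------------------------------------------------------------------------
# c. / n. level


def _c_fmt(t: Transcript, cdna: int) -> str:
    """Format a cDNA position as a c. (coding) or n. position string."""
    if not t.is_coding:
        return str(cdna)
    ccs, cce = t.cdna_coding_start, t.cdna_coding_end
    if cdna < ccs:
        return f"-{ccs - cdna}"
    if cdna > cce:
        return f"*{cdna - cce}"
    return str(cdna - ccs + 1)


def _intronic_fmt(t: Transcript, gpos: int) -> Optional[str]:
    """Intronic offset position, e.g. 30+2 or 31-5; None if not intronic."""
    for i, iv in enumerate(t.introns):
        if not (iv.start <= gpos <= iv.end):
            continue
        if t.strand == 1:
            d_donor = gpos - iv.start + 1
            d_acceptor = iv.end - gpos + 1
        else:
            d_donor = iv.end - gpos + 1
            d_acceptor = gpos - iv.start + 1
        donor_exon = t.exons[i]
        acceptor_exon = t.exons[i + 1]
        if d_donor <= d_acceptor:
            anchor = t.cdna_position(
                donor_exon.end if t.strand == 1 else donor_exon.start)
            return f"{_c_fmt(t, anchor)}+{d_donor}"
        anchor = t.cdna_position(
            acceptor_exon.start if t.strand == 1 else acceptor_exon.end)
        return f"{_c_fmt(t, anchor)}-{d_acceptor}"
    return None


def _position_token(t: Transcript, gpos: int) -> str:
    c = t.cdna_position(gpos)
    if c is not None:
        return _c_fmt(t, c)
    tok = _intronic_fmt(t, gpos)
    if tok is None:
        raise HgvsError(
            f"position {gpos} outside transcript {t.id} body")
    return tok


def hgvs_c(allele: VariantAllele, transcript: Transcript,
           store: AnnotationStore) -> HgvsDescription:
    """Transcript-level description (c. for coding, n. for non-coding)."""
    t = transcript
    level = "c" if t.is_coding else "n"
    acc = t.accession
    v = allele.variant
    if v.is_structural:
        raise UnsupportedNotationError("structural variants have no HGVS support")
    strand = t.strand
    ref = "" if v.ref_allele == "-" else v.ref_allele
    alt = "" if allele.allele == "-" else allele.allele
    ref_t = ref if strand == 1 else reverse_complement(ref)
    alt_t = alt if strand == 1 else reverse_complement(alt)

    def desc(body: str) -> HgvsDescription:
        return HgvsDescription(acc, level, f"{acc}:{level}.{body}")

    if len(ref) == 1 and len(alt) == 1:  # substitution
        tok = _position_token(t, v.start)
        if ref_t == alt_t:
            return desc(f"{tok}{ref_t}=")
        return desc(f"{tok}{ref_t}>{alt_t}")

    cdna = store.spliced_sequence(t)

    if ref and not alt:  # deletion
        g5, g3 = (v.start, v.end) if strand == 1 else (v.end, v.start)
        c5 = t.cdna_position(g5)
        c3 = t.cdna_position(g3)
        if c5 is not None and c3 is not None and c3 - c5 + 1 == len(ref):
            i = shift_deletion(cdna, c5 - 1, len(ref))
            lo, hi = i + 1, i + len(ref)
            body = (f"{_c_fmt(t, lo)}del" if len(ref) == 1
                    else f"{_c_fmt(t, lo)}_{_c_fmt(t, hi)}del")
            return desc(body)
        return _intronic_indel(t, allele, desc, store)

    if alt and not ref:  # insertion
        g5, g3 = (v.end, v.start) if strand == 1 else (v.start, v.end)
        c5 = t.cdna_position(g5)
        c3 = t.cdna_position(g3)
        if c5 is not None and c3 == c5 + 1:
            i, ins = shift_insertion(cdna, c5 - 1, alt_t)
            if is_duplication(cdna, i, ins):
                lo, hi = i - len(ins) + 2, i + 1
                body = (f"{_c_fmt(t, lo)}dup" if len(ins) == 1
                        else f"{_c_fmt(t, lo)}_{_c_fmt(t, hi)}dup")
                return desc(body)
            body = f"{_c_fmt(t, i + 1)}_{_c_fmt(t, i + 2)}ins{ins}"
            return desc(body)
        return _intronic_indel(t, allele, desc, store)

    # delins (no shifting: the replaced span is fixed)
    g5, g3 = (v.start, v.end) if strand == 1 else (v.end, v.start)
    body = (f"{_position_token(t, g5)}_{_position_token(t, g3)}delins{alt_t}"
            if v.start != v.end else
            f"{_position_token(t, g5)}delins{alt_t}")
    return desc(body)


def _intronic_indel(t: Transcript, allele: VariantAllele, desc, store):
    """Indel not fully exonic: shift within the containing intron if any,
    otherwise describe the input span unshifted."""
    v = allele.variant
    strand = t.strand
    ref = "" if v.ref_allele == "-" else v.ref_allele
    alt = "" if allele.allele == "-" else allele.allele
    intron = None
    s, e = v.span()
    for iv in t.introns:
        if iv.start <= s and e <= iv.end:
            intron = iv
            break
    if intron is not None and bool(ref) != bool(alt):
        gseq = store.genome.sequence(t.chrom, intron.start, intron.end)
        iseq = gseq if strand == 1 else reverse_complement(gseq)

        def g_of(idx0: int) -> int:  # intron (transcript-orientation) index -> genomic
            return (intron.start + idx0 if strand == 1 else intron.end - idx0)

        if ref:  # deletion
            i0 = (v.start - intron.start if strand == 1
                  else intron.end - v.end)
            i = shift_deletion(iseq, i0, len(ref))
            lo_g, hi_g = g_of(i), g_of(i + len(ref) - 1)
            body = (f"{_position_token(t, lo_g)}del" if len(ref) == 1 else
                    f"{_position_token(t, lo_g)}_{_position_token(t, hi_g)}del")
            return desc(body)
        ins_t = alt if strand == 1 else reverse_complement(alt)
        anchor0 = (v.end - intron.start if strand == 1
                   else intron.end - v.start)
        i, ins = shift_insertion(iseq, anchor0, ins_t)
        if is_duplication(iseq, i, ins):
            lo_g, hi_g = g_of(i - len(ins) + 1), g_of(i)
            body = (f"{_position_token(t, lo_g)}dup" if len(ins) == 1 else
                    f"{_position_token(t, lo_g)}_{_position_token(t, hi_g)}dup")
            return desc(body)
        body = (f"{_position_token(t, g_of(i))}_"
                f"{_position_token(t, g_of(i + 1))}ins{ins}")
        return desc(body)

    # mixed exon/intron span: unshifted description of the input span
    g5, g3 = (v.start, v.end) if strand == 1 else (v.end, v.start)
    if not alt:
        body = (f"{_position_token(t, g5)}del" if v.start == v.end else
                f"{_position_token(t, g5)}_{_position_token(t, g3)}del")
    else:
        body = f"{_position_token(t, g5)}_{_position_token(t, g3)}ins{alt}"
    return desc(body)


# ---------------------------------------------------------------------------
# p. level


def _aa3(aa: str) -> str:
    if aa == "*":
        return "Ter"
    if aa == "U":
        return "Sec"
    if aa == "X":
        return "Xaa"
    return seq3(aa)


def hgvs_p(allele: VariantAllele, transcript: Transcript,
           store: AnnotationStore) -> Optional[HgvsDescription]:
    """Protein-level description, by re-translating the mutant CDS.

    Returns None when the allele does not cleanly change the coding
    sequence (non-coding effects are absent, not errors).
    """
    t = transcript
    if not t.is_coding:
        return None
    v = allele.variant
    if v.is_structural:
        return None
    cds = store.cds_sequence(t)
    cdna = store.spliced_sequence(t)
    utr3 = cdna[t.cdna_coding_end:]
    table = store.codon_table_for(t.chrom)
    sec = t.selenocysteine_positions
    strand = t.strand
    ref = "" if v.ref_allele == "-" else v.ref_allele
    alt = "" if allele.allele == "-" else allele.allele
    alt_t = alt if strand == 1 else reverse_complement(alt)

    if v.is_insertion_site:
        g5 = v.end if strand == 1 else v.start
        c5 = t.cds_position(g5)
        g3 = v.start if strand == 1 else v.end
        c3 = t.cds_position(g3)
        if c5 is None or c3 != c5 + 1 or not alt_t:
            return None
        mutant = cds[:c5] + alt_t + cds[c5:]
    else:
        g5, g3 = (v.start, v.end) if strand == 1 else (v.end, v.start)
        cs = t.cds_position(g5)
        ce = t.cds_position(g3)
        if cs is None or ce is None or ce - cs + 1 != (v.end - v.start + 1):
            return None
        mutant = cds[:cs - 1] + alt_t + cds[ce:]

    try:
        ref_p = translate_cds(cds, table, selenocysteine=sec)
        alt_p_full = translate_cds(mutant + utr3, table, selenocysteine=sec)
    except ValueError:
        return None
    # truncate the mutant translation at its first stop
    stop_i = alt_p_full.find("*")
    alt_p = alt_p_full if stop_i < 0 else alt_p_full[:stop_i + 1]

    acc = t.accession

    def desc(body: str) -> HgvsDescription:
        return HgvsDescription(acc, "p", f"{acc}:p.{body}")

    if ref_p == alt_p:
        # synonymous: name the (first) affected residue
        pos = ((cs if not v.is_insertion_site else c5) + 2) // 3
        pos = min(pos, len(ref_p))
        return desc(f"{_aa3(ref_p[pos - 1])}{pos}=")

    # first differing residue
    i = 0
    while i < len(ref_p) and i < len(alt_p) and ref_p[i] == alt_p[i]:
        i += 1
    pos = i + 1
    if pos == 1:
        return desc("Met1?")
    ref_aa = ref_p[i] if i < len(ref_p) else ""
    alt_aa = alt_p[i] if i < len(alt_p) else ""

    frameshift = (len(alt_t) - (0 if v.is_insertion_site
                                else (v.end - v.start + 1))) % 3 != 0
    if frameshift:
        if alt_aa == "*":
            return desc(f"{_aa3(ref_aa)}{pos}Ter")
        stop_off = alt_p[i:].find("*")
        ter = "?" if stop_off < 0 else str(stop_off + 1)
        new = _aa3(alt_aa) if alt_aa else "?"
        return desc(f"{_aa3(ref_aa)}{pos}{new}fsTer{ter}")

    if ref_aa == "*":  # stop lost: extension
        stop_off = alt_p[i:].find("*")
        ext = "?" if stop_off < 0 else str(stop_off)
        return desc(f"Ter{pos}{_aa3(alt_aa)}extTer{ext}")
    if alt_aa == "*":  # premature stop truncates the protein
        return desc(f"{_aa3(ref_aa)}{pos}Ter")
    if len(ref_p) == len(alt_p) and ref_p[i + 1:] == alt_p[i + 1:]:
        if alt_aa == "*":
            return desc(f"{_aa3(ref_aa)}{pos}Ter")
        return desc(f"{_aa3(ref_aa)}{pos}{_aa3(alt_aa)}")

    # in-frame length change
    diff = len(ref_p) - len(alt_p)
    if diff > 0:  # deletion of diff residues
        # shift to the most 3' equivalent residue run
        j = i
        while (j + diff < len(ref_p)
               and ref_p[j + diff] == ref_p[j]):
            j += 1
        lo, hi = j + 1, j + diff
        if diff == 1:
            return desc(f"{_aa3(ref_p[lo - 1])}{lo}del")
        return desc(f"{_aa3(ref_p[lo - 1])}{lo}_{_aa3(ref_p[hi - 1])}{hi}del")
    ins_n = -diff
    if alt_p[i:i + ins_n] == alt_p[i + ins_n:i + 2 * ins_n] and False:
        pass  # duplication naming not attempted; plain ins form below
    inserted = alt_p[i:i + ins_n]
    if "*" in inserted:
        return desc(f"{_aa3(ref_aa if ref_aa else ref_p[i-1])}{pos}Ter")
    left = i  # residue before the insertion (1-based)
    if left == 0 or left >= len(ref_p):
        return desc(f"{_aa3(alt_p[i])}{pos}ins")
    ins3 = "".join(_aa3(a) for a in inserted)
    return desc(f"{_aa3(ref_p[left - 1])}{left}_{_aa3(ref_p[left])}{left + 1}"
                f"ins{ins3}")


# ---------------------------------------------------------------------------
# Parsing (HGVS input)

_HGVS_RE = re.compile(r"^(?P<acc>[^:]+):(?P<level>[gcnp])\.(?P<rest>\S+)$")
_POS_RE = r"(?:\*|-)?\d+(?:[+-]\d+)?"
_SNV_RE = re.compile(
    rf"^(?P<pos>{_POS_RE})(?P<ref>[ACGTN])(?:>(?P<alt>[ACGTN])|=)$")
_DEL_RE = re.compile(
    rf"^(?P<p1>{_POS_RE})(?:_(?P<p2>{_POS_RE}))?del(?P<seq>[ACGTN]*)$")
_DUP_RE = re.compile(
    rf"^(?P<p1>{_POS_RE})(?:_(?P<p2>{_POS_RE}))?dup(?P<seq>[ACGTN]*)$")
_INS_RE = re.compile(
    rf"^(?P<p1>{_POS_RE})_(?P<p2>{_POS_RE})ins(?P<seq>[ACGTN]+)$")
_CPOS_RE = re.compile(r"^(?P<base>(?:\*|-)?\d+)(?P<off>[+-]\d+)?$")


def _c_position_to_genomic(t: Transcript, token: str) -> int:
    m = _CPOS_RE.match(token)
    if not m:
        raise HgvsError(f"unparseable position token {token!r}")
    base = m.group("base")
    off = int(m.group("off") or 0)
    if t.is_coding:
        ccs, cce = t.cdna_coding_start, t.cdna_coding_end
        if base.startswith("-"):
            cdna = ccs - int(base[1:])
        elif base.startswith("*"):
            cdna = cce + int(base[1:])
        else:
            cdna = ccs + int(base) - 1
    else:
        cdna = int(base)
    g = t.genomic_position(cdna)
    if off:
        g += off * t.strand
    return g


def parse_hgvs_input(notation: str, store: AnnotationStore) -> Variant:
    """Resolve a g./c./n. HGVS notation to a genomic Variant.

    The reference feature is looked up in the annotation store (chromosome
    for g., transcript accession for c./n.); a version mismatch warns and
    resolves on the accession.  p. notation is unsupported.
    """
    notation = notation.strip()
    m = _HGVS_RE.match(notation)
    if not m:
        raise HgvsError(f"unparseable HGVS notation {notation!r}")
    acc, level, rest = m.group("acc"), m.group("level"), m.group("rest")
    if level == "p":
        raise UnsupportedNotationError(
            f"protein-level HGVS input is not supported: {notation!r}")

    if level == "g":
        chrom = acc
        if chrom not in store.genome:
            raise ResolutionError(f"unknown sequence {chrom!r} in {notation!r}")

        def fetch(s, e):
            return store.genome.sequence(chrom, s, e)

        sm = _SNV_RE.match(rest)
        if sm:
            pos = int(sm.group("pos"))
            alt = sm.group("alt") or sm.group("ref")
            return Variant(chrom=chrom, start=pos, end=pos,
                           ref_allele=sm.group("ref"), alt_alleles=[alt])
        dm = _DEL_RE.match(rest)
        if dm:
            p1 = int(dm.group("p1"))
            p2 = int(dm.group("p2") or p1)
            return Variant(chrom=chrom, start=p1, end=p2,
                           ref_allele=fetch(p1, p2), alt_alleles=["-"])
        um = _DUP_RE.match(rest)
        if um:
            p1 = int(um.group("p1"))
            p2 = int(um.group("p2") or p1)
            return Variant(chrom=chrom, start=p2 + 1, end=p2,
                           ref_allele="-", alt_alleles=[fetch(p1, p2)])
        im = _INS_RE.match(rest)
        if im:
            p1 = int(im.group("p1"))
            return Variant(chrom=chrom, start=p1 + 1, end=p1,
                           ref_allele="-", alt_alleles=[im.group("seq")])
        raise HgvsError(f"unsupported g. description {notation!r}")

    # c. / n.
    t = store.transcript_by_id(acc)
    if t is None:
        raise ResolutionError(f"unknown transcript {acc!r} in {notation!r}")
    if "." in acc:
        want = acc.rsplit(".", 1)[1]
        if want.isdigit() and int(want) != t.version:
            log.warning("HGVS version mismatch for %s: input %s, store %s; "
                        "resolving on accession", acc, want, t.version)
    expected_level = "c" if t.is_coding else "n"
    if level != expected_level:
        raise HgvsError(
            f"{notation!r}: transcript {t.id} requires {expected_level}. level")
    strand = t.strand

    def t2g_allele(seq: str) -> str:
        return seq if strand == 1 else reverse_complement(seq)

    sm = _SNV_RE.match(rest)
    if sm:
        g = _c_position_to_genomic(t, sm.group("pos"))
        alt = sm.group("alt") or sm.group("ref")
        return Variant(chrom=t.chrom, start=g, end=g,
                       ref_allele=t2g_allele(sm.group("ref")),
                       alt_alleles=[t2g_allele(alt)])
    dm = _DEL_RE.match(rest)
    if dm:
        g1 = _c_position_to_genomic(t, dm.group("p1"))
        g2 = (_c_position_to_genomic(t, dm.group("p2"))
              if dm.group("p2") else g1)
        lo, hi = min(g1, g2), max(g1, g2)
        return Variant(chrom=t.chrom, start=lo, end=hi,
                       ref_allele=store.genome.sequence(t.chrom, lo, hi),
                       alt_alleles=["-"])
    um = _DUP_RE.match(rest)
    if um:
        g1 = _c_position_to_genomic(t, um.group("p1"))
        g2 = (_c_position_to_genomic(t, um.group("p2"))
              if um.group("p2") else g1)
        lo, hi = min(g1, g2), max(g1, g2)
        # duplicate placed 3' of the run in transcript orientation
        anchor = hi if strand == 1 else lo
        if strand == 1:
            return Variant(chrom=t.chrom, start=anchor + 1, end=anchor,
                           ref_allele="-",
                           alt_alleles=[store.genome.sequence(t.chrom, lo, hi)])
        return Variant(chrom=t.chrom, start=anchor, end=anchor - 1,
                       ref_allele="-",
                       alt_alleles=[store.genome.sequence(t.chrom, lo, hi)])
    im = _INS_RE.match(rest)
    if im:
        g1 = _c_position_to_genomic(t, im.group("p1"))
        g2 = _c_position_to_genomic(t, im.group("p2"))
        lo = min(g1, g2)
        return Variant(chrom=t.chrom, start=lo + 1, end=lo,
                       ref_allele="-",
                       alt_alleles=[t2g_allele(im.group("seq"))])
    raise HgvsError(f"unsupported {level}. description {notation!r}")
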
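"""Consequence assignment engine.

For each (variant allele, overlapped feature) pair the engine builds one
:class:`OverlapResult` carrying Sequence Ontology consequence terms plus
transcript/protein coordinates, codon and amino-acid changes, and open
``extras`` for plugins and custom tracks.

Transcript consequences are evaluated by a suite of *predicates*, one per
assignable term.  Before a predicate runs, a cheap pre-predicate gate checks
whether it can possibly apply (e.g. protein-level predicates are skipped for
a wholly intronic variant); gated-out predicates are counted as skipped in
the run statistics.  Gates are sound: disabling them never changes the
assigned terms, only the amount of work done.  Expensive intermediate
results (the coding-change analysis, spliced sequences) are computed once
per pair and cached on the evaluation context.

Term sets are reduced with the most-specific-term rule: a term that is an
ancestor of another assigned term is dropped, while terms on distinct
ontology branches (say a splice-region change that also alters the protein)
co-exist on one result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional

from .models import MotifFeature, RegulatoryFeature, RunStatistics, Transcript
from .motifs import MotifImpact, motif_consequence
from .registry import Registry, default_registry, most_specific_terms
from .store import AnnotationStore, reverse_complement, translate_cds
from .variants import Variant, VariantAllele

__all__ = [
    "OverlapResult",
    "CoordinateBundle",
    "map_to_transcript",
    "assign_consequences",
    "assign_sv_consequences",
    "TRANSCRIPT_PREDICATES",
    "SPLICE_DONOR_ACCEPTOR_BASES",
    "SPLICE_REGION_EXONIC_BASES",
    "SPLICE_REGION_INTRONIC_BASES",
]

SPLICE_DONOR_ACCEPTOR_BASES = 2   # first/last N intronic bases
SPLICE_REGION_EXONIC_BASES = 3    # exonic bases 1..3 from a junction
SPLICE_REGION_INTRONIC_BASES = (3, 8)  # intronic bases 3..8 from a junction

NON_CODING_BIOTYPES_EXEMPT = ()  # all non-protein_coding biotypes are non-coding


def _overlap(a1: int, a2: int, b1: int, b2: int) -> bool:
    return a1 <= b2 and a2 >= b1


@dataclass
class CoordinateBundle:
    """Transcript-relative coordinates of a variant span."""

    cdna_interval: Optional[tuple[int, int]] = None
    cds_interval: Optional[tuple[int, int]] = None
    protein_interval: Optional[tuple[int, int]] = None
    exon_number: Optional[str] = None
    intron_number: Optional[str] = None
    distance: Optional[int] = None  # bp to transcript when outside it


@dataclass
class OverlapResult:
    """One unit of annotation: one alternative allele on one feature."""

    allele: VariantAllele
    feature: object  # Transcript | RegulatoryFeature | MotifFeature | None
    terms: list[str]
    coords: CoordinateBundle = field(default_factory=CoordinateBundle)
    ref_codons: Optional[str] = None
    alt_codons: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    hgvs_g: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    motif_impact: Optional[MotifImpact] = None
    colocated: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def variant(self) -> Variant:
        return self.allele.variant

    @property
    def feature_type(self) -> str:
        if self.feature is None:
            return "Intergenic"
        if isinstance(self.feature, Transcript):
            return "Transcript"
        if isinstance(self.feature, RegulatoryFeature):
            return "RegulatoryFeature"
        if isinstance(self.feature, MotifFeature):
            return "MotifFeature"
        return type(self.feature).__name__

    @property
    def feature_id(self) -> str:
        return "" if self.feature is None else self.feature.id

    def impact(self, registry: Optional[Registry] = None) -> str:
        registry = registry or default_registry()
        return min(
            (registry[t] for t in self.terms), key=lambda t: t.rank
        ).impact


# ---------------------------------------------------------------------------
# Evaluation context


class _TranscriptContext:
    """Cached geometry and sequence analysis for one (allele, transcript)."""

    def __init__(self, allele: VariantAllele, transcript: Transcript,
                 store: AnnotationStore, flank: int):
        self.allele = allele
        self.t = transcript
        self.store = store
        self.flank = flank
        v = allele.variant
        self.s, self.e = v.span()
        self.ins = v.is_insertion_site

    # -- geometry ----------------------------------------------------------

    @cached_property
    def inside(self) -> bool:
        if self.ins:
            return self.t.start <= self.s and self.e <= self.t.end
        return _overlap(self.s, self.e, self.t.start, self.t.end)

    @cached_property
    def distance(self) -> Optional[int]:
        if self.inside:
            return None
        if self.e < self.t.start:
            return self.t.start - self.e
        return self.s - self.t.end

    @cached_property
    def genomically_before(self) -> bool:
        return self.e < self.t.start

    @cached_property
    def is_upstream(self) -> bool:
        if self.inside:
            return False
        return self.genomically_before if self.t.strand == 1 else not self.genomically_before

    def _touches(self, start: int, end: int) -> bool:
        """Span/insertion overlap with a genomic window.

        A zero-length insertion touches a window only when both flanking
        bases lie inside it (the insertion point is interior to the window).
        """
        if self.ins:
            return start <= self.s and self.e <= end
        return _overlap(self.s, self.e, start, end)

    @cached_property
    def overlapped_exons(self) -> list[int]:
        return [i for i, ex in enumerate(self.t.exons)
                if self._touches(ex.start, ex.end)]

    @cached_property
    def overlaps_exon(self) -> bool:
        return bool(self.overlapped_exons)

    @cached_property
    def overlapped_introns(self) -> list[int]:
        return [i for i, iv in enumerate(self.t.introns)
                if self._touches(iv.start, iv.end)]

    @cached_property
    def overlaps_intron(self) -> bool:
        return bool(self.overlapped_introns)

    @cached_property
    def donor_windows(self) -> list[tuple[int, int]]:
        k = SPLICE_DONOR_ACCEPTOR_BASES
        out = []
        for iv in self.t.introns:
            if len(iv) < k:
                continue
            if self.t.strand == 1:
                out.append((iv.start, iv.start + k - 1))
            else:
                out.append((iv.end - k + 1, iv.end))
        return out

    @cached_property
    def acceptor_windows(self) -> list[tuple[int, int]]:
        k = SPLICE_DONOR_ACCEPTOR_BASES
        out = []
        for iv in self.t.introns:
            if len(iv) < k:
                continue
            if self.t.strand == 1:
                out.append((iv.end - k + 1, iv.end))
            else:
                out.append((iv.start, iv.start + k - 1))
        return out

    @cached_property
    def splice_region_windows(self) -> list[tuple[int, int]]:
        """Exonic 1..3 and intronic 3..8 windows around every junction."""
        ex_n = SPLICE_REGION_EXONIC_BASES
        in_lo, in_hi = SPLICE_REGION_INTRONIC_BASES
        wins: list[tuple[int, int]] = []
        introns = self.t.introns
        for i, iv in enumerate(introns):
            # intronic windows, measured from each junction irrespective of strand
            left = (iv.start + in_lo - 1, min(iv.end, iv.start + in_hi - 1))
            right = (max(iv.start, iv.end - in_hi + 1), iv.end - in_lo + 1)
            for w in (left, right):
                if w[0] <= w[1]:
                    wins.append(w)
        for i, ex in enumerate(self.t.exons):
            first = i == 0
            last = i == len(self.t.exons) - 1
            # exonic side: junctions exist where the exon meets an intron
            lo_end = (ex.start, min(ex.end, ex.start + ex_n - 1))
            hi_end = (max(ex.start, ex.end - ex_n + 1), ex.end)
            if self.t.strand == 1:
                if not first:
                    wins.append(lo_end)
                if not last:
                    wins.append(hi_end)
            else:
                if not first:
                    wins.append(hi_end)
                if not last:
                    wins.append(lo_end)
        return wins

    @cached_property
    def near_splice(self) -> bool:
        pad = max(SPLICE_REGION_INTRONIC_BASES[1], SPLICE_REGION_EXONIC_BASES)
        for iv in self.t.introns:
            for junction in (iv.start, iv.end):
                if _overlap(self.s - pad, self.e + pad, junction, junction):
                    return True
        return False

    @cached_property
    def boundary_insertion(self) -> bool:
        """Insertion whose flanking bases straddle an exon/intron junction."""
        if not self.ins or not self.inside:
            return False
        left_exonic = any(ex.start <= self.s <= ex.end for ex in self.t.exons)
        right_exonic = any(ex.start <= self.e <= ex.end for ex in self.t.exons)
        return left_exonic != right_exonic

    # -- cDNA geometry -----------------------------------------------------

    @cached_property
    def flank_cdna(self) -> Optional[tuple[int, int]]:
        """For insertions: cDNA positions of both flanking bases, transcript
        order; None unless both flanks are exonic."""
        if not self.ins:
            return None
        a = self.t.cdna_position(self.s)
        b = self.t.cdna_position(self.e)
        if a is None or b is None:
            return None
        return (min(a, b), max(a, b))

    @cached_property
    def cdna_interval(self) -> Optional[tuple[int, int]]:
        if self.ins:
            return self.flank_cdna
        positions = []
        for i in self.overlapped_exons:
            ex = self.t.exons[i]
            lo = max(self.s, ex.start)
            hi = min(self.e, ex.end)
            positions += [self.t.cdna_position(lo), self.t.cdna_position(hi)]
        if not positions:
            return None
        return (min(positions), max(positions))

    @cached_property
    def cds_interval(self) -> Optional[tuple[int, int]]:
        t = self.t
        if not t.is_coding or self.cdna_interval is None:
            return None
        lo = max(self.cdna_interval[0], t.cdna_coding_start)
        hi = min(self.cdna_interval[1], t.cdna_coding_end)
        if lo > hi:
            return None
        return (lo - t.cdna_coding_start + 1, hi - t.cdna_coding_start + 1)

    @cached_property
    def protein_interval(self) -> Optional[tuple[int, int]]:
        if self.cds_interval is None:
            return None
        lo, hi = self.cds_interval
        return (math.ceil(lo / 3), math.ceil(hi / 3))

    @cached_property
    def overlaps_cds_region(self) -> bool:
        """Cheap gate: span intersects the genomic CDS bounds."""
        if not self.t.is_coding or not self.inside:
            return False
        return self._touches(self.t.cds_genomic_start, self.t.cds_genomic_end)

    @cached_property
    def overlaps_5utr(self) -> bool:
        t = self.t
        if not t.is_coding:
            return False
        if self.ins:
            if self.flank_cdna is None:
                return False
            return self.flank_cdna[0] < t.cdna_coding_start
        if self.cdna_interval is None:
            return False
        return self.cdna_interval[0] < t.cdna_coding_start

    @cached_property
    def overlaps_3utr(self) -> bool:
        t = self.t
        if not t.is_coding:
            return False
        if self.ins:
            if self.flank_cdna is None:
                return False
            return self.flank_cdna[1] > t.cdna_coding_end
        if self.cdna_interval is None:
            return False
        return self.cdna_interval[1] > t.cdna_coding_end

    # -- allele sequence in transcript orientation --------------------------

    @cached_property
    def alt_t(self) -> str:
        alt = "" if self.allele.allele == "-" else self.allele.allele
        return alt if self.t.strand == 1 else reverse_complement(alt)

    # -- coding-change analysis ---------------------------------------------

    @cached_property
    def coding(self) -> "_CodingChange":
        return _analyse_coding(self)


@dataclass
class _CodingChange:
    terms: list[str] = field(default_factory=list)
    ref_codons: Optional[str] = None
    alt_codons: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None


def _case_codons(codons: str, changed: set[int]) -> str:
    """Codon display: changed bases upper-case in lower-case context."""
    return "".join(
        c.upper() if i in changed else c.lower() for i, c in enumerate(codons)
    )


def _analyse_coding(ctx: _TranscriptContext) -> _CodingChange:
    t = ctx.t
    if not ctx.overlaps_cds_region:
        return _CodingChange()
    store = ctx.store
    cds = store.cds_sequence(t)
    table = store.codon_table_for(t.chrom)
    sec = t.selenocysteine_positions
    cds_len = len(cds)
    n_complete = cds_len - cds_len % 3

    if ctx.ins:
        return _analyse_coding_insertion(ctx, cds, n_complete)

    # transcript-orientation endpoints of the span
    g5, g3 = (ctx.s, ctx.e) if t.strand == 1 else (ctx.e, ctx.s)
    cs = t.cds_position(g5)
    ce = t.cds_position(g3)
    span_len = ctx.e - ctx.s + 1
    fully_coding = (
        cs is not None and ce is not None and ce - cs + 1 == span_len
    )
    if not fully_coding:
        return _analyse_coding_partial(ctx, cds)

    at = ctx.alt_t
    out = _CodingChange()
    if "N" in at:
        out.terms = ["coding_sequence_variant"]
        return out
    if cs > n_complete:
        out.terms = ["incomplete_terminal_codon_variant"]
        return out
    if ce > n_complete:
        out.terms = ["incomplete_terminal_codon_variant"]
        return out

    net = len(at) - span_len
    if net != 0 or len(at) != span_len:
        # deletion / length-changing complex substitution
        if net % 3 != 0:
            out.terms.append("frameshift_variant")
        elif net < 0:
            out.terms.append("inframe_deletion")
        else:
            out.terms.append("inframe_insertion")
        if cs <= 3:
            out.terms.insert(0, "start_lost")
        stop_first = n_complete - 2
        local_sec = tuple(p - (cds_len // 3 - 1) for p in sec)
        last_codon_is_stop = translate_cds(
            cds[n_complete - 3:n_complete], table) == "*"
        if ce >= stop_first and last_codon_is_stop and "start_lost" not in out.terms:
            out.terms.append("stop_lost")
        return out

    # length-preserving substitution: rebuild the affected codons
    i0 = (cs - 1) // 3
    i1 = (ce - 1) // 3
    ref_codons = cds[i0 * 3:(i1 + 1) * 3]
    alt_local = cds[:cs - 1] + at + cds[ce:]
    alt_codons = alt_local[i0 * 3:(i1 + 1) * 3]
    local_sec = tuple(p - i0 for p in sec if i0 < p <= i1 + 1)
    ref_aa = translate_cds(ref_codons, table, selenocysteine=local_sec)
    alt_aa = translate_cds(alt_codons, table, selenocysteine=local_sec)

    changed = set(range(cs - 1 - i0 * 3, ce - i0 * 3))
    out.ref_codons = _case_codons(ref_codons, changed)
    out.alt_codons = _case_codons(alt_codons, changed)
    out.ref_aa = ref_aa
    out.alt_aa = alt_aa

    if cs <= 3 and alt_codons[:3] != ref_codons[:3]:
        out.terms = ["start_lost"]
        return out
    if ref_aa == alt_aa:
        out.terms = ["stop_retained_variant" if "*" in ref_aa
                     else "synonymous_variant"]
    elif "*" in ref_aa and "*" not in alt_aa:
        out.terms = ["stop_lost"]
    elif "*" in alt_aa and "*" not in ref_aa:
        out.terms = ["stop_gained"]
    else:
        out.terms = ["missense_variant"]
    return out


def _analyse_coding_insertion(ctx: _TranscriptContext, cds: str,
                              n_complete: int) -> _CodingChange:
    t = ctx.t
    g5, g3 = (ctx.s, ctx.e) if t.strand == 1 else (ctx.e, ctx.s)
    c5 = t.cds_position(g5)
    c3 = t.cds_position(g3)
    out = _CodingChange()
    if c5 is None or c3 is None or c3 != c5 + 1:
        return out  # boundary cases belong to splice/UTR predicates
    ins = ctx.alt_t
    if not ins:
        return out
    if "N" in ins:
        out.terms = ["coding_sequence_variant"]
    elif c5 >= n_complete:
        out.terms = ["incomplete_terminal_codon_variant"]
    elif len(ins) % 3 != 0:
        out.terms = ["frameshift_variant"]
    else:
        out.terms = ["inframe_insertion"]
    return out


def _analyse_coding_partial(ctx: _TranscriptContext, cds: str) -> _CodingChange:
    """Span overlaps the CDS but is not a clean interior coding change."""
    t = ctx.t
    out = _CodingChange()
    if ctx.cds_interval is None:
        return out

    def genomic_of_cds(cpos: int) -> int:
        return t.genomic_position(t.cdna_coding_start + cpos - 1)

    start_codon = sorted(genomic_of_cds(p) for p in (1, 3))
    cds_len = len(cds)
    n_complete = cds_len - cds_len % 3
    if ctx._touches(start_codon[0], start_codon[1]):
        out.terms = ["start_lost"]
        return out
    if n_complete >= 3:
        stop_codon = sorted(
            genomic_of_cds(p) for p in (n_complete - 2, n_complete))
        table = ctx.store.codon_table_for(t.chrom)
        if (translate_cds(cds[n_complete - 3:n_complete], table) == "*"
                and ctx._touches(stop_codon[0], stop_codon[1])):
            out.terms = ["stop_lost"]
            return out
    out.terms = ["coding_sequence_variant"]
    return out


# ---------------------------------------------------------------------------
# Predicates


def _pred_upstream(ctx):
    return (not ctx.inside and ctx.is_upstream
            and ctx.distance is not None and ctx.distance <= ctx.flank)


def _pred_downstream(ctx):
    return (not ctx.inside and not ctx.is_upstream
            and ctx.distance is not None and ctx.distance <= ctx.flank)


def _pred_intron(ctx):
    if not ctx.inside:
        return False
    k = SPLICE_DONOR_ACCEPTOR_BASES
    for i in ctx.overlapped_introns:
        iv = ctx.t.introns[i]
        interior = (iv.start + k, iv.end - k)
        if ctx.ins:
            in_donor = any(w[0] <= ctx.s and ctx.e <= w[1]
                           for w in ctx.donor_windows)
            in_acceptor = any(w[0] <= ctx.s and ctx.e <= w[1]
                              for w in ctx.acceptor_windows)
            if not (in_donor or in_acceptor):
                return True
        elif interior[0] <= interior[1] and _overlap(
                ctx.s, ctx.e, interior[0], interior[1]):
            return True
    return False


def _pred_splice_donor(ctx):
    return ctx.inside and any(ctx._touches(*w) for w in ctx.donor_windows)


def _pred_splice_acceptor(ctx):
    return ctx.inside and any(ctx._touches(*w) for w in ctx.acceptor_windows)


def _pred_splice_region(ctx):
    if not ctx.inside:
        return False
    if ctx.boundary_insertion:
        return True
    return any(ctx._touches(*w) for w in ctx.splice_region_windows)


def _pred_5utr(ctx):
    return ctx.inside and ctx.overlaps_5utr and not ctx.boundary_insertion


def _pred_3utr(ctx):
    return ctx.inside and ctx.overlaps_3utr and not ctx.boundary_insertion


def _coding_pred(term):
    def pred(ctx):
        return ctx.inside and term in ctx.coding.terms
    pred.__name__ = f"_pred_{term}"
    return pred


def _pred_nc_exon(ctx):
    t = ctx.t
    if t.is_coding or not ctx.inside or not ctx.overlaps_exon:
        return False
    if ctx.boundary_insertion:
        return False
    if t.mature_mirna is not None and ctx._touches(
            t.mature_mirna.start, t.mature_mirna.end):
        return False  # the mature-miRNA predicate claims these
    return True


def _pred_mature_mirna(ctx):
    t = ctx.t
    return (t.biotype == "miRNA" and ctx.inside
            and t.mature_mirna is not None
            and ctx._touches(t.mature_mirna.start, t.mature_mirna.end))


def _pred_nc_transcript(ctx):
    return (not ctx.t.is_coding) and ctx.inside


_GATE_OUTSIDE = lambda ctx: not ctx.inside
_GATE_INTRON = lambda ctx: ctx.overlaps_intron
_GATE_SPLICE = lambda ctx: ctx.near_splice
_GATE_CDS = lambda ctx: ctx.overlaps_cds_region
_GATE_EXON_CODING = lambda ctx: ctx.overlaps_exon and ctx.t.is_coding
_GATE_NON_CODING = lambda ctx: not ctx.t.is_coding
_GATE_MIRNA = lambda ctx: ctx.t.biotype == "miRNA"

#: (term, gate, predicate) — order controls evaluation, not output order.
TRANSCRIPT_PREDICATES = [
    ("upstream_gene_variant", _GATE_OUTSIDE, _pred_upstream),
    ("downstream_gene_variant", _GATE_OUTSIDE, _pred_downstream),
    ("splice_donor_variant", _GATE_SPLICE, _pred_splice_donor),
    ("splice_acceptor_variant", _GATE_SPLICE, _pred_splice_acceptor),
    ("splice_region_variant", _GATE_SPLICE, _pred_splice_region),
    ("intron_variant", _GATE_INTRON, _pred_intron),
    ("5_prime_UTR_variant", _GATE_EXON_CODING, _pred_5utr),
    ("3_prime_UTR_variant", _GATE_EXON_CODING, _pred_3utr),
    ("start_lost", _GATE_CDS, _coding_pred("start_lost")),
    ("stop_gained", _GATE_CDS, _coding_pred("stop_gained")),
    ("stop_lost", _GATE_CDS, _coding_pred("stop_lost")),
    ("stop_retained_variant", _GATE_CDS, _coding_pred("stop_retained_variant")),
    ("synonymous_variant", _GATE_CDS, _coding_pred("synonymous_variant")),
    ("missense_variant", _GATE_CDS, _coding_pred("missense_variant")),
    ("frameshift_variant", _GATE_CDS, _coding_pred("frameshift_variant")),
    ("inframe_insertion", _GATE_CDS, _coding_pred("inframe_insertion")),
    ("inframe_deletion", _GATE_CDS, _coding_pred("inframe_deletion")),
    ("incomplete_terminal_codon_variant", _GATE_CDS,
     _coding_pred("incomplete_terminal_codon_variant")),
    ("coding_sequence_variant", _GATE_CDS,
     _coding_pred("coding_sequence_variant")),
    ("non_coding_transcript_exon_variant", _GATE_NON_CODING, _pred_nc_exon),
    ("mature_miRNA_variant", _GATE_MIRNA, _pred_mature_mirna),
    ("non_coding_transcript_variant", _GATE_NON_CODING, _pred_nc_transcript),
]

N_PREDICATES = len(TRANSCRIPT_PREDICATES)


def map_to_transcript(allele: VariantAllele, transcript: Transcript,
                      store: AnnotationStore, flank: int = 5000) -> CoordinateBundle:
    """Project a variant span through a transcript's exon structure."""
    ctx = _TranscriptContext(allele, transcript, store, flank)
    return _bundle_from_ctx(ctx)


def _bundle_from_ctx(ctx: _TranscriptContext) -> CoordinateBundle:
    t = ctx.t
    if not ctx.inside:
        return CoordinateBundle(distance=ctx.distance)
    s, e = ctx.s, ctx.e
    return CoordinateBundle(
        cdna_interval=ctx.cdna_interval,
        cds_interval=ctx.cds_interval,
        protein_interval=ctx.protein_interval,
        exon_number=t.exon_number(s, e) if ctx.overlaps_exon else None,
        intron_number=t.intron_number(s, e) if ctx.overlaps_intron else None,
    )


def assign_consequences(allele: VariantAllele, feature, store: AnnotationStore,
                        stats: Optional[RunStatistics] = None,
                        flank: int = 5000, gates: bool = True,
                        registry: Optional[Registry] = None) -> OverlapResult:
    """Build the OverlapResult for one allele on one feature.

    ``feature`` may be a Transcript, RegulatoryFeature, MotifFeature, or
    None (intergenic).  Structural variants are routed to the SV term rules.
    """
    registry = registry or default_registry()
    v = allele.variant
    if feature is None:
        return OverlapResult(allele=allele, feature=None,
                             terms=["intergenic_variant"])
    if v.is_structural:
        terms = assign_sv_consequences(v, feature, flank=flank)
        res = OverlapResult(allele=allele, feature=feature,
                            terms=most_specific_terms(terms, registry))
        if isinstance(feature, Transcript):
            res.coords = map_to_transcript(allele, feature, store, flank)
        return res

    if isinstance(feature, Transcript):
        ctx = _TranscriptContext(allele, feature, store, flank)
        terms: list[str] = []
        for term, gate, predicate in TRANSCRIPT_PREDICATES:
            if gates and not gate(ctx):
                if stats is not None:
                    stats.predicate_evaluations_skipped += 1
                continue
            if stats is not None:
                stats.predicate_evaluations += 1
            if predicate(ctx):
                terms.append(term)
        res = OverlapResult(
            allele=allele, feature=feature,
            terms=most_specific_terms(terms, registry),
            coords=_bundle_from_ctx(ctx),
            ref_codons=ctx.coding.ref_codons, alt_codons=ctx.coding.alt_codons,
            ref_aa=ctx.coding.ref_aa, alt_aa=ctx.coding.alt_aa,
        )
        return res

    if isinstance(feature, MotifFeature):
        impact = motif_consequence(allele, feature, store.genome)
        return OverlapResult(allele=allele, feature=feature,
                             terms=["TF_binding_site_variant"],
                             motif_impact=impact)
    if isinstance(feature, RegulatoryFeature):
        return OverlapResult(allele=allele, feature=feature,
                             terms=["regulatory_region_variant"])
    raise TypeError(f"unsupported feature type {type(feature)!r}")


def assign_sv_consequences(sv: Variant, feature, flank: int = 5000) -> list[str]:
    """Structural-variant consequence terms for one feature.

    Deletions that swallow a whole feature ablate it; partial deletions
    truncate.  Duplications/copy-number gains amplify whole features and
    elongate partially covered ones; structural insertions inside a feature
    elongate it.  A SV overlapping only a transcript's flank is reported
    up/downstream like any other variant.
    """
    if not sv.is_structural:
        raise ValueError("assign_sv_consequences requires a structural variant")
    s, e = sv.span()
    is_transcript = isinstance(feature, Transcript)
    fs, fe = feature.start, feature.end
    contains = s <= fs and fe <= e
    overlaps = _overlap(s, e, fs, fe)

    if not overlaps:
        if not is_transcript:
            return []
        before = e < fs
        upstream = before if feature.strand == 1 else not before
        return ["upstream_gene_variant" if upstream else "downstream_gene_variant"]

    if is_transcript:
        ablation, amplification = "transcript_ablation", "transcript_amplification"
    elif isinstance(feature, MotifFeature):
        ablation, amplification = "TFBS_ablation", "TFBS_amplification"
    else:
        ablation, amplification = ("regulatory_region_ablation",
                                   "regulatory_region_amplification")

    sv_type = sv.sv_type
    terms: list[str] = []
    if sv_type == "DEL":
        if contains:
            terms.append(ablation)
        else:
            terms.append("feature_truncation")
            if (is_transcript and feature.is_coding and _overlap(
                    s, e, feature.cds_genomic_start, feature.cds_genomic_end)):
                terms.append("coding_sequence_variant")
    elif sv_type in ("DUP", "CNV"):
        terms.append(amplification if contains else "feature_elongation")
    elif sv_type == "INS":
        terms.append("feature_elongation")
    else:
        # unknown SV class: report the least specific applicable term
        terms.append("coding_sequence_variant"
                     if is_transcript and feature.is_coding
                     else "feature_truncation" if contains
                     else "feature_elongation")
    return terms
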
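"""Transcription-factor binding motif scoring.

A motif is a position weight matrix (PWM) of per-position nucleotide
probabilities.  The effect of an allele on a motif is summarised as the
change in a *relative* log-probability score:

    score(seq) = (sum_i log p_i(seq_i) - sum_i log p_i_min)
                 / (sum_i log p_i_max - sum_i log p_i_min)

so the consensus sequence scores 1, the anti-consensus 0, and every other
sequence falls in between.  Columns are pseudocounted (1e-2) when matrices
are loaded, so no probability is zero.  A motif position is flagged
"informative" when its column information content is at least 1 bit (of a
2-bit maximum), i.e. the column strongly prefers a subset of bases.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional

from .models import MotifFeature

__all__ = [
    "MotifImpact",
    "PSEUDOCOUNT",
    "INFORMATIVE_BITS",
    "parse_jaspar",
    "pseudocounted",
    "score_motif",
    "column_information_content",
    "motif_consequence",
]

PSEUDOCOUNT = 1e-2
INFORMATIVE_BITS = 1.0
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifImpact:
    """Effect of one variant allele on one motif placement."""

    motif_position: int          # 1-based, strand-aware position in motif
    ref_score: float
    alt_score: float
    informative: bool

    @property
    def delta(self) -> float:
        return self.alt_score - self.ref_score


def pseudocounted(columns: list[dict[str, float]],
                  pseudocount: float = PSEUDOCOUNT) -> list[dict[str, float]]:
    """Normalise count/frequency columns to probabilities with a pseudocount."""
    out = []
    for col in columns:
        total = sum(col.get(b, 0.0) for b in _BASES)
        if total <= 0:
            raise ValueError("PWM column with non-positive total")
        freqs = {b: col.get(b, 0.0) / total for b in _BASES}
        denom = 1.0 + 4 * pseudocount
        out.append({b: (freqs[b] + pseudocount) / denom for b in _BASES})
    return out


def parse_jaspar(path) -> dict[str, list[dict[str, float]]]:
    """Parse a JASPAR-style plain-text matrix file.

    Format: ``>matrix_id name`` header followed by four rows ``A [ n n ... ]``
    (brackets optional).  Returns matrix_id -> pseudocounted probability
    columns.
    """
    matrices: dict[str, list[dict[str, float]]] = {}
    current: Optional[str] = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal rows, current
        if current is None:
            return
        if set(rows) != set(_BASES):
            raise ValueError(f"matrix {current!r} missing base rows")
        width = {len(v) for v in rows.values()}
        if len(width) != 1:
            raise ValueError(f"matrix {current!r} has ragged rows")
        cols = [{b: rows[b][i] for b in _BASES} for i in range(width.pop())]
        matrices[current] = pseudocounted(cols)
        rows = {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current = line[1:].split()[0]
                continue
            m = re.match(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?$", line)
            if not m or current is None:
                raise ValueError(f"unparseable matrix line: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    return matrices


def score_motif(seq: str, pwm: list[dict[str, float]]) -> float:
    """Relative min-max normalised log-probability score in [0, 1].

    ``seq`` must match the PWM width; N scores as the column background
    (uniform expectation over the column's probabilities).
    """
    seq = seq.upper()
    if len(seq) != len(pwm):
        raise ValueError(
            f"sequence length {len(seq)} != PWM width {len(pwm)}")
    logp = 0.0
    logp_min = 0.0
    logp_max = 0.0
    for base, col in zip(seq, pwm):
        probs = [col[b] for b in _BASES]
        if base == "N":
            p = sum(probs) / 4.0
        elif base in col:
            p = col[base]
        else:
            raise ValueError(f"invalid base {base!r} in motif sequence")
        logp += math.log(p)
        logp_min += math.log(min(probs))
        logp_max += math.log(max(probs))
    if logp_max == logp_min:  # degenerate flat matrix
        return 1.0
    return (logp - logp_min) / (logp_max - logp_min)


def column_information_content(col: dict[str, float]) -> float:
    """Shannon information content of a PWM column, in bits (max 2)."""
    return 2.0 + sum(p * math.log2(p) for p in (col[b] for b in _BASES) if p > 0)


def motif_consequence(allele, motif: MotifFeature, genome) -> Optional[MotifImpact]:
    """Score the change an allele makes to a motif placement.

    Reference and mutant motif sequences are built in motif strand
    orientation.  SNVs (and length-preserving substitutions) report scores;
    indels overlap the motif but have no aligned score, so ``None`` is
    returned and the caller reports the consequence term alone.
    """
    v = allele.variant
    ref_seq = genome.sequence(motif.chrom, motif.start, motif.end).upper()
    if v.is_insertion_site or allele.ref == "-" or allele.allele == "-":
        return None
    if allele.length_change != 0:
        return None
    if "N" in allele.allele:
        return None
    # paste the substituted bases into the motif window (genome forward strand)
    s = max(v.start, motif.start)
    e = min(v.end, motif.end)
    if s > e:
        return None
    alt_seq = list(ref_seq)
    for gpos in range(s, e + 1):
        alt_seq[gpos - motif.start] = allele.allele[gpos - v.start]
    alt_seq = "".join(alt_seq)

    if motif.strand == -1:
        ref_m = reverse_complement(ref_seq)
        alt_m = reverse_complement(alt_seq)
        motif_pos = motif.end - e + 1
    else:
        ref_m, alt_m = ref_seq, alt_seq
        motif_pos = s - motif.start + 1
    ic = column_information_content(motif.pwm[motif_pos - 1])
    return MotifImpact(
        motif_position=motif_pos,
        ref_score=score_motif(ref_m, motif.pwm),
        alt_score=score_motif(alt_m, motif.pwm),
        informative=ic >= INFORMATIVE_BITS,
    )
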
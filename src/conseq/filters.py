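"""Result prioritisation and the field-operator-value filter language.

Prioritisation (``pick_one`` / ``per_gene``) keeps one result per variant
(or per gene), preferring the canonical transcript, then protein-coding
biotype, then the most severe consequence, with deterministic tie-breaks
(longest CDS, then smallest feature id).

The filter grammar is ``FIELD OP [VALUE]`` clauses joined with AND/OR,
where AND binds tighter than OR and there are no parentheses:

    Consequence is missense_variant
    AFR >0.1 AND EUR <0.05
    Gene in gene_list.txt AND Phenotype matches cancer

Operators: is/eq, ne, gt, lt, gte, lte (and their symbol forms), in
(comma-list or one-value-per-line file), matches (case-insensitive
substring), exists.  A field that does not resolve to an output column or
extras key evaluates false with a warning; numeric comparators evaluate
false on non-numeric values.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Optional

from .engine import OverlapResult
from .models import Transcript
from .output import result_to_row
from .registry import Registry, default_registry

__all__ = [
    "FilterSyntaxError", "FilterClause", "FilterExpression", "parse_filter",
    "apply_filter", "pick_one", "per_gene", "sort_key",
]

log = logging.getLogger(__name__)


class FilterSyntaxError(ValueError):
    pass


_OPS = {
    "is": "eq", "eq": "eq", "=": "eq", "==": "eq",
    "ne": "ne", "!=": "ne",
    "gt": "gt", ">": "gt", "lt": "lt", "<": "lt",
    "gte": "gte", ">=": "gte", "lte": "lte", "<=": "lte",
    "in": "in", "matches": "matches", "exists": "exists",
}
_SYM_OP_RE = re.compile(r"^(>=|<=|!=|==|>|<|=)(.+)$")


@dataclass(frozen=True)
class FilterClause:
    field: str
    op: str
    value: Optional[str] = None

    def evaluate(self, row: dict[str, str]) -> bool:
        if self.field not in row:
            log.warning("filter field %r not in output; clause is false",
                        self.field)
            return False
        raw = row[self.field]
        if self.op == "exists":
            return raw not in ("", "-", None)
        if raw in ("", "-", None):
            return False
        values = [v for part in str(raw).split(",") for v in part.split("&")]
        if self.op == "eq":
            return any(v.lower() == self.value.lower() for v in values)
        if self.op == "ne":
            return all(v.lower() != self.value.lower() for v in values)
        if self.op == "matches":
            return self.value.lower() in str(raw).lower()
        if self.op == "in":
            if os.path.exists(self.value):
                with open(self.value) as fh:
                    allowed = {ln.strip().lower() for ln in fh if ln.strip()}
            else:
                allowed = {v.strip().lower() for v in self.value.split(",")}
            return any(v.lower() in allowed for v in values)
        # numeric comparators
        try:
            x = float(str(raw).split(",")[0].split(":")[-1])
            y = float(self.value)
        except (TypeError, ValueError):
            return False
        return {"gt": x > y, "lt": x < y, "gte": x >= y, "lte": x <= y}[self.op]


@dataclass(frozen=True)
class FilterExpression:
    """OR-combined groups of AND-combined clauses (AND binds tighter)."""

    or_groups: tuple[tuple[FilterClause, ...], ...]

    def evaluate(self, row: dict[str, str]) -> bool:
        return any(all(c.evaluate(row) for c in group)
                   for group in self.or_groups)


def parse_filter(text: str) -> FilterExpression:
    """Parse a filter expression; syntax errors report the token position."""
    tokens = text.split()
    if not tokens:
        raise FilterSyntaxError("empty filter expression")
    groups: list[list[FilterClause]] = [[]]
    i = 0
    dangling = False
    while i < len(tokens):
        field = tokens[i]
        if field.upper() in ("AND", "OR"):
            raise FilterSyntaxError(
                f"expected field name at token {i + 1}, got {field!r}")
        i += 1
        if i >= len(tokens):
            raise FilterSyntaxError(
                f"missing operator after field {field!r} (token {i})")
        op_tok = tokens[i]
        sym = _SYM_OP_RE.match(op_tok)
        if sym and sym.group(1) in _OPS:
            op = _OPS[sym.group(1)]
            value = sym.group(2)
            i += 1
        else:
            if op_tok.lower() not in _OPS:
                raise FilterSyntaxError(
                    f"unknown operator {op_tok!r} at token {i + 1}")
            op = _OPS[op_tok.lower()]
            i += 1
            value = None
            if op != "exists":
                if i >= len(tokens):
                    raise FilterSyntaxError(
                        f"missing value for operator {op_tok!r} (token {i})")
                value = tokens[i]
                i += 1
        groups[-1].append(FilterClause(field=field, op=op, value=value))
        dangling = False
        if i < len(tokens):
            joiner = tokens[i].upper()
            if joiner == "AND":
                i += 1
                dangling = True
            elif joiner == "OR":
                groups.append([])
                i += 1
                dangling = True
            else:
                raise FilterSyntaxError(
                    f"expected AND/OR at token {i + 1}, got {tokens[i]!r}")
    if dangling or not groups[-1]:
        raise FilterSyntaxError("trailing AND/OR without a clause")
    return FilterExpression(tuple(tuple(g) for g in groups))


def apply_filter(expr: FilterExpression, results: list[OverlapResult],
                 registry: Optional[Registry] = None) -> list[OverlapResult]:
    registry = registry or default_registry()
    return [r for r in results if expr.evaluate(result_to_row(r, registry))]


# ---------------------------------------------------------------------------
# Prioritisation


def sort_key(res: OverlapResult, registry: Registry):
    feat = res.feature
    is_transcript = isinstance(feat, Transcript)
    canonical = is_transcript and bool(feat.flags.get("canonical"))
    protein_coding = is_transcript and feat.biotype == "protein_coding"
    min_rank = min(registry.rank(t) for t in res.terms)
    cds_len = feat.cds_length() if is_transcript and feat.is_coding else 0
    feature_id = feat.id if feat is not None else "~"
    return (not canonical, not protein_coding, min_rank, -cds_len, feature_id)


def pick_one(results: list[OverlapResult],
             registry: Optional[Registry] = None) -> OverlapResult:
    """The single highest-priority result for one variant allele set."""
    if not results:
        raise ValueError("pick_one requires at least one result")
    registry = registry or default_registry()
    return min(results, key=lambda r: sort_key(r, registry))


def per_gene(results: list[OverlapResult],
             registry: Optional[Registry] = None) -> list[OverlapResult]:
    """One result per overlapped gene (same ordering as pick_one);
    results without a gene (intergenic/regulatory) collapse to one."""
    registry = registry or default_registry()
    by_gene: dict[str, list[OverlapResult]] = {}
    for r in results:
        gene = (r.feature.gene_id if isinstance(r.feature, Transcript)
                else "")
        by_gene.setdefault(gene, []).append(r)
    picked = [pick_one(group, registry) for _, group in sorted(by_gene.items())]
    return picked
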
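"""Consequence term registry.

Variant consequences are named with Sequence Ontology (SO) classes.  The
registry is a small curated table shipped as package data: each entry carries
the SO accession, parent links (restricted to other registry members), a
unique severity rank (1 = most severe) and an impact class.  The parent links
preserve enough of the SO tree to support the "most specific term only" rule
and ontology-style filtering; the rank order follows the conventional
severity table used by variant annotation tools.

Users may supply their own registry file with the same columns to override
the shipped one (``load_registry(path)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "ConsequenceTerm",
    "Registry",
    "load_registry",
    "default_registry",
    "most_specific_terms",
    "most_severe",
]

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True)
class ConsequenceTerm:
    """One Sequence Ontology consequence class."""

    so_name: str
    so_accession: str
    parents: tuple[str, ...]
    rank: int
    impact: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.so_name


class Registry:
    """Immutable lookup table of consequence terms.

    Supports name lookup, severity comparison, and ancestor queries used by
    :func:`most_specific_terms`.
    """

    def __init__(self, terms: Iterable[ConsequenceTerm]):
        self._by_name: dict[str, ConsequenceTerm] = {}
        for t in terms:
            if t.so_name in self._by_name:
                raise ValueError(f"duplicate registry term {t.so_name!r}")
            self._by_name[t.so_name] = t
        ranks = [t.rank for t in self._by_name.values()]
        if len(set(ranks)) != len(ranks):
            raise ValueError("registry ranks are not unique")
        for t in self._by_name.values():
            for p in t.parents:
                if p not in self._by_name:
                    raise ValueError(
                        f"term {t.so_name!r} names unknown parent {p!r}"
                    )
        # reject cycles up front so ancestor walks terminate
        for t in self._by_name.values():
            self.ancestors(t.so_name)

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __getitem__(self, name: str) -> ConsequenceTerm:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown consequence term {name!r}") from None

    def rank(self, name: str) -> int:
        return self[name].rank

    def impact(self, name: str) -> str:
        return self[name].impact

    def ancestors(self, name: str) -> set[str]:
        """All transitive ancestors of ``name`` within the registry."""
        seen: set[str] = set()
        stack = list(self[name].parents)
        while stack:
            p = stack.pop()
            if p == name:
                raise ValueError(f"cycle in registry parent links at {name!r}")
            if p in seen:
                continue
            seen.add(p)
            stack.extend(self[p].parents)
        return seen


def load_registry(path=None) -> Registry:
    """Load a registry from ``path`` or the shipped default table."""
    if path is None:
        text = (
            resources.files("conseq.data")
            .joinpath("consequence_terms.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    terms = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"malformed registry line: {line!r}")
        name, acc, parents, rank, impact = fields
        if impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {impact!r} for {name!r}")
        terms.append(
            ConsequenceTerm(
                so_name=name,
                so_accession=acc,
                parents=() if parents == "-" else tuple(parents.split(",")),
                rank=int(rank),
                impact=impact,
            )
        )
    return Registry(terms)


_DEFAULT: Registry | None = None


def default_registry() -> Registry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_registry()
    return _DEFAULT


def most_specific_terms(terms: Iterable[str], registry: Registry) -> list[str]:
    """Drop every term that is an ancestor of another term in the set.

    Terms on distinct ontology branches are all retained.  Output preserves
    severity order (most severe first).  Unknown terms raise ``KeyError``.
    """
    names = list(dict.fromkeys(terms))
    covered: set[str] = set()
    for n in names:
        covered |= registry.ancestors(n)
    kept = [n for n in names if n not in covered]
    return sorted(kept, key=registry.rank)


def most_severe(terms: Iterable[str], registry: Registry) -> str:
    """The single lowest-rank (most severe) term of a non-empty collection."""
    names = list(terms)
    if not names:
        raise ValueError("most_severe requires a non-empty term collection")
    return min(names, key=registry.rank)
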
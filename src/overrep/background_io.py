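"""Annotation backgrounds, query sets and term-description tables.

The background format is deliberately loose plain text: one record per
line, the first whitespace-separated token is an item identifier (a gene,
a protein, anything), every further token on the line is an annotation
term attached to that item.  Items may carry zero terms; a line may repeat
an earlier item, in which case the annotation sets are unioned, so that
concatenating two background files is equivalent to merging them.  Lines
starting with ``#`` are comments.

Query sets are one identifier per line, same comment rule.

A minimal GAF 2.x reader covers the common case of Gene Ontology
annotation; it maps DB object IDs (column 2) to GO IDs (column 5), skips
``NOT``-qualified rows, and records each term's namespace from the aspect
code (P/F/C).

Identifier matching everywhere in this package is case-sensitive and does
no normalisation: silently case-folding mixed-source IDs corrupts data in
ways that are very hard to notice downstream.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger("overrep")

__all__ = [
    "InputError",
    "Background",
    "QuerySet",
    "TermInfo",
    "load_background",
    "load_query",
    "merge_backgrounds",
    "load_gaf",
    "write_background",
    "load_term_table",
    "write_term_table",
]

#: GAF aspect code -> Gene Ontology namespace.
GAF_ASPECTS = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class InputError(Exception):
    """Malformed or unusable input data (bad file, empty background, ...)."""


@dataclass(frozen=True)
class TermInfo:
    """Human-readable description of an annotation term.

    Parameters
    ----------
    term:
        The term identifier as it appears in backgrounds (e.g. ``GO:0003723``).
    name:
        Free-text description; may be empty when unknown.
    namespace:
        Category label such as a GO aspect; may be empty.
    """

    term: str
    name: str = ""
    namespace: str = ""


class Background:
    """An annotated item universe: the denominator of every enrichment test.

    Stores an ordered set of item identifiers and, per item, the set of
    annotation terms it carries.  Per-term carrier counts (``K`` in the
    contingency notation) and the total item count ``N`` are derived on
    construction and kept consistent by immutability.
    """

    __slots__ = ("_items", "_annotations", "_term_counts")

    def __init__(self, annotations: Mapping[str, Iterable[str]]):
        """Build a background from an (insertion-ordered) item -> terms map."""
        self._items: tuple[str, ...] = tuple(annotations)
        if len(self._items) != len(set(self._items)):
            raise ValueError("duplicate item identifiers in annotation map")
        self._annotations: dict[str, frozenset[str]] = {
            item: frozenset(terms) for item, terms in annotations.items()
        }
        counts = Counter(
            term for terms in self._annotations.values() for term in terms
        )
        self._term_counts: dict[str, int] = dict(counts)

    @property
    def items(self) -> tuple[str, ...]:
        """All item identifiers, in file/insertion order."""
        return self._items

    @property
    def annotations(self) -> Mapping[str, frozenset[str]]:
        """Item -> set of terms the item is annotated with."""
        return self._annotations

    @property
    def term_counts(self) -> Mapping[str, int]:
        """Term -> number of distinct items carrying it (``K``)."""
        return self._term_counts

    @property
    def size(self) -> int:
        """Total number of items (``N``)."""
        return len(self._items)

    def terms_of(self, item: str) -> frozenset[str]:
        return self._annotations[item]

    def carriers(self, term: str) -> list[str]:
        """Items annotated with *term*, in background order."""
        return [i for i in self._items if term in self._annotations[i]]

    def __len__(self) -> int:
        return self.size

    def __contains__(self, item: str) -> bool:
        return item in self._annotations

    def __iter__(self) -> Iterator[str]:
        return iter(self._items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Background):
            return NotImplemented
        return (
            self._items == other._items
            and self._annotations == other._annotations
        )

    def __hash__(self):  # pragma: no cover - mappings are unhashable by design
        raise TypeError("Background is not hashable")

    def __repr__(self) -> str:
        return (
            f"Background(N={self.size}, "
            f"terms={len(self._term_counts)})"
        )


@dataclass(frozen=True)
class QuerySet:
    """A named list of item identifiers to be tested against a background.

    May legitimately contain items absent from a given background; those
    are dropped (with a warning and a reported count) at analysis time, so
    the query size ``n`` counts only matched items.
    """

    name: str
    items: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.items) != len(set(self.items)):
            raise ValueError("duplicate items in query set")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[str]:
        return iter(self.items)


def _data_lines(path: str | os.PathLike, comment: str) -> Iterator[str]:
    try:
        handle = open(path, "r", encoding="utf-8")
    except FileNotFoundError as exc:
        raise InputError(f"input file not found: {path}") from exc
    with handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith(comment):
                continue
            yield stripped


def load_background(path: str | os.PathLike) -> Background:
    """Read a plain-text background file.

    Each non-comment line is whitespace-split; the first token is the item
    identifier, the rest are its annotation terms (duplicates on a line
    collapse).  Repeated item lines union their term sets.  Items with no
    terms still count toward ``N``.

    Raises
    ------
    InputError
        If the file is missing or contains no items.
    """
    annotations: dict[str, set[str]] = {}
    for line in _data_lines(path, "#"):
        tokens = line.split()
        item, terms = tokens[0], tokens[1:]
        annotations.setdefault(item, set()).update(terms)
    if not annotations:
        raise InputError(f"empty background: {path}")
    return Background(annotations)


def load_query(path: str | os.PathLike, name: str | None = None) -> QuerySet:
    """Read a query set (one identifier per line, ``#`` comments).

    Duplicates are removed keeping first occurrence; the set name defaults
    to the file's base name.

    Raises
    ------
    InputError
        If the file is missing or contains no identifiers.
    """
    seen: dict[str, None] = {}
    for line in _data_lines(path, "#"):
        # only the first token counts; trailing tokens on a query line are
        # almost certainly a user error, so be loud about them
        tokens = line.split()
        if len(tokens) > 1:
            logger.warning(
                "query line %r has extra tokens; using first token only", line
            )
        seen.setdefault(tokens[0])
    if not seen:
        raise InputError(f"empty query set: {path}")
    return QuerySet(name=name or os.path.basename(os.fspath(path)),
                    items=tuple(seen))


def merge_backgrounds(backgrounds: list[Background]) -> Background:
    """Union several backgrounds into one.

    The merged item universe is the union of all item sets (first-seen
    order); per-item annotation sets are unioned across inputs and term
    counts recomputed.  Merging is idempotent and order-independent in its
    resulting counts.
    """
    if not backgrounds:
        raise ValueError("merge_backgrounds: need at least one background")
    merged: dict[str, set[str]] = {}
    for bg in backgrounds:
        for item in bg.items:
            merged.setdefault(item, set()).update(bg.annotations[item])
    return Background(merged)


def load_gaf(path: str | os.PathLike) -> tuple[Background, dict[str, TermInfo]]:
    """Read a GAF 2.x annotation file into a background plus term table.

    Column 2 (DB object ID) becomes the item, column 5 (GO ID) the term;
    the aspect code in column 9 (P/F/C) supplies each term's namespace.
    Rows whose qualifier (column 4) contains ``NOT`` are excluded; rows
    with fewer than 15 tab-separated fields are skipped with a warning.
    """
    annotations: dict[str, set[str]] = {}
    term_info: dict[str, TermInfo] = {}
    for lineno, line in enumerate(_data_lines(path, "!"), start=1):
        fields = line.split("\t")
        if len(fields) < 15:
            logger.warning(
                "%s line %d: %d fields (GAF needs >= 15), skipped",
                path, lineno, len(fields),
            )
            continue
        qualifier = fields[3]
        if "NOT" in qualifier.split("|"):
            continue
        item, term, aspect = fields[1], fields[4], fields[8]
        annotations.setdefault(item, set()).add(term)
        if term not in term_info:
            term_info[term] = TermInfo(
                term=term, namespace=GAF_ASPECTS.get(aspect, aspect)
            )
    if not annotations:
        raise InputError(f"empty background: {path}")
    return Background(annotations), term_info


def write_background(background: Background, path: str | os.PathLike) -> None:
    """Write a background in the plain-text dialect read by `load_background`.

    Terms are written sorted for stable output; an item with no terms
    produces a line holding just the identifier.  Round-trip through
    `load_background` reproduces the background exactly.
    """
    with open(path, "w", encoding="utf-8") as handle:
        for item in background.items:
            terms = sorted(background.annotations[item])
            handle.write(" ".join([item, *terms]) + "\n")


def load_term_table(path: str | os.PathLike) -> dict[str, TermInfo]:
    """Read a 3-column TSV term table: term, namespace, name.

    The name column may contain tabs-free free text; missing trailing
    columns default to empty strings.  Duplicate term rows keep the first.
    """
    table: dict[str, TermInfo] = {}
    for line in _data_lines(path, "#"):
        fields = line.split("\t")
        term = fields[0]
        namespace = fields[1] if len(fields) > 1 else ""
        name = fields[2] if len(fields) > 2 else ""
        table.setdefault(term, TermInfo(term=term, name=name,
                                        namespace=namespace))
    return table


def write_term_table(table: Mapping[str, TermInfo],
                     path: str | os.PathLike) -> None:
    """Write a term table as 3-column TSV (term, namespace, name)."""
    with open(path, "w", encoding="utf-8") as handle:
        for term in sorted(table):
            info = table[term]
            handle.write(f"{info.term}\t{info.namespace}\t{info.name}\n")
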
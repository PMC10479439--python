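"""Synonym-group lexicon: the ground truth for equivalent natural-product names.

A :class:`SynonymGroup` collects every known name of one natural product —
a preferred common name (PT), a Latin binomial, and spelling variants.  The
:class:`Lexicon` holds disjoint groups and answers exact lookups on
normalized names.  Group disjointness is a hard invariant: equivalence sets
drive the "equivalent-match" retrieval mode and must be unambiguous.

On disk a lexicon is a header-bearing CSV with columns
``group_id, name, name_type`` where ``name_type`` is one of ``preferred``,
``latin_binomial`` or ``variant``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .textprep import normalize

__all__ = [
    "SynonymGroup",
    "Lexicon",
    "LexiconFormatError",
    "LexiconConflictError",
    "load_lexicon",
    "write_lexicon",
    "equivalents",
    "add_names",
]

NAME_TYPES = ("preferred", "latin_binomial", "variant")


class LexiconFormatError(ValueError):
    """Malformed lexicon file (missing columns, missing required name kinds)."""


class LexiconConflictError(ValueError):
    """The same normalized name is claimed by two distinct groups."""


@dataclass(frozen=True)
class SynonymGroup:
    group_id: str
    preferred_term: str
    latin_binomial: str
    variants: frozenset[str] = field(default_factory=frozenset)

    @property
    def names(self) -> frozenset[str]:
        """The group's full name set (PT, binomial, variants)."""
        return self.variants | {self.preferred_term, self.latin_binomial}

    @property
    def genus(self) -> str:
        """First token of the Latin binomial."""
        return self.latin_binomial.split(" ", 1)[0]


class Lexicon:
    """Immutable collection of disjoint synonym groups with an exact-name index."""

    def __init__(self, groups: Iterable[SynonymGroup]):
        self._groups: dict[str, SynonymGroup] = {}
        self._index: dict[str, str] = {}
        for g in groups:
            if g.group_id in self._groups:
                raise LexiconConflictError(f"duplicate group_id {g.group_id!r}")
            for name in g.names:
                owner = self._index.get(name)
                if owner is not None:
                    raise LexiconConflictError(
                        f"name {name!r} appears in groups {owner!r} and {g.group_id!r}"
                    )
                self._index[name] = g.group_id
            self._groups[g.group_id] = g

    def __len__(self) -> int:
        return len(self._groups)

    def __iter__(self) -> Iterator[SynonymGroup]:
        return iter(self._groups.values())

    def __contains__(self, name: str) -> bool:
        return normalize(name) in self._index

    @property
    def group_ids(self) -> list[str]:
        return list(self._groups)

    def group(self, group_id: str) -> SynonymGroup:
        return self._groups[group_id]

    def lookup(self, name: str) -> str | None:
        """Group id owning ``name`` (normalized first), or None."""
        return self._index.get(normalize(name))

    def names(self) -> set[str]:
        """Union of all group name sets."""
        return set(self._index)

    def genus_tokens(self) -> set[str]:
        return {g.genus for g in self}


def _build_group(group_id: str, rows: list[tuple[str, str]]) -> SynonymGroup:
    preferred = [n for n, t in rows if t == "preferred"]
    binomial = [n for n, t in rows if t == "latin_binomial"]
    variants = {n for n, t in rows if t == "variant"}
    if not preferred or not binomial:
        raise LexiconFormatError(
            f"group {group_id!r} needs at least one preferred and one "
            f"latin_binomial name"
        )
    return SynonymGroup(
        group_id=group_id,
        preferred_term=preferred[0],
        latin_binomial=binomial[0],
        variants=frozenset(variants | set(preferred[1:]) | set(binomial[1:])),
    )


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a ``group_id,name,name_type`` CSV into a :class:`Lexicon`.

    Names are normalized on load; duplicate ``(group_id, name)`` rows
    collapse silently.  A normalized name claimed by two groups raises
    :class:`LexiconConflictError` naming both.
    """
    by_group: dict[str, list[tuple[str, str]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"group_id", "name", "name_type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise LexiconFormatError(
                f"lexicon file {path} must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            ntype = row["name_type"].strip()
            if ntype not in NAME_TYPES:
                raise LexiconFormatError(
                    f"unknown name_type {ntype!r} (expected one of {NAME_TYPES})"
                )
            name = normalize(row["name"])
            if not name:
                continue
            entry = (name, ntype)
            rows = by_group.setdefault(row["group_id"].strip(), [])
            if entry not in rows:
                rows.append(entry)
    return Lexicon(_build_group(gid, rows) for gid, rows in by_group.items())


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write the CSV form read by :func:`load_lexicon` (round-trip safe)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group_id", "name", "name_type"])
        for g in lex:
            writer.writerow([g.group_id, g.preferred_term, "preferred"])
            writer.writerow([g.group_id, g.latin_binomial, "latin_binomial"])
            for v in sorted(g.variants):
                writer.writerow([g.group_id, v, "variant"])


def equivalents(lex: Lexicon, name: str) -> set[str]:
    """Full name set of the group owning ``name``, or the empty set."""
    gid = lex.lookup(name)
    if gid is None:
        return set()
    return set(lex.group(gid).names)


def add_names(lex: Lexicon, group_id: str, names: Iterable[str]) -> Lexicon:
    """Return a new lexicon with ``names`` added to ``group_id`` as variants.

    Already-present names are no-ops; a name owned by a different group
    raises :class:`LexiconConflictError`.
    """
    target = lex.group(group_id)  # KeyError if unknown
    additions: set[str] = set()
    for raw in names:
        norm = normalize(raw)
        if not norm:
            continue
        owner = lex.lookup(norm)
        if owner is not None and owner != group_id:
            raise LexiconConflictError(
                f"name {norm!r} already belongs to group {owner!r}, "
                f"cannot add to {group_id!r}"
            )
        if owner is None:
            additions.add(norm)
    if not additions:
        return lex
    updated = SynonymGroup(
        group_id=target.group_id,
        preferred_term=target.preferred_term,
        latin_binomial=target.latin_binomial,
        variants=target.variants | additions,
    )
    return Lexicon(updated if g.group_id == group_id else g for g in lex)
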
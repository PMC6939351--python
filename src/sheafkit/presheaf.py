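"""Set-valued presheaves as relational section tables.

A presheaf F on a finite space attaches to every open set U a *section table*:
a set of rows, each row a total assignment of a value to every point of U.
Inclusions U ⊆ V of opens are carried to *restriction maps* F(V) → F(U); for
tabular presheaves these are column projections, but the data model allows
arbitrary explicitly-stored maps so that the functor laws (identity and
composition) can actually be checked rather than assumed.

Values are opaque strings compared by equality; there are no typed domains.
F(∅) is fixed to the terminal table (one empty row) for every presheaf built
here, which makes the sheaf condition over the empty cover automatic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    InclusionError,
    MalformedTableError,
    NotOpenError,
    UnknownSectionError,
)
from .topology import EMPTY_OPEN, FiniteSpace, OpenSet, _sort_key

logger = logging.getLogger("sheafkit")

__all__ = [
    "Section",
    "EMPTY_SECTION",
    "SectionTable",
    "Presheaf",
    "tabular_presheaf",
    "restrict",
    "project",
    "check_functoriality",
    "FunctorialityReport",
]


@dataclass(frozen=True)
class Section:
    """One row: a total assignment point label → value over some open set."""

    items: tuple

    @classmethod
    def make(cls, assignment: Mapping[str, str]) -> "Section":
        return cls(tuple(sorted((str(k), str(v)) for k, v in assignment.items())))

    @property
    def domain(self) -> OpenSet:
        return OpenSet(k for k, _ in self.items)

    def as_dict(self) -> dict:
        return dict(self.items)

    def __getitem__(self, point: str) -> str:
        for k, v in self.items:
            if k == point:
                return v
        raise KeyError(point)

    def project(self, points: Iterable[str]) -> "Section":
        """Column projection onto a subset of this section's points."""
        pts = OpenSet(points)
        if not pts <= self.domain:
            raise InclusionError(
                f"cannot project section over {{{self.domain.label}}} "
                f"onto {{{pts.label}}}: not a subset"
            )
        return Section(tuple((k, v) for k, v in self.items if k in pts))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ",".join(f"{k}↦{v}" for k, v in self.items)
        return f"Section({inner or '∅'})"


EMPTY_SECTION = Section(())


@dataclass(frozen=True)
class SectionTable:
    """The set of sections attached to one open set (set semantics, no duplicates)."""

    open: OpenSet
    sections: frozenset

    def __post_init__(self):
        object.__setattr__(self, "open", OpenSet(self.open))
        object.__setattr__(self, "sections", frozenset(self.sections))
        for s in self.sections:
            if s.domain != self.open:
                raise MalformedTableError(
                    f"row {s!r} has domain {{{s.domain.label}}} but the table "
                    f"is over {{{self.open.label}}}"
                )

    @classmethod
    def from_rows(cls, points: Iterable[str], rows: Iterable[Mapping[str, str]]) -> "SectionTable":
        return cls(OpenSet(points), frozenset(Section.make(r) for r in rows))

    @classmethod
    def empty(cls, points: Iterable[str]) -> "SectionTable":
        return cls(OpenSet(points), frozenset())

    @classmethod
    def terminal(cls) -> "SectionTable":
        """The one-row table over the empty open set."""
        return cls(EMPTY_OPEN, frozenset([EMPTY_SECTION]))

    def rows_sorted(self) -> list:
        cached = self.__dict__.get("_rows_sorted")
        if cached is None:
            cols = sorted(self.open)
            cached = sorted(self.sections, key=lambda s: tuple(s[c] for c in cols))
            object.__setattr__(self, "_rows_sorted", cached)
        return cached

    def to_frame(self) -> pd.DataFrame:
        """Canonical pandas view: sorted columns, rows in canonical order."""
        cols = sorted(self.open)
        data = [[s[c] for c in cols] for s in self.rows_sorted()]
        return pd.DataFrame(data, columns=cols, dtype=str)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SectionTable":
        rows = [dict(zip(df.columns, rec)) for rec in df.astype(str).itertuples(index=False)]
        if len(rows) != len({Section.make(r) for r in rows}):
            logger.warning("duplicate rows merged (set semantics)")
        return cls.from_rows(df.columns, rows)

    def __len__(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.rows_sorted())

    def __contains__(self, s: Section) -> bool:
        return s in self.sections


def project(table: SectionTable, U: Iterable[str]) -> SectionTable:
    """Project a table onto a subset of its attributes, merging duplicate rows."""
    U = OpenSet(U)
    if not U <= table.open:
        raise InclusionError(
            f"{{{U.label}}} is not a subset of the table's open {{{table.open.label}}}"
        )
    return SectionTable(U, frozenset(s.project(U) for s in table.sections))


class Presheaf:
    """A finite space, a table per open, and explicit restriction maps per inclusion.

    ``tables`` maps each OpenSet of the space to its SectionTable;
    ``restrictions`` maps each inclusion pair ``(V, U)`` with U ⊆ V to a dict
    sending each section of F(V) to a section over U.
    """

    def __init__(self, space: FiniteSpace, tables: Mapping[OpenSet, SectionTable],
                 restrictions: Mapping[tuple, Mapping[Section, Section]]):
        self.space = space
        self.tables = {OpenSet(k): v for k, v in tables.items()}
        self.restrictions = {
            (OpenSet(v), OpenSet(u)): dict(m) for (v, u), m in restrictions.items()
        }
        for U in space.opens:
            if U not in self.tables:
                raise NotOpenError(f"no table supplied for open {{{U.label}}}")
            if self.tables[U].open != U:
                raise MalformedTableError(
                    f"table keyed by {{{U.label}}} is over {{{self.tables[U].open.label}}}"
                )
        for k in self.tables:
            if k not in space.opens:
                raise NotOpenError(f"table key {{{k.label}}} is not open in the space")

    def table(self, U: Iterable[str]) -> SectionTable:
        U = OpenSet(U)
        try:
            return self.tables[U]
        except KeyError:
            raise NotOpenError(f"{{{U.label}}} is not open in this space") from None

    def sections(self, U: Iterable[str]) -> frozenset:
        return self.table(U).sections

    def restrict(self, V: Iterable[str], U: Iterable[str], s: Section) -> Section:
        V, U = OpenSet(V), OpenSet(U)
        if not U <= V:
            raise InclusionError(
                f"{{{U.label}}} is not included in {{{V.label}}}"
            )
        if s not in self.table(V):
            raise UnknownSectionError(f"{s!r} is not a section over {{{V.label}}}")
        return self.restrictions[(V, U)][s]

    def inclusion_pairs(self) -> list:
        """All (V, U) with U ⊆ V, canonically ordered."""
        out = []
        for V in self.space.opens_sorted():
            for U in self.space.opens_sorted():
                if U <= V:
                    out.append((V, U))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Presheaf):
            return NotImplemented
        return (
            self.space == other.space
            and self.tables == other.tables
            and self.restrictions == other.restrictions
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = {U.label or "∅": len(t) for U, t in sorted(
            self.tables.items(), key=lambda kv: _sort_key(kv[0]))}
        return f"Presheaf({sizes})"


def tabular_presheaf(space: FiniteSpace, generators: Mapping) -> Presheaf:
    """Build the presheaf generated by tables attached to some opens.

    Every open U contained in at least one generator open G receives the union
    of the projections of those generator tables onto U; opens not under any
    generator get the empty table (gaps in knowledge, to be filled by
    sheaving).  F(∅) is always the terminal table.  All restriction maps are
    column projections.
    """
    gens = {}
    for key, tab in generators.items():
        G = OpenSet(key)
        if G not in space.opens:
            raise NotOpenError(f"generator key {{{G.label}}} is not open in the space")
        if not isinstance(tab, SectionTable):
            tab = SectionTable.from_rows(G, tab)
        if tab.open != G:
            raise MalformedTableError(
                f"generator table over {{{tab.open.label}}} attached to {{{G.label}}}"
            )
        if G in gens:
            gens[G] = SectionTable(G, gens[G].sections | tab.sections)
        else:
            gens[G] = tab

    tables = {}
    for U in space.opens:
        if U == EMPTY_OPEN:
            tables[U] = SectionTable.terminal()
            continue
        secs = set()
        for G, tab in gens.items():
            if U <= G:
                secs |= project(tab, U).sections
        tables[U] = SectionTable(U, frozenset(secs))

    restrictions = {}
    for V in space.opens:
        for U in space.opens:
            if U <= V:
                restrictions[(V, U)] = {s: s.project(U) for s in tables[V].sections}
    return Presheaf(space, tables, restrictions)


def restrict(presheaf: Presheaf, V: Iterable[str], U: Iterable[str], s: Section) -> Section:
    return presheaf.restrict(V, U, s)


@dataclass
class FunctorialityReport:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def check_functoriality(presheaf: Presheaf, max_violations: int = 10) -> FunctorialityReport:
    """Check the presheaf functor laws over all inclusion chains.

    Verifies, for every inclusion U ⊆ V: the restriction map is defined on all
    of F(V) and lands inside F(U); restriction along V ⊆ V is the identity;
    and for every chain U ⊆ V ⊆ W, res_{W→U} = res_{V→U} ∘ res_{W→V}.
    Violations are returned as data, not raised.
    """
    violations = []

    def note(msg):
        if len(violations) < max_violations:
            violations.append(msg)

    opens = presheaf.space.opens_sorted()
    for V in opens:
        for U in opens:
            if not U <= V:
                continue
            rmap = presheaf.restrictions.get((V, U))
            if rmap is None:
                note(f"no restriction map for {{{V.label}}} ⊇ {{{U.label}}}")
                continue
            for s in presheaf.table(V).sections:
                if s not in rmap:
                    note(f"restriction {{{V.label}}}→{{{U.label}}} undefined at {s!r}")
                elif rmap[s] not in presheaf.table(U):
                    note(
                        f"restriction {{{V.label}}}→{{{U.label}}} sends {s!r} "
                        f"outside F({{{U.label}}})"
                    )
            if U == V:
                for s in presheaf.table(V).sections:
                    if rmap.get(s) != s:
                        note(f"identity restriction at {{{V.label}}} moves {s!r}")
    for W in opens:
        for V in opens:
            if not V <= W:
                continue
            for U in opens:
                if not U <= V:
                    continue
                for s in presheaf.table(W).sections:
                    try:
                        direct = presheaf.restrictions[(W, U)][s]
                        via = presheaf.restrictions[(V, U)][
                            presheaf.restrictions[(W, V)][s]
                        ]
                    except KeyError:
                        continue  # already reported as undefined
                    if direct != via:
                        note(
                            f"composition law fails on chain {{{U.label}}} ⊆ "
                            f"{{{V.label}}} ⊆ {{{W.label}}} at {s!r}"
                        )
    return FunctorialityReport(ok=not violations, violations=violations)
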
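"""Natural joins, pullbacks, matching families and the sheaf condition.

The sheaf condition says that data attached to the members of an open cover
which pairwise agree on overlaps (a *matching family*) glue to exactly one
section over the covered set: at most one (separatedness) and at least one
(gluability).  On the relational reading, gluing is the natural join and a
pullback of two tables over a shared attribute set is the constrained product
of their rows.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import CoverError, InclusionError, NotOpenError
from .presheaf import Presheaf, Section, SectionTable
from .topology import EMPTY_OPEN, FiniteSpace, OpenSet, _sort_key

__all__ = [
    "natural_join",
    "pullback",
    "PullbackResult",
    "MatchingFamily",
    "matching_families",
    "amalgamations",
    "irredundant_covers",
    "is_sheaf",
    "SheafReport",
]


def natural_join(t1: SectionTable, t2: SectionTable) -> SectionTable:
    """All merges of a row of t1 with a row of t2 that agree on shared points.

    Disjoint attribute sets give the full Cartesian product; identical
    attribute sets give the intersection of the row sets.
    """
    shared = OpenSet(t1.open & t2.open)
    out_open = OpenSet(t1.open | t2.open)
    index = defaultdict(list)
    for s2 in t2.sections:
        index[s2.project(shared)].append(s2)
    rows = set()
    for s1 in t1.sections:
        for s2 in index.get(s1.project(shared), ()):
            merged = dict(s1.items)
            merged.update(s2.items)
            rows.add(Section.make(merged))
    return SectionTable(out_open, frozenset(rows))


class PullbackResult(NamedTuple):
    apex: SectionTable
    proj1: dict  # apex row -> originating row of t1
    proj2: dict  # apex row -> originating row of t2


def pullback(t1: SectionTable, t2: SectionTable, over: Iterable[str]) -> PullbackResult:
    """The constrained product of two tables over a common attribute set.

    Rows of the apex are merges of row pairs whose projections onto ``over``
    (and onto the rest of any attribute overlap, which a single merged record
    necessarily respects) coincide.  ``proj1``/``proj2`` send each apex row
    back to its originating rows, and the square over ``over`` commutes.
    """
    over = OpenSet(over)
    shared = OpenSet(t1.open & t2.open)
    if not over <= shared:
        raise InclusionError(
            f"pullback base {{{over.label}}} is not contained in the attribute "
            f"overlap {{{shared.label}}}"
        )
    apex = natural_join(t1, t2)
    proj1 = {r: r.project(t1.open) for r in apex.sections}
    proj2 = {r: r.project(t2.open) for r in apex.sections}
    return PullbackResult(apex, proj1, proj2)


@dataclass(frozen=True)
class MatchingFamily:
    """One section per cover element, pairwise agreeing on overlaps."""

    target: OpenSet
    cover: frozenset
    choice: tuple  # sorted tuple of (OpenSet, Section)

    @classmethod
    def make(cls, target, cover, choice: dict) -> "MatchingFamily":
        items = tuple(sorted(choice.items(), key=lambda kv: _sort_key(kv[0])))
        return cls(OpenSet(target), frozenset(cover), items)

    def section_at(self, V: OpenSet) -> Section:
        return dict(self.choice)[V]


def _cover_elements(F: Presheaf, U: OpenSet, cover) -> list:
    elems = []
    for V in cover:
        V = OpenSet(V)
        if V not in F.space.opens:
            raise NotOpenError(f"cover element {{{V.label}}} is not open")
        elems.append(V)
    union = OpenSet(frozenset().union(*elems) if elems else frozenset())
    if union != U:
        raise CoverError(
            f"cover unions to {{{union.label}}}, not to the target {{{U.label}}}"
        )
    return sorted(set(elems), key=_sort_key, reverse=True)


def matching_families(F: Presheaf, U: Iterable[str], cover) -> list:
    """Enumerate all matching families for the given cover of U."""
    U = OpenSet(U)
    if U not in F.space.opens:
        raise NotOpenError(f"{{{U.label}}} is not open")
    elems = _cover_elements(F, U, cover)
    out = []
    choice = {}
    index = {}  # (V, overlap) -> {restriction: [sections]} for hash-join pruning

    def overlap_index(V: OpenSet, I: OpenSet) -> dict:
        key = (V, I)
        if key not in index:
            d = {}
            for s in F.table(V).rows_sorted():
                d.setdefault(F.restrict(V, I, s), []).append(s)
            index[key] = d
        return index[key]

    def rec(i: int):
        if i == len(elems):
            out.append(MatchingFamily.make(U, elems, choice))
            return
        V = elems[i]
        constraints = [
            (OpenSet(V & W), F.restrict(W, OpenSet(V & W), t))
            for W, t in choice.items()
        ]
        if constraints:
            I, want = max(constraints, key=lambda c: len(c[0]))
            candidates = overlap_index(V, I).get(want, [])
            constraints = [c for c in constraints if c[0] != I or c[1] != want]
        else:
            candidates = F.table(V).rows_sorted()
        for s in candidates:
            if any(F.restrict(V, I, s) != want for I, want in constraints):
                continue
            choice[V] = s
            rec(i + 1)
            del choice[V]

    rec(0)
    return out


def amalgamations(F: Presheaf, family: MatchingFamily) -> list:
    """Sections over the family's target restricting to every chosen section."""
    out = []
    for s in F.table(family.target).rows_sorted():
        if all(F.restrict(family.target, V, s) == t for V, t in family.choice):
            out.append(s)
    return out


def irredundant_covers(space: FiniteSpace, U: OpenSet):
    """Yield every cover of U by non-empty opens none of which contains another.

    Irredundant covers suffice for the sheaf condition on a finite space:
    dropping an element contained in another never changes the matching
    families' glue.  The empty open set never appears (it is redundant in any
    cover of a non-empty U), and U = ∅ is covered only by the empty cover.
    """
    if U == EMPTY_OPEN:
        yield frozenset()
        return
    cands = sorted(
        (O for O in space.opens if O and O <= U),
        key=_sort_key,
        reverse=True,
    )
    suffix_union = [frozenset()] * (len(cands) + 1)
    for i in range(len(cands) - 1, -1, -1):
        suffix_union[i] = suffix_union[i + 1] | cands[i]
    chosen = []
    covered = [frozenset()]

    def rec(i: int):
        if not U <= (covered[-1] | suffix_union[i]):
            return
        if i == len(cands):
            if covered[-1] == U:
                yield frozenset(chosen)
            return
        yield from rec(i + 1)  # skip cands[i]
        c = cands[i]
        if all(not (c <= d or d <= c) for d in chosen):
            chosen.append(c)
            covered.append(covered[-1] | c)
            yield from rec(i + 1)
            chosen.pop()
            covered.pop()

    yield from rec(0)


@dataclass
class SheafReport:
    separated: bool
    gluable: bool
    witnesses: list = field(default_factory=list)
    n_witnesses: int = 0

    @property
    def is_sheaf(self) -> bool:
        return self.separated and self.gluable

    def __bool__(self) -> bool:
        return self.is_sheaf


def is_sheaf(F: Presheaf, max_witnesses: int = 10) -> SheafReport:
    """Check separatedness and gluability over every irredundant cover.

    For each open U and each irredundant cover of U, every matching family
    must have exactly one amalgamation in F(U).  Failures are reported as
    witnesses (capped at ``max_witnesses``, with the total count kept).
    """
    separated = True
    gluable = True
    witnesses = []
    n_witnesses = 0

    def note(kind, U, cover, family, sections):
        nonlocal n_witnesses
        n_witnesses += 1
        if len(witnesses) < max_witnesses:
            witnesses.append(
                {
                    "kind": kind,
                    "open": U.label,
                    "cover": sorted(V.label for V in cover),
                    "family": family,
                    "sections": sections,
                }
            )

    for U in F.space.opens_sorted():
        for cover in irredundant_covers(F.space, U):
            # Precompute each candidate amalgamation's restriction signature.
            elems = sorted(cover, key=_sort_key)
            sig = defaultdict(list)
            for s in F.table(U).rows_sorted():
                key = tuple(F.restrict(U, V, s) for V in elems)
                sig[key].append(s)
            for fam in matching_families(F, U, cover):
                key = tuple(fam.section_at(V) for V in elems)
                glues = sig.get(key, [])
                if len(glues) == 0:
                    gluable = False
                    note("not-gluable", U, cover, fam, [])
                elif len(glues) > 1:
                    separated = False
                    note("not-separated", U, cover, fam, glues)
    return SheafReport(separated, gluable, witnesses, n_witnesses)
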
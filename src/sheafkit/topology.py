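"""Finite topological spaces.

A finite topology is stored extensionally: the full set of open sets, each an
immutable set of point labels.  On finite spaces a topology is the same thing
as an Alexandrov topology, so every point has a *minimal open neighbourhood*
(the intersection of all opens containing it) and the space is equivalently
described by its *specialization preorder*

    x <= y  iff  every open set containing x also contains y.

Both constructions are provided here, together with the canonical cover of an
open set by the minimal opens of its points, which is what sheafification
glues over.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable

from .errors import NotOpenError, TopologyError, UnknownPointError

__all__ = [
    "OpenSet",
    "FiniteSpace",
    "PreorderRelation",
    "make_space",
    "standard_topology",
    "minimal_open",
    "specialization_preorder",
    "canonical_cover",
]


class OpenSet(frozenset):
    """An immutable set of point labels; the canonical form sorts labels."""

    def __new__(cls, points: Iterable[str] = ()) -> "OpenSet":
        return super().__new__(cls, (str(p) for p in points))

    @property
    def label(self) -> str:
        """Canonical serialized form: labels sorted lexicographically, comma-joined."""
        return ",".join(sorted(self))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ",".join(sorted(self)) if self else "∅"
        return f"OpenSet({{{inner}}})"


EMPTY_OPEN = OpenSet()


def _sort_key(o: OpenSet) -> tuple:
    return (len(o), o.label)


@dataclass(frozen=True)
class FiniteSpace:
    """A validated finite topological space (construct via :func:`make_space`)."""

    points: frozenset
    opens: frozenset

    def is_open(self, points: Iterable[str]) -> bool:
        return OpenSet(points) in self.opens

    def opens_sorted(self) -> list:
        """Opens in canonical order: by size, then by serialized label."""
        return sorted(self.opens, key=_sort_key)

    @property
    def full(self) -> OpenSet:
        return OpenSet(self.points)

    def minimal_open(self, x: str) -> OpenSet:
        return minimal_open(self, x)

    def specialization_preorder(self) -> "PreorderRelation":
        return specialization_preorder(self)

    def canonical_cover(self, U: OpenSet) -> frozenset:
        return canonical_cover(self, U)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FiniteSpace(points={{{','.join(sorted(self.points))}}}, "
            f"n_opens={len(self.opens)})"
        )


@dataclass(frozen=True)
class PreorderRelation:
    """A reflexive transitive relation on point labels; pairs (x, y) read x <= y."""

    pairs: frozenset

    def holds(self, x: str, y: str) -> bool:
        return (x, y) in self.pairs

    def nonreflexive(self) -> frozenset:
        return frozenset((x, y) for (x, y) in self.pairs if x != y)


def make_space(points: Iterable[str], opens: Iterable[Iterable[str]]) -> FiniteSpace:
    """Validate and build a finite topological space.

    Raises :class:`TopologyError` naming the first violated axiom together
    with the witnessing sets.
    """
    pts = frozenset(str(p) for p in points)
    ops = frozenset(OpenSet(o) for o in opens)

    for o in sorted(ops, key=_sort_key):
        if not o <= pts:
            stray = sorted(o - pts)
            raise TopologyError(
                f"open set {{{o.label}}} is not a subset of the point set: "
                f"unknown points {stray}"
            )
    if EMPTY_OPEN not in ops:
        raise TopologyError("the empty set is not among the opens")
    if OpenSet(pts) not in ops:
        raise TopologyError(
            f"the full point set {{{OpenSet(pts).label}}} is not among the opens"
        )
    # Pairwise closure suffices on a finite family.
    oplist = sorted(ops, key=_sort_key)
    for a in oplist:
        for b in oplist:
            u = OpenSet(a | b)
            if u not in ops:
                raise TopologyError(
                    f"not closed under union: {{{a.label}}} ∪ {{{b.label}}} "
                    f"= {{{u.label}}} is missing"
                )
            i = OpenSet(a & b)
            if i not in ops:
                raise TopologyError(
                    f"not closed under intersection: {{{a.label}}} ∩ {{{b.label}}} "
                    f"= {{{i.label}}} is missing"
                )
    return FiniteSpace(points=pts, opens=ops)


def standard_topology(points: Iterable[str], kind: str) -> FiniteSpace:
    """The discrete (all subsets) or indiscrete ({emptyset, D}) topology on *points*."""
    pts = sorted({str(p) for p in points})
    if not pts:
        raise ValueError("point set must be non-empty")
    if kind == "discrete":
        ops = [OpenSet(c) for r in range(len(pts) + 1) for c in combinations(pts, r)]
    elif kind == "indiscrete":
        ops = [EMPTY_OPEN, OpenSet(pts)]
    else:
        raise ValueError(f"kind must be 'discrete' or 'indiscrete', got {kind!r}")
    return FiniteSpace(points=frozenset(pts), opens=frozenset(ops))


def minimal_open(space: FiniteSpace, x: str) -> OpenSet:
    """The smallest open set containing *x*: the intersection of all opens containing it."""
    if x not in space.points:
        raise UnknownPointError(f"point {x!r} is not in the space")
    acc = set(space.points)
    for o in space.opens:
        if x in o:
            acc &= o
    return OpenSet(acc)


def specialization_preorder(space: FiniteSpace) -> PreorderRelation:
    """x <= y iff every open containing x also contains y (iff y in minimal_open(x))."""
    pairs = set()
    for x in space.points:
        mx = minimal_open(space, x)
        for y in mx:
            pairs.add((x, y))
    return PreorderRelation(pairs=frozenset(pairs))


def canonical_cover(space: FiniteSpace, U: Iterable[str]) -> frozenset:
    """The cover of open U by the minimal open neighbourhoods of its points."""
    U = OpenSet(U)
    if U not in space.opens:
        raise NotOpenError(f"{{{U.label}}} is not open in this space")
    return frozenset(minimal_open(space, x) for x in U)


def powerset(items: Iterable) -> Iterable[tuple]:
    s = sorted(items)
    return chain.from_iterable(combinations(s, r) for r in range(len(s) + 1))
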
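"""Sheafification: complete a presheaf to its nearest sheaf.

On a finite space every point x has a minimal open neighbourhood m(x), and the
stalk of a presheaf F at x is simply F(m(x)).  The sheafification therefore
needs no two-step plus construction: the completed sheaf is

    F⁺(U) = { compatible families (s_x ∈ F(m(x)))_{x ∈ U} },

where compatibility means that whenever m(y) ⊆ m(x) the germ chosen at x
restricts to the germ chosen at y.  Because sections assign values to points,
each compatible family merges into a single record over U (the value at p is
the germ at p evaluated at p), which is exactly the natural-join reading of
gluing.  Restrictions of F⁺ are column projections, and the unit map sends a
section of F(U) to the record of its own germs.

The result is verified to satisfy the sheaf condition before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

from .errors import PresheafError, SizeError
from .presheaf import (
    EMPTY_SECTION,
    Presheaf,
    Section,
    SectionTable,
    check_functoriality,
)
from .sheafcheck import is_sheaf
from .topology import EMPTY_OPEN, OpenSet, _sort_key, minimal_open

__all__ = [
    "SheafificationResult",
    "Diagnostics",
    "sheafify",
    "check_idempotence",
    "check_universal_property",
    "unit_morphism",
    "inclusion_morphism",
    "terminal_sheaf",
]


@dataclass(frozen=True)
class Diagnostics:
    """Per-open bookkeeping: completion rows added, input rows merged by the unit."""

    rows_added: int
    rows_merged: int


@dataclass
class SheafificationResult:
    input: Presheaf
    sheaf: Presheaf
    unit: dict  # OpenSet -> {Section of F(U) -> Section of F⁺(U)}
    diagnostics: dict  # OpenSet -> Diagnostics


def _require_well_formed(F: Presheaf) -> None:
    report = check_functoriality(F)
    if not report.ok:
        raise PresheafError(
            "input presheaf is not functorial: " + "; ".join(report.violations[:3])
        )
    if len(F.sections(EMPTY_OPEN)) != 1:
        raise PresheafError(
            f"F(∅) must be terminal (one empty section), found "
            f"{len(F.sections(EMPTY_OPEN))} sections"
        )


def _germ_families(F: Presheaf, mins: list) -> list:
    """All compatible choices of one section per minimal open (sorted big-first).

    Compatibility is forced along inclusions; for merely overlapping minimal
    opens, agreement on the (open) overlap is an implied consequence used
    here as eager pruning, with a hash index on overlap restrictions so that
    large tables join in near-linear time.
    """
    families = []
    assign = {}
    index = {}  # (m, overlap) -> {restriction: [sections]}

    def overlap_index(m: OpenSet, I: OpenSet) -> dict:
        key = (m, I)
        if key not in index:
            d = {}
            for s in F.table(m).rows_sorted():
                d.setdefault(F.restrict(m, I, s), []).append(s)
            index[key] = d
        return index[key]

    def rec(i: int):
        if i == len(mins):
            families.append(dict(assign))
            return
        m = mins[i]
        forced = None
        constraints = []  # (overlap, required restriction)
        for m2 in mins[:i]:
            if m <= m2:
                v = F.restrict(m2, m, assign[m2])
                if forced is not None and forced != v:
                    return
                forced = v
            else:
                I = OpenSet(m & m2)
                constraints.append((I, F.restrict(m2, I, assign[m2])))
        if forced is not None:
            candidates = [forced] if forced in F.table(m) else []
        elif constraints:
            I, want = constraints[0]
            candidates = overlap_index(m, I).get(want, [])
            constraints = constraints[1:]
        else:
            candidates = F.table(m).rows_sorted()
        for s in candidates:
            if any(F.restrict(m, I, s) != want for I, want in constraints):
                continue
            assign[m] = s
            rec(i + 1)
            del assign[m]

    rec(0)
    return families


def sheafify(F: Presheaf) -> SheafificationResult:
    """Construct the nearest sheaf F⁺ from F, with the unit map and diagnostics.

    ``diagnostics[U].rows_added`` counts sections of F⁺(U) not hit by the unit
    (knowledge inferred by gluing); ``rows_merged`` counts input sections of
    F(U) identified by the unit with another input section.
    """
    _require_well_formed(F)
    space = F.space
    mopen = {x: minimal_open(space, x) for x in space.points}

    plus_tables = {}
    unit = {}
    diagnostics = {}
    for U in space.opens_sorted():
        mins = sorted({mopen[x] for x in U}, key=_sort_key, reverse=True)
        records = set()
        for fam in _germ_families(F, mins):
            rec = Section.make({p: fam[mopen[p]][p] for p in U})
            if rec in records:
                raise PresheafError(
                    f"distinct germ families over {{{U.label}}} collapse to the "
                    "same record; sections cannot be serialized as merged rows"
                )
            records.add(rec)
        plus_tables[U] = SectionTable(U, frozenset(records))

        unit_U = {}
        for s in F.table(U).sections:
            img = Section.make({p: F.restrict(U, mopen[p], s)[p] for p in U})
            assert img in records, "unit image escaped F⁺ (functoriality broken)"
            unit_U[s] = img
        unit[U] = unit_U
        image = set(unit_U.values())
        diagnostics[U] = Diagnostics(
            rows_added=len(records) - len(image),
            rows_merged=len(F.table(U)) - len(image),
        )

    restrictions = {}
    for V in space.opens:
        for U in space.opens:
            if U <= V:
                restrictions[(V, U)] = {
                    s: s.project(U) for s in plus_tables[V].sections
                }
    sheaf = Presheaf(space, plus_tables, restrictions)
    report = is_sheaf(sheaf)
    if not report.is_sheaf:  # pragma: no cover - internal consistency guard
        raise PresheafError(
            f"sheafification produced a non-sheaf (separated={report.separated}, "
            f"gluable={report.gluable})"
        )
    return SheafificationResult(input=F, sheaf=sheaf, unit=unit, diagnostics=diagnostics)


def check_idempotence(F: Presheaf) -> bool:
    """Sheafifying a sheafification changes no table (universality consequence)."""
    once = sheafify(F)
    twice = sheafify(once.sheaf)
    return all(
        once.sheaf.table(U) == twice.sheaf.table(U) for U in F.space.opens
    )


def unit_morphism(result: SheafificationResult) -> dict:
    """The unit F → F⁺ as a plain morphism dict (open -> section map)."""
    return {U: dict(m) for U, m in result.unit.items()}


def inclusion_morphism(F: Presheaf, G: Presheaf) -> dict:
    """The componentwise-identity morphism for F a sub-presheaf of G."""
    phi = {}
    for U in F.space.opens:
        if not F.sections(U) <= G.sections(U):
            raise PresheafError(
                f"F({{{OpenSet(U).label}}}) is not a subset of G at that open"
            )
        phi[U] = {s: s for s in F.sections(U)}
    return phi


def terminal_sheaf(space) -> Presheaf:
    """The sheaf with exactly one section per open (all values '*')."""
    tables = {
        U: SectionTable(U, frozenset([Section.make({p: "*" for p in U})]))
        for U in space.opens
    }
    restrictions = {}
    for V in space.opens:
        for U in space.opens:
            if U <= V:
                restrictions[(V, U)] = {s: s.project(U) for s in tables[V].sections}
    return Presheaf(space, tables, restrictions)


def _check_morphism(F: Presheaf, G: Presheaf, phi: Mapping) -> dict:
    phi = {OpenSet(k): dict(v) for k, v in phi.items()}
    for U in F.space.opens:
        if U not in phi:
            raise PresheafError(f"morphism has no component at {{{U.label}}}")
        for s in F.sections(U):
            if s not in phi[U]:
                raise PresheafError(f"morphism undefined at {s!r} over {{{U.label}}}")
            if phi[U][s] not in G.table(U):
                raise PresheafError(f"morphism image of {s!r} is not in G({{{U.label}}})")
    for V in F.space.opens:
        for U in F.space.opens:
            if not U <= V:
                continue
            for s in F.sections(V):
                if G.restrict(V, U, phi[V][s]) != phi[U][F.restrict(V, U, s)]:
                    raise PresheafError(
                        f"morphism is not natural on {{{U.label}}} ⊆ {{{V.label}}}"
                    )
    return phi


def check_universal_property(
    F: Presheaf,
    G: Presheaf,
    phi: Mapping,
    max_points: int = 4,
    max_rows: int = 6,
    max_nodes: int = 10_000_000,
) -> bool:
    """Brute-force the universal property of the unit F → F⁺.

    Given a sheaf G and a natural morphism φ: F → G, counts the natural
    morphisms ψ: F⁺ → G with ψ∘unit = φ by exhaustive enumeration of
    component maps (with naturality forcing from larger opens), and returns
    True iff exactly one exists.  Enforced bounds keep the enumeration finite
    in practice; beyond them a :class:`SizeError` is raised.
    """
    if len(F.space.points) > max_points:
        raise SizeError(f"space has {len(F.space.points)} points (> {max_points})")
    result = sheafify(F)
    Fp = result.sheaf
    for H in (F, G, Fp):
        for U in H.space.opens:
            if len(H.table(U)) > max_rows:
                raise SizeError(
                    f"table over {{{OpenSet(U).label}}} has {len(H.table(U))} rows "
                    f"(> {max_rows})"
                )
    if not is_sheaf(G).is_sheaf:
        raise PresheafError("G is not a sheaf")
    phi = _check_morphism(F, G, phi)

    opens = sorted(F.space.opens, key=_sort_key, reverse=True)
    count = 0
    nodes = 0
    assigned = {}

    def forced_map(U: OpenSet):
        forced = {}
        for t in F.sections(U):
            s = result.unit[U][t]
            want = phi[U][t]
            if forced.setdefault(s, want) != want:
                return None
        for W in assigned:
            if U < W:
                for r in Fp.sections(W):
                    s = r.project(U)
                    want = G.restrict(W, U, assigned[W][r])
                    if forced.setdefault(s, want) != want:
                        return None
        return forced

    def rec(i: int):
        nonlocal count, nodes
        nodes += 1
        if nodes > max_nodes:
            raise SizeError("morphism enumeration exceeded the node budget")
        if count >= 2:
            return
        if i == len(opens):
            count += 1
            return
        U = opens[i]
        forced = forced_map(U)
        if forced is None:
            return
        free = [s for s in Fp.table(U).rows_sorted() if s not in forced]
        targets = G.table(U).rows_sorted()
        if free and not targets:
            return
        for combo in product(targets, repeat=len(free)):
            assigned[U] = {**forced, **dict(zip(free, combo))}
            rec(i + 1)
            del assigned[U]
            if count >= 2:
                return

    rec(0)
    return count == 1
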
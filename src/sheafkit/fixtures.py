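"""Seeded random fixtures: Alexandrov spaces from random preorders, plus tables.

Random spaces are generated preorder-first — draw a random relation, take its
reflexive-transitive closure, and form the topology of up-sets — which makes
them valid topologies by construction and means the specialization preorder of
the generated space must recover exactly the generating closure (a property
the test suite leans on).  edge probability 0 gives the discrete topology and
1 the indiscrete one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Tuple

from .presheaf import Presheaf, SectionTable, tabular_presheaf
from .topology import FiniteSpace, OpenSet, powerset

__all__ = ["FixtureSpec", "Bundle", "random_preorder", "space_from_preorder",
           "random_space", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a random space + tabular presheaf."""

    seed: int
    n_points: int = 3
    edge_prob: float = 0.3
    value_alphabet: tuple = ("a", "b", "c")
    rows_per_generator: tuple = (1, 3)
    n_generators: int = 2


@dataclass
class Bundle:
    """A presheaf plus provenance (generator parameters, or 'user' for loaded data)."""

    presheaf: Presheaf
    provenance: dict = field(default_factory=lambda: {"source": "user"})


def random_preorder(rnd: random.Random, points: list, edge_prob: float) -> frozenset:
    """Reflexive-transitive closure of a random relation on *points*."""
    n = len(points)
    rel = [[i == j for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and rnd.random() < edge_prob:
                rel[i][j] = True
    for k in range(n):  # Warshall
        for i in range(n):
            if rel[i][k]:
                for j in range(n):
                    if rel[k][j]:
                        rel[i][j] = True
    return frozenset(
        (points[i], points[j]) for i in range(n) for j in range(n) if rel[i][j]
    )


def space_from_preorder(points: list, pairs: frozenset) -> FiniteSpace:
    """The Alexandrov topology of up-sets of the preorder (x in U, x<=y => y in U)."""
    up = {p: frozenset(q for q in points if (p, q) in pairs) for p in points}
    opens = [
        OpenSet(sub)
        for sub in powerset(points)
        if all(up[p] <= frozenset(sub) for p in sub)
    ]
    return FiniteSpace(points=frozenset(points), opens=frozenset(opens))


def random_space(rnd: random.Random, n_points: int, edge_prob: float) -> Tuple[FiniteSpace, frozenset]:
    points = [f"p{i}" for i in range(n_points)]
    pairs = random_preorder(rnd, points, edge_prob)
    return space_from_preorder(points, pairs), pairs


def generate_fixture(spec: FixtureSpec) -> Bundle:
    """A random space with random generator tables; identical spec ⇒ identical bundle."""
    if spec.n_points < 1:
        raise ValueError("n_points must be at least 1")
    rnd = random.Random(spec.seed)
    space, _ = random_space(rnd, spec.n_points, spec.edge_prob)
    nonempty = [U for U in space.opens_sorted() if U]
    generators = {}
    for _ in range(spec.n_generators):
        G = rnd.choice(nonempty)
        lo, hi = spec.rows_per_generator
        rows = [
            {p: rnd.choice(spec.value_alphabet) for p in G}
            for _ in range(rnd.randint(lo, hi))
        ]
        tab = SectionTable.from_rows(G, rows)
        if G in generators:
            tab = SectionTable(G, generators[G].sections | tab.sections)
        generators[G] = tab
    presheaf = tabular_presheaf(space, generators)
    provenance = {
        "source": "generator",
        "seed": spec.seed,
        "n_points": spec.n_points,
        "edge_prob": spec.edge_prob,
        "value_alphabet": list(spec.value_alphabet),
        "rows_per_generator": list(spec.rows_per_generator),
        "n_generators": spec.n_generators,
    }
    return Bundle(presheaf=presheaf, provenance=provenance)
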
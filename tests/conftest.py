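import random

import pytest

from sheafkit import OpenSet, standard_topology, tabular_presheaf
from sheafkit.applications.binding import binding_space, example_feature_tables
from sheafkit.applications.cards import (
    RANKS,
    SUITS,
    known_cards_table,
    rank_table,
    suit_table,
)
from sheafkit.fixtures import FixtureSpec, generate_fixture
from sheafkit.presheaf import SectionTable


@pytest.fixture
def discrete_rs():
    return standard_topology(["R", "S"], "discrete")


@pytest.fixture
def indiscrete_rs():
    return standard_topology(["R", "S"], "indiscrete")


@pytest.fixture
def space_binding():
    return binding_space()


@pytest.fixture
def feature_tables():
    return example_feature_tables()


@pytest.fixture
def card_generators_presheaf(discrete_rs):
    """Rank and suit one-column tables on the discrete 2-point space."""
    return tabular_presheaf(
        discrete_rs,
        {OpenSet(["R"]): rank_table(), OpenSet(["S"]): suit_table()},
    )


@pytest.fixture
def full_deck_presheaf(discrete_rs):
    """All 52 cards attached to the top open: already a sheaf."""
    deck = known_cards_table((r, s) for r in RANKS for s in SUITS)
    return tabular_presheaf(discrete_rs, {OpenSet(["R", "S"]): deck})


@pytest.fixture
def qh2s_indiscrete_presheaf(indiscrete_rs):
    """Known queen-of-hearts and two-of-spades, cards as non-compositional wholes."""
    return tabular_presheaf(
        indiscrete_rs,
        {OpenSet(["R", "S"]): known_cards_table([("Q", "♡"), ("2", "♠")])},
    )


def random_fixture(seed, **overrides):
    """A seeded random presheaf bundle with mildly varied shape parameters."""
    rnd = random.Random(seed)
    params = dict(
        seed=seed,
        n_points=rnd.choice([2, 3, 4]),
        edge_prob=rnd.choice([0.0, 0.2, 0.4, 0.7, 1.0]),
        rows_per_generator=(1, 3),
        n_generators=rnd.choice([1, 2, 3]),
    )
    params.update(overrides)
    return generate_fixture(FixtureSpec(**params))


def random_table(rnd, points, alphabet=("a", "b", "c"), max_rows=5):
    rows = [
        {p: rnd.choice(alphabet) for p in points}
        for _ in range(rnd.randint(0, max_rows))
    ]
    return SectionTable.from_rows(points, rows)
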
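"""Playing-card completion: systematic capacity depends on the topology.

The two feature dimensions rank (R) and suit (S) carry either the discrete
topology — the dimensions are independent, and sheaving completes one-column
rank and suit tables to the full Cartesian deck — or the indiscrete topology,
under which cards are non-compositional wholes and sheaving adds nothing.
"""

from __future__ import annotations

from typing import Iterable, Optional

from ..errors import ConfigError
from ..presheaf import SectionTable, tabular_presheaf
from ..sheaving import SheafificationResult, sheafify
from ..topology import OpenSet, standard_topology

RANK_POINT = "R"
SUIT_POINT = "S"

RANKS = ("2", "3", "4", "5", "6", "7", "8", "9", "10", "J", "Q", "K", "A")
SUITS = ("♠", "♣", "♢", "♡")

#: ASCII aliases for terminals without the card glyphs.
ASCII_SUITS = {"♠": "S", "♣": "C", "♢": "D", "♡": "H"}


def rank_table(ranks: Iterable[str] = RANKS) -> SectionTable:
    """The one-column table of rank symbols over the open {R}."""
    return SectionTable.from_rows([RANK_POINT], [{RANK_POINT: r} for r in ranks])


def suit_table(suits: Iterable[str] = SUITS) -> SectionTable:
    """The one-column table of suit symbols over the open {S}."""
    return SectionTable.from_rows([SUIT_POINT], [{SUIT_POINT: s} for s in suits])


def known_cards_table(cards: Iterable[tuple]) -> SectionTable:
    """A two-column table over {R, S}, one row per known (rank, suit) card."""
    return SectionTable.from_rows(
        [RANK_POINT, SUIT_POINT],
        [{RANK_POINT: r, SUIT_POINT: s} for r, s in cards],
    )


def card_demo(
    ranks: Optional[Iterable[str]] = None,
    suits: Optional[Iterable[str]] = None,
    topology_kind: str = "discrete",
    known_cards: Optional[SectionTable] = None,
) -> SheafificationResult:
    """Build the card presheaf on the requested topology and sheafify it.

    Discrete: generators are the rank table over {R} and the suit table over
    {S}; the completed sheaf's global table is their Cartesian product.
    Indiscrete: the only non-trivial open is {R, S} itself, carrying the table
    of known (non-compositional) cards; sheaving leaves it unchanged.
    """
    space = standard_topology([RANK_POINT, SUIT_POINT], topology_kind)
    if topology_kind == "discrete":
        if ranks is None:
            ranks = RANKS
        if suits is None:
            suits = SUITS
        ranks, suits = list(ranks), list(suits)
        if not ranks or not suits:
            raise ConfigError("discrete card demo needs non-empty ranks and suits")
        generators = {
            OpenSet([RANK_POINT]): rank_table(ranks),
            OpenSet([SUIT_POINT]): suit_table(suits),
        }
    else:
        if known_cards is None:
            raise ConfigError("indiscrete card demo needs a known_cards table")
        if not isinstance(known_cards, SectionTable):
            known_cards = known_cards_table(known_cards)
        generators = {OpenSet([RANK_POINT, SUIT_POINT]): known_cards}
    presheaf = tabular_presheaf(space, generators)
    return sheafify(presheaf)
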
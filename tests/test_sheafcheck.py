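import random
from itertools import product

import pytest

from sheafkit import (
    CoverError,
    InclusionError,
    OpenSet,
    Presheaf,
    Section,
    SectionTable,
    amalgamations,
    irredundant_covers,
    is_sheaf,
    matching_families,
    natural_join,
    pullback,
    standard_topology,
    tabular_presheaf,
)
from sheafkit.presheaf import EMPTY_SECTION

from conftest import random_table


def join_oracle(t1, t2, over=None):
    """Brute force: full Cartesian product of rows, keep pairs agreeing on shared points."""
    shared = t1.open & t2.open
    rows = set()
    for s1, s2 in product(t1.sections, t2.sections):
        if all(s1[p] == s2[p] for p in shared):
            merged = dict(s1.items)
            merged.update(s2.items)
            rows.add(Section.make(merged))
    return SectionTable(OpenSet(t1.open | t2.open), frozenset(rows))


class TestNaturalJoin:
    def test_colour_location_join_orientation_location(self, feature_tables):
        """The printed colour-orientation table: (red,hor)1 (red,hor)2 (blue,hor)3 (red,ver)4."""
        cl, ol, _ = feature_tables
        joined = natural_join(cl, ol)
        expected = {
            ("red", "1", "hor"),
            ("red", "2", "hor"),
            ("blue", "3", "hor"),
            ("red", "4", "ver"),
        }
        assert {(s["C"], s["L"], s["O"]) for s in joined.sections} == expected

    def test_disjoint_attributes_give_all_pairwise_combinations(self):
        ranks = SectionTable.from_rows(["R"], [{"R": r} for r in "QK2"])
        suits = SectionTable.from_rows(["S"], [{"S": s} for s in "♠♡"])
        assert len(natural_join(ranks, suits)) == 6

    def test_join_with_empty_table_is_empty(self, feature_tables):
        cl, _, _ = feature_tables
        assert len(natural_join(cl, SectionTable.empty(["O", "L"]))) == 0

    def test_equal_attribute_sets_join_to_intersection(self):
        a = SectionTable.from_rows(["x"], [{"x": v} for v in "abc"])
        b = SectionTable.from_rows(["x"], [{"x": v} for v in "bcd"])
        assert natural_join(a, b).sections == (a.sections & b.sections)

    @pytest.mark.parametrize("seed", range(20))
    def test_join_laws_on_random_tables(self, seed):
        """Commutative, associative, idempotent; agrees with the product-filter oracle."""
        rnd = random.Random(seed)
        pools = [["x", "y"], ["y", "z"], ["z", "w", "x"]]
        t1, t2, t3 = (random_table(rnd, p, alphabet="ab") for p in pools)
        assert natural_join(t1, t2) == natural_join(t2, t1)
        assert natural_join(natural_join(t1, t2), t3) == natural_join(
            t1, natural_join(t2, t3)
        )
        assert natural_join(t1, t1) == t1
        assert natural_join(t1, t2) == join_oracle(t1, t2)


class TestPullback:
    def test_binding_pullback_over_location(self, feature_tables):
        cl, ol, _ = feature_tables
        apex, proj1, proj2 = pullback(cl, ol, OpenSet(["L"]))
        assert apex == natural_join(cl, ol)
        # the square commutes: both projections agree on the base
        for row in apex.sections:
            assert proj1[row].project(["L"]) == proj2[row].project(["L"])
            assert proj1[row] in cl.sections and proj2[row] in ol.sections

    def test_pullback_over_empty_base_of_disjoint_tables_is_cartesian(self):
        a = SectionTable.from_rows(["x"], [{"x": v} for v in "abc"])
        b = SectionTable.from_rows(["y"], [{"y": v} for v in "12"])
        apex = pullback(a, b, OpenSet()).apex
        assert len(apex) == 6

    def test_base_must_be_inside_the_overlap(self, feature_tables):
        cl, ol, _ = feature_tables
        with pytest.raises(InclusionError):
            pullback(cl, ol, OpenSet(["C"]))

    @pytest.mark.parametrize("seed", range(10))
    def test_pullback_apex_equals_join_over_full_overlap(self, seed):
        rnd = random.Random(seed)
        t1 = random_table(rnd, ["x", "y"], alphabet="ab")
        t2 = random_table(rnd, ["y", "z"], alphabet="ab")
        over = OpenSet(t1.open & t2.open)
        assert pullback(t1, t2, over).apex == natural_join(t1, t2)


class TestMatchingFamilies:
    def test_card_cover_has_52_families(self, card_generators_presheaf):
        fams = matching_families(
            card_generators_presheaf,
            ["R", "S"],
            [OpenSet(["R"]), OpenSet(["S"])],
        )
        assert len(fams) == 52

    def test_singleton_cover_families_are_the_sections(self, full_deck_presheaf):
        U = OpenSet(["R", "S"])
        fams = matching_families(full_deck_presheaf, U, [U])
        assert {f.section_at(U) for f in fams} == full_deck_presheaf.sections(U)

    def test_binding_canonical_cover_has_four_families(self, feature_tables):
        from sheafkit import canonical_cover
        from sheafkit.applications.binding import binding_presheaf, binding_space

        F = binding_presheaf(feature_tables)
        U = OpenSet(["C", "O", "F", "L"])
        fams = matching_families(F, U, canonical_cover(binding_space(), U))
        assert len(fams) == 4

    def test_cover_must_union_to_target(self, card_generators_presheaf):
        with pytest.raises(CoverError):
            matching_families(card_generators_presheaf, ["R", "S"], [OpenSet(["R"])])


class TestIsSheaf:
    def test_full_deck_is_a_sheaf(self, full_deck_presheaf):
        report = is_sheaf(full_deck_presheaf)
        assert report.separated and report.gluable and report.is_sheaf

    def test_any_indiscrete_presheaf_is_a_sheaf(self, qh2s_indiscrete_presheaf):
        assert is_sheaf(qh2s_indiscrete_presheaf).is_sheaf

    def test_generators_without_completion_are_not_gluable(
        self, card_generators_presheaf
    ):
        """52 matching families, 0 amalgamations in the empty top table."""
        report = is_sheaf(card_generators_presheaf)
        assert report.separated
        assert not report.gluable
        assert report.n_witnesses == 52
        assert report.witnesses[0]["kind"] == "not-gluable"
        fam = report.witnesses[0]["family"]
        assert amalgamations(card_generators_presheaf, fam) == []

    def test_collapsing_restrictions_break_separatedness(self):
        """Two global rows whose hand-built restrictions share every germ."""
        space = standard_topology(["x", "y"], "discrete")
        top, ox, oy, bot = (
            OpenSet(["x", "y"]),
            OpenSet(["x"]),
            OpenSet(["y"]),
            OpenSet(),
        )
        s1 = Section.make({"x": "1", "y": "1"})
        s2 = Section.make({"x": "2", "y": "2"})
        gx, gy = Section.make({"x": "1"}), Section.make({"y": "1"})
        tables = {
            top: SectionTable(top, frozenset([s1, s2])),
            ox: SectionTable(ox, frozenset([gx])),
            oy: SectionTable(oy, frozenset([gy])),
            bot: SectionTable.terminal(),
        }
        restrictions = {
            (top, top): {s1: s1, s2: s2},
            (top, ox): {s1: gx, s2: gx},  # both rows collapse onto the same germs
            (top, oy): {s1: gy, s2: gy},
            (top, bot): {s1: EMPTY_SECTION, s2: EMPTY_SECTION},
            (ox, ox): {gx: gx},
            (ox, bot): {gx: EMPTY_SECTION},
            (oy, oy): {gy: gy},
            (oy, bot): {gy: EMPTY_SECTION},
            (bot, bot): {EMPTY_SECTION: EMPTY_SECTION},
        }
        F = Presheaf(space, tables, restrictions)
        from sheafkit import check_functoriality

        assert check_functoriality(F).ok
        report = is_sheaf(F)
        assert not report.separated
        assert any(w["kind"] == "not-separated" for w in report.witnesses)


def test_irredundant_covers_are_antichains_unioning_to_target():
    space = standard_topology(["a", "b", "c"], "discrete")
    U = OpenSet(["a", "b", "c"])
    covers = list(irredundant_covers(space, U))
    for cover in covers:
        assert OpenSet().union(*cover) == U
        for v, w in product(cover, cover):
            if v != w:
                assert not v <= w
    # the singleton cover and the cover by atoms are both present
    assert frozenset([U]) in covers
    assert frozenset([OpenSet(["a"]), OpenSet(["b"]), OpenSet(["c"])]) in covers
    assert len(set(covers)) == len(covers)
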
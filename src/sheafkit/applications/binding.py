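"""Triple-conjunction visual feature binding.

Colour, orientation and spatial-frequency maps are indexed by location; the
topology on {C, O, F, L} makes location the shared (general) dimension, so in
the specialization preorder C ≤ L, O ≤ L and F ≤ L.  Binding the features
into objects is the staged pullback (C ×_L O) ×_L F — equivalently the
natural join of the feature-location tables — and arises as sheaving of the
feature-location presheaf.
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

from ..errors import SchemaError
from ..presheaf import Presheaf, SectionTable, tabular_presheaf
from ..sheafcheck import pullback
from ..sheaving import SheafificationResult, sheafify
from ..topology import FiniteSpace, OpenSet, make_space

LOCATION_POINT = "L"
BINDING_POINTS = ("C", "O", "F", "L")

#: The nine opens of the binding topology: location is in every non-empty open.
BINDING_OPENS = (
    (),
    ("L",),
    ("C", "L"),
    ("O", "L"),
    ("F", "L"),
    ("C", "O", "L"),
    ("C", "F", "L"),
    ("O", "F", "L"),
    ("C", "O", "F", "L"),
)


def binding_space() -> FiniteSpace:
    return make_space(BINDING_POINTS, BINDING_OPENS)


def example_feature_tables() -> Tuple[SectionTable, SectionTable, SectionTable]:
    """The four-location colour/orientation/frequency tables of the worked demo.

    Locations 1–4 hold (red, hor, low), (red, hor, high), (blue, hor, low) and
    (red, ver, low) respectively.
    """
    colours = ["red", "red", "blue", "red"]
    orients = ["hor", "hor", "hor", "ver"]
    freqs = ["low", "high", "low", "low"]
    locs = ["1", "2", "3", "4"]
    cl = SectionTable.from_rows(
        ["C", "L"], [{"C": c, "L": i} for c, i in zip(colours, locs)]
    )
    ol = SectionTable.from_rows(
        ["O", "L"], [{"O": o, "L": i} for o, i in zip(orients, locs)]
    )
    fl = SectionTable.from_rows(
        ["F", "L"], [{"F": f, "L": i} for f, i in zip(freqs, locs)]
    )
    return cl, ol, fl


def triple_conjunction(
    feature_tables: Sequence[SectionTable],
    location_point: str = LOCATION_POINT,
) -> Tuple[SectionTable, int]:
    """Left-fold of binary pullbacks of feature tables over the location point.

    Returns the bound object table and the number of binary pullbacks
    performed (two for three feature tables).  The row set is independent of
    the fold order because the natural join is associative and commutative.
    """
    tables = list(feature_tables)
    if not tables:
        raise SchemaError("at least one feature table is required")
    seen_features = set()
    for t in tables:
        if location_point not in t.open:
            raise SchemaError(
                f"table over {{{t.open.label}}} is missing the location "
                f"attribute {location_point!r}"
            )
        feats = t.open - {location_point}
        if feats & seen_features:
            raise SchemaError(
                f"feature points repeat across tables: {sorted(feats & seen_features)}"
            )
        seen_features |= feats
    acc = tables[0]
    count = 0
    for t in tables[1:]:
        acc = pullback(acc, t, OpenSet([location_point])).apex
        count += 1
    return acc, count


def binding_presheaf(
    feature_tables: Iterable[SectionTable] = None,
) -> Presheaf:
    """The tabular presheaf generated by the CL, OL and FL tables."""
    if feature_tables is None:
        feature_tables = example_feature_tables()
    generators = {t.open: t for t in feature_tables}
    return tabular_presheaf(binding_space(), generators)


def binding_demo(feature_tables: Iterable[SectionTable] = None) -> SheafificationResult:
    """Sheafify the feature-location presheaf; the global table is the bound objects."""
    return sheafify(binding_presheaf(feature_tables))
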
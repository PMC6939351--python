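"""Binocular depth triangulation, analytically and as discrete sheaving.

Each eye sees the target along a line of sight: the left ray is
l ↦ eye_left + l·(cos λ, sin λ) and the right ray r ↦ eye_right + r·(cos ρ,
sin ρ), with l, r the (signed) distances along the rays.  The target position
is the intersection of the rays — the pullback of the two parameterizations —
found in closed form by solving the 2×2 linear system.

The same computation is staged as sheaving: on the label space {L, R, P} with
topology {∅, {P}, {L,P}, {R,P}, {L,R,P}}, the tables LP = {(l, pos_left(l))}
and RP = {(r, pos_right(r))} over a finite distance grid glue exactly at the
grid points where both rays report the same (rounded) position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import numpy as np

from ..errors import ParallelLinesError, BehindEyesWarning
from ..presheaf import SectionTable, tabular_presheaf
from ..sheaving import SheafificationResult, sheafify
from ..topology import FiniteSpace, make_space

#: Rays with |sin(λ − ρ)| at or below this are treated as parallel.
PARALLEL_EPS = 1e-12

STEREO_POINTS = ("L", "R", "P")
STEREO_OPENS = ((), ("P",), ("L", "P"), ("R", "P"), ("L", "R", "P"))


@dataclass(frozen=True)
class Position:
    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class EyeGeometry:
    """Line-of-sight angles (radians) and eye positions (length units).

    Defaults put the left eye at the origin and the right eye one baseline
    unit along the x-axis; with both eyes at the origin the rays reduce to the
    pure l·(cos λ, sin λ) / r·(cos ρ, sin ρ) parameterization.
    """

    lam: float
    rho: float
    left_eye: Tuple[float, float] = (0.0, 0.0)
    right_eye: Tuple[float, float] = (1.0, 0.0)

    @classmethod
    def with_baseline(cls, lam: float, rho: float, baseline: float = 1.0) -> "EyeGeometry":
        return cls(lam=lam, rho=rho, left_eye=(0.0, 0.0), right_eye=(baseline, 0.0))


@dataclass(frozen=True)
class LineOfSight:
    """A ray from an eye: origin, angle, and optional sampled distance parameters."""

    origin: Tuple[float, float]
    angle: float
    samples: Optional[tuple] = None

    @property
    def direction(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])

    def at(self, t: float) -> np.ndarray:
        return np.asarray(self.origin, dtype=float) + t * self.direction


def triangulate(geometry: EyeGeometry) -> Tuple[Position, float, float]:
    """Intersect the two lines of sight; returns (position, l, r).

    Solves left_eye + l·(cos λ, sin λ) = right_eye + r·(cos ρ, sin ρ).
    Raises :class:`ParallelLinesError` when |sin(λ − ρ)| ≤ 1e−12; emits a
    :class:`BehindEyesWarning` when the intersection has l < 0 or r < 0.
    """
    lam, rho = geometry.lam, geometry.rho
    if abs(math.sin(lam - rho)) <= PARALLEL_EPS:
        raise ParallelLinesError(
            f"lines of sight with λ={lam} and ρ={rho} are parallel"
        )
    a = np.array(
        [[math.cos(lam), -math.cos(rho)], [math.sin(lam), -math.sin(rho)]]
    )
    b = np.asarray(geometry.right_eye, dtype=float) - np.asarray(
        geometry.left_eye, dtype=float
    )
    l, r = np.linalg.solve(a, b)
    if l < 0 or r < 0:
        warnings.warn(
            f"intersection lies behind an eye (l={l:.6g}, r={r:.6g})",
            BehindEyesWarning,
            stacklevel=2,
        )
    pos = LineOfSight(geometry.left_eye, lam).at(l)
    return Position(float(pos[0]), float(pos[1])), float(l), float(r)


def geometry_for_target(
    x: float,
    y: float,
    left_eye: Tuple[float, float] = (0.0, 0.0),
    right_eye: Tuple[float, float] = (1.0, 0.0),
) -> EyeGeometry:
    """The angles each eye must adopt to fixate the target (x, y)."""
    lam = math.atan2(y - left_eye[1], x - left_eye[0])
    rho = math.atan2(y - right_eye[1], x - right_eye[0])
    return EyeGeometry(lam=lam, rho=rho, left_eye=left_eye, right_eye=right_eye)


def stereo_space() -> FiniteSpace:
    """{L, R, P} with opens {∅, {P}, {L,P}, {R,P}, {L,R,P}}: distances specialize position."""
    return make_space(STEREO_POINTS, STEREO_OPENS)


def _fmt(v: float, decimals: int) -> str:
    # round-then-add-0.0 normalizes -0.0 so string equality is well behaved
    return f"{round(v, decimals) + 0.0:.{decimals}f}"


def _position_value(p: np.ndarray, decimals: int) -> str:
    return f"{_fmt(p[0], decimals)}|{_fmt(p[1], decimals)}"


def line_of_sight_table(
    distance_point: str,
    sight: LineOfSight,
    distances: Iterable[float],
    decimals: int,
) -> SectionTable:
    """The relation {(t, position(t))} over the open {distance_point, P}."""
    rows = [
        {distance_point: _fmt(t, decimals), "P": _position_value(sight.at(t), decimals)}
        for t in distances
    ]
    return SectionTable.from_rows([distance_point, "P"], rows)


def stereo_as_sheaving(
    geometry: EyeGeometry,
    distance_grid: Iterable[float],
    decimals: int = 9,
) -> SheafificationResult:
    """Triangulation as sheaving over a finite distance grid.

    Positions are rounded to ``decimals`` before the join, so the global
    table over {L, R, P} holds exactly the grid pairs whose ray positions
    coincide at that resolution.
    """
    grid = list(distance_grid)
    left = LineOfSight(geometry.left_eye, geometry.lam, tuple(grid))
    right = LineOfSight(geometry.right_eye, geometry.rho, tuple(grid))
    space = stereo_space()
    generators = {
        ("L", "P"): line_of_sight_table("L", left, grid, decimals),
        ("R", "P"): line_of_sight_table("R", right, grid, decimals),
    }
    return sheafify(tabular_presheaf(space, generators))


def matched_positions(result: SheafificationResult) -> list:
    """Decode the glued global sections of a stereo sheaving back to positions."""
    out = []
    for s in result.sheaf.table(STEREO_POINTS):
        x, y = s["P"].split("|")
        out.append(Position(float(x), float(y)))
    return out
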
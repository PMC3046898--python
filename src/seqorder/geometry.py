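"""Regular-tetrahedron mapping of base compositions and the inscribed sphere.

A composition (a, c, g, t) maps one-to-one onto a point of a regular
tetrahedron whose vertices are the four single-base compositions.  Two
coordinate systems are in use:

* the *original* system (X, Y, Z), spanning [−3/4, 3/4] per axis, and
* the *reduced* system (x, y, z) = (4/3)(X, Y, Z), spanning [−1, 1]:

      x = (a+g) − (c+t)   (purine excess)
      y = (a+c) − (g+t)   (amino excess)
      z = (a+t) − (g+c)   (weak-bond excess, i.e. minus the GC excess)

The inscribed sphere of the tetrahedron has radius 1/4 in the original
system and (4/3)·(1/4) = 1/3 in the reduced one; mixing coordinates from one
system with the radius of the other inflates the apparent outside fraction —
this module keeps the two systems and their radii explicitly paired.

Distance convention: the stated radii 1/4 and 1/3, and the equivalence of
sphere membership with S < 1/3, all hold simultaneously when "distance" is
the root-mean-square coordinate sqrt((x²+y²+z²)/3); that RMS metric is what
:func:`rms_distance` computes, with the plain Euclidean norm exposed
separately.  Membership verdicts are canonically decided by S < 1/3 (strict)
so they never depend on the metric reading; the RMS-distance criterion
agrees by the identity ρ² = 4S − 1 (ρ the reduced-system Euclidean norm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

from .composition import BaseComposition
from .indices import genome_order_index

__all__ = [
    "ReducedPoint",
    "OriginalPoint",
    "SphereVerdict",
    "reduced_point",
    "original_point",
    "to_original",
    "to_reduced",
    "point_to_composition",
    "insphere_radius",
    "rms_distance",
    "euclidean_distance",
    "insphere_test",
]

System = Literal["reduced", "original"]

_BOUND_TOL = 1e-9
#: recovered frequencies below this are rejected as outside the tetrahedron
_FREQ_TOL = -1e-9

S_THRESHOLD = 1.0 / 3.0


def _check_bounds(coords: tuple[float, float, float], bound: float, label: str) -> None:
    for c in coords:
        if abs(c) > bound + _BOUND_TOL:
            raise ValueError(f"{label} coordinate {c} outside [-{bound}, {bound}]")


@dataclass(frozen=True)
class ReducedPoint:
    """Mapping point in the reduced system; each coordinate in [−1, 1]."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        _check_bounds((self.x, self.y, self.z), 1.0, "reduced")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class OriginalPoint:
    """Mapping point in the original system; each coordinate in [−3/4, 3/4]."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        _check_bounds((self.x, self.y, self.z), 0.75, "original")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class SphereVerdict:
    """Inscribed-sphere membership of one composition.

    ``inside`` is decided by S < 1/3 (strict); ``rms_distance_reduced``
    records the RMS-coordinate distance in the reduced system, which gives
    the same verdict against the reduced radius 1/3 by construction.
    """

    s_value: float
    rms_distance_reduced: float
    inside: bool
    system: System
    radius_used: float


def reduced_point(comp: BaseComposition) -> ReducedPoint:
    """Map a composition into the reduced system (coordinates in [−1, 1])."""
    a, c, g, t = comp.a, comp.c, comp.g, comp.t
    return ReducedPoint(
        x=(a + g) - (c + t),
        y=(a + c) - (g + t),
        z=(a + t) - (g + c),
    )


def original_point(comp: BaseComposition) -> OriginalPoint:
    """Map a composition into the original system (coordinates in [−3/4, 3/4])."""
    return to_original(reduced_point(comp))


def to_original(p: ReducedPoint) -> OriginalPoint:
    """Scale a reduced-system point by 3/4 into the original system."""
    return OriginalPoint(0.75 * p.x, 0.75 * p.y, 0.75 * p.z)


def to_reduced(p: OriginalPoint) -> ReducedPoint:
    """Scale an original-system point by 4/3 back into the reduced system."""
    return ReducedPoint(p.x / 0.75, p.y / 0.75, p.z / 0.75)


def point_to_composition(p: ReducedPoint) -> BaseComposition:
    """Invert the reduced mapping; errors if the point lies outside the
    tetrahedron (i.e. any recovered frequency would be negative)."""
    a = (1.0 + p.x + p.y + p.z) / 4.0
    c = (1.0 - p.x + p.y - p.z) / 4.0
    g = (1.0 + p.x - p.y - p.z) / 4.0
    t = (1.0 - p.x - p.y + p.z) / 4.0
    if min(a, c, g, t) < _FREQ_TOL:
        raise ValueError(
            f"point {p.as_tuple()} lies outside the tetrahedron "
            f"(recovered frequencies {(a, c, g, t)})"
        )
    return BaseComposition(a, c, g, t)


def insphere_radius(system: System) -> float:
    """Inscribed-sphere radius: 1/3 (reduced) or 1/4 (original).

    The ratio 4/3 between them is the coordinate-transform factor; using the
    original-system radius against reduced-system coordinates understates
    the sphere and wrongly pushes points outside.
    """
    if system == "reduced":
        return 1.0 / 3.0
    if system == "original":
        return 0.25
    raise ValueError(f"unknown system {system!r} (expected 'reduced' or 'original')")


def euclidean_distance(p: Union[ReducedPoint, OriginalPoint]) -> float:
    """Plain Euclidean norm sqrt(x² + y² + z²) of a mapping point."""
    return math.sqrt(p.x**2 + p.y**2 + p.z**2)


def rms_distance(p: Union[ReducedPoint, OriginalPoint]) -> float:
    """RMS-coordinate distance sqrt((x² + y² + z²)/3), in the point's own
    system.  Under this convention the tetrahedron's face-touching points sit
    exactly at :func:`insphere_radius` of that system."""
    return math.sqrt((p.x**2 + p.y**2 + p.z**2) / 3.0)


def insphere_test(comp: BaseComposition, system: System = "reduced") -> SphereVerdict:
    """Inscribed-sphere membership verdict for a composition.

    ``inside`` iff S < 1/3 (strict; S = 1/3 counts as outside).  The RMS
    distance and per-system radius are recorded alongside; the distance
    criterion agrees with the S criterion for every composition because
    rms_distance² = (4S − 1)/3 in the reduced system.
    """
    radius = insphere_radius(system)  # validates the system name
    s = genome_order_index(comp)
    return SphereVerdict(
        s_value=s,
        rms_distance_reduced=rms_distance(reduced_point(comp)),
        inside=s < S_THRESHOLD,
        system=system,
        radius_used=radius,
    )
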
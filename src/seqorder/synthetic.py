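"""Seeded generators of sequences and genome cohorts with controlled GC
content and PR2-deviation structure.

A cohort member is built from two independent controls: its GC content
(drawn uniformly over a configurable range, emulating the wide GC spread of
bacterial genomes) and its PR2 deviation (zero-mean Gaussian perturbations
delta1 of a vs t and delta2 of c vs g, applied *within* the AT and GC pools
so GC content is preserved exactly).  With ``skew_scale = 0`` every member
satisfies a = t and c = g exactly, which pins the x and y mapping
coordinates at zero; small positive skews reproduce the near-PR2 regime of
real genomes where nearly all cross-genome variance sits on the z (GC)
coordinate.

The generator makes no attempt at codon structure, repeats or
replichore-segmented skews: members are i.i.d. draws per base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .composition import BaseComposition

__all__ = [
    "CohortSpec",
    "CohortMember",
    "ReferenceComposition",
    "random_sequence",
    "generate_cohort",
    "counterexample_compositions",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic genome cohort.

    ``skew_scale`` is the standard deviation of the a−t and c−g
    perturbations (frequency units); ``sequence_length`` of None means
    composition-only members.
    """

    n: int
    gc_low: float = 0.25
    gc_high: float = 0.75
    skew_scale: float = 0.005
    sequence_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.gc_low <= self.gc_high < 1.0):
            raise ValueError(
                f"gc bounds ({self.gc_low}, {self.gc_high}) must satisfy "
                "0 < gc_low <= gc_high < 1"
            )
        if self.skew_scale < 0:
            raise ValueError("skew_scale must be non-negative")
        if self.sequence_length is not None and self.sequence_length < 1:
            raise ValueError("sequence_length must be >= 1")


@dataclass(frozen=True)
class CohortMember:
    id: str
    composition: BaseComposition
    sequence: Optional[str] = None


@dataclass(frozen=True)
class ReferenceComposition:
    """A named composition with its known reference values attached."""

    name: str
    composition: BaseComposition
    expected: dict


def random_sequence(
    comp: BaseComposition, length: int, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Draw ``length`` i.i.d. bases from a composition; seeded and repeatable."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=comp.as_array())
    return "".join(_BASES[idx])


def generate_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Generate ``spec.n`` members with uniform GC and Gaussian PR2 skews.

    Each member's composition is a = (1−gc)/2 + d1, t = (1−gc)/2 − d1,
    c = gc/2 + d2, g = gc/2 − d2 with d_i ~ Normal(0, skew_scale/2), so that
    the observable deviations a − t = 2·d1 and c − g = 2·d2 each have
    standard deviation exactly ``skew_scale``.  Perturbations are truncated
    (with a logged warning) so no frequency goes negative.  GC content is
    preserved exactly by construction.
    """
    rng = np.random.default_rng(spec.seed)
    members = []
    for i in range(spec.n):
        gc = rng.uniform(spec.gc_low, spec.gc_high)
        at_half, gc_half = (1.0 - gc) / 2.0, gc / 2.0
        if spec.skew_scale > 0:
            d1, d2 = rng.normal(0.0, spec.skew_scale / 2.0, size=2)
        else:
            d1 = d2 = 0.0
        if abs(d1) > at_half or abs(d2) > gc_half:
            logger.warning("member %d: PR2 skew truncated at the boundary", i)
            d1 = float(np.clip(d1, -at_half, at_half))
            d2 = float(np.clip(d2, -gc_half, gc_half))
        comp = BaseComposition(
            a=at_half + d1, c=gc_half + d2, g=gc_half - d2, t=at_half - d1
        )
        seq = None
        if spec.sequence_length is not None:
            seq = random_sequence(comp, spec.sequence_length, rng=rng)
        members.append(CohortMember(id=f"synth_{i:04d}", composition=comp, sequence=seq))
    return members


def counterexample_compositions() -> dict[str, ReferenceComposition]:
    """Named fixture compositions with their known reference values.

    Contains the tetrahedron centre (uniform), the four vertices, the
    two-base degenerate composition a = c = 1/2 that breaks the S < 1/3
    rule, the human Sirtuin-3 gene composition and the X. fastidiosa 9a5c
    genome composition (printed at 4 significant figures, hence summing to
    0.9999 before renormalization).
    """
    entries = [
        ReferenceComposition(
            "uniform", BaseComposition(0.25, 0.25, 0.25, 0.25),
            {"s": 0.25, "shannon_bits": 2.0},
        ),
        ReferenceComposition("vertex_a", BaseComposition(1, 0, 0, 0), {"s": 1.0}),
        ReferenceComposition("vertex_c", BaseComposition(0, 1, 0, 0), {"s": 1.0}),
        ReferenceComposition("vertex_g", BaseComposition(0, 0, 1, 0), {"s": 1.0}),
        ReferenceComposition("vertex_t", BaseComposition(0, 0, 0, 1), {"s": 1.0}),
        ReferenceComposition(
            "ac_half", BaseComposition(0.5, 0.5, 0.0, 0.0), {"s": 0.5},
        ),
        ReferenceComposition(
            "sirtuin3", BaseComposition(0.174, 0.279, 0.333, 0.214),
            {"s_3dp": 0.265, "s_reduced_3dp": 0.273},
        ),
        ReferenceComposition(
            "x_fastidiosa", BaseComposition(0.2254, 0.2494, 0.2773, 0.2478),
            {"ac_sum_3dp": 0.475},
        ),
    ]
    return {e.name: e for e in entries}
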
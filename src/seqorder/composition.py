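"""Nucleotide counting, base-composition vectors and Chargaff PR2 deviations.

The composition vector ``(a, c, g, t)`` of relative base frequencies is the
central object of the package: every downstream quantity — the genome order
index S, the Shannon and alpha-order entropies, the tetrahedron mapping
coordinates — is a function of it.  Chargaff's second parity rule (PR2) is
the empirical, *approximate* intra-strand equality a ≈ t and c ≈ g; this
module reports deviations from it exactly as computed, never thresholded or
zeroed, because those deviations carry strand-asymmetry signal (replication,
transcription and repair biases).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BaseCounts",
    "BaseComposition",
    "PR2Report",
    "count_bases",
    "frequencies",
    "reverse_complement",
    "pr2_deviation",
]

logger = logging.getLogger(__name__)

#: |sum - 1| above this is silently renormalized away (numerical noise).
SUM_TOLERANCE = 1e-9
#: |sum - 1| above this triggers a logged warning before renormalizing
#: (typical of printed frequencies rounded to a few decimals).
WARN_TOLERANCE = 1e-6

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class BaseCounts:
    """Raw nucleotide counts for one sequence.

    ``n_other`` counts characters that map to none of A/C/G/T after
    case-folding and U→T; they are excluded from frequency denominators.
    """

    n_a: int
    n_c: int
    n_g: int
    n_t: int
    n_other: int = 0

    def __post_init__(self) -> None:
        for name in ("n_a", "n_c", "n_g", "n_t", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total_acgt(self) -> int:
        return self.n_a + self.n_c + self.n_g + self.n_t


@dataclass(frozen=True)
class BaseComposition:
    """Relative frequencies (a, c, g, t), non-negative and summing to one.

    Inputs whose sum deviates from 1 by more than ~1e-9 are renormalized on
    construction; deviations beyond 1e-6 (e.g. frequencies copied from a
    table printed at limited precision) additionally log a warning.
    """

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        vals = (self.a, self.c, self.g, self.t)
        if any(v < -SUM_TOLERANCE for v in vals):
            raise ValueError(f"negative frequency in {vals}")
        total = sum(vals)
        if total <= 0:
            raise ValueError("frequencies sum to zero")
        if abs(total - 1.0) > SUM_TOLERANCE:
            if abs(total - 1.0) > WARN_TOLERANCE:
                logger.warning(
                    "composition sums to %.6g; renormalizing to 1", total
                )
            for name, v in zip("acgt", vals):
                object.__setattr__(self, name, max(v, 0.0) / total)
        else:
            # clamp tiny negatives within tolerance
            for name, v in zip("acgt", vals):
                if v < 0:
                    object.__setattr__(self, name, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t], dtype=float)

    @property
    def gc(self) -> float:
        """GC content, c + g."""
        return self.c + self.g

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PR2Report:
    """Deviations of one composition from Chargaff's second parity rule.

    All four statistics are reported exactly as computed.  Under exact PR2
    (a = t and c = g) the first three vanish; ``ac_sum`` additionally equals
    0.5 only if a + c = 0.5 holds as a separate constraint.
    """

    delta_at: float
    delta_cg: float
    purine_excess: float
    ac_sum: float


def count_bases(seq: str) -> BaseCounts:
    """Count A/C/G/T occurrences in ``seq``, case-insensitively.

    ``U`` counts as T so RNA input works transparently; every other
    character (IUPAC ambiguity codes, gaps, whitespace) increments
    ``n_other``.  An empty sequence yields all-zero counts.
    """
    up = seq.upper()
    n_a = up.count("A")
    n_c = up.count("C")
    n_g = up.count("G")
    n_t = up.count("T") + up.count("U")
    return BaseCounts(n_a, n_c, n_g, n_t, len(up) - n_a - n_c - n_g - n_t)


def frequencies(counts: BaseCounts) -> BaseComposition:
    """Relative frequencies from counts; ``n_other`` is excluded from the
    denominator so ambiguous characters never dilute the four frequencies.
    """
    n = counts.total_acgt
    if n == 0:
        raise ValueError("no informative (A/C/G/T) bases to derive frequencies from")
    return BaseComposition(
        counts.n_a / n, counts.n_c / n, counts.n_g / n, counts.n_t / n
    )


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement; accepts A/C/G/T/N (any case)."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot complement characters: {sorted(bad)}")
    return up.translate(_COMPLEMENT)[::-1]


def pr2_deviation(comp: BaseComposition) -> PR2Report:
    """PR2 deviation statistics of a composition.

    Returns a − t, c − g, the purine excess (a+g) − (c+t) and the sum a + c.
    No thresholding is applied: small deviations are data, not noise to be
    treated as zero.
    """
    return PR2Report(
        delta_at=comp.a - comp.t,
        delta_cg=comp.c - comp.g,
        purine_excess=(comp.a + comp.g) - (comp.c + comp.t),
        ac_sum=comp.a + comp.c,
    )
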
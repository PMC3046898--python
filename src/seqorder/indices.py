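"""Genome order index S, Shannon entropy, the alpha-order entropy family,
and the PR2-collapsed single-variable forms.

The genome order index is

    S = a^2 + c^2 + g^2 + t^2,

the sum of squared base frequencies: 0.25 at the uniform composition, 1 at a
single-base composition.  It is the alpha = 2 member of the Tsallis-form
alpha-order entropy family

    H_alpha = (sum_i p_i^alpha - 1) / (1 - alpha),

whose alpha → 1 limit is the natural-log Shannon entropy and whose alpha = 2
value is the Gini–Simpson index 1 − S.  Shannon entropy is additive over
independent sources; S is multiplicative (S_joint = S1·S2), which is one
concrete sense in which the two statistics are not interchangeable.

The "reduced" forms collapse S and H to functions of the adenine frequency
alone under the three exact-PR2 constraints a = t, c = g, a + c = 1/2.  Real
sequences satisfy these only approximately, so the collapsed forms generally
disagree with the full four-variable statistics; ``index_discrepancy``
quantifies the gap for a given composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .composition import BaseComposition

__all__ = [
    "IndexBundle",
    "DiscrepancyRecord",
    "genome_order_index",
    "shannon_entropy",
    "alpha_order_entropy",
    "gini_simpson",
    "reduced_index_pr2",
    "reduced_entropy_pr2",
    "index_discrepancy",
    "index_bundle",
]

LogBase = Literal["bits", "nats"]


def _log(x: float, log_base: LogBase) -> float:
    if log_base == "bits":
        return math.log2(x)
    if log_base == "nats":
        return math.log(x)
    raise ValueError(f"unknown log_base {log_base!r} (expected 'bits' or 'nats')")


@dataclass(frozen=True)
class IndexBundle:
    """S, Shannon H and the Gini–Simpson index for one composition."""

    s: float
    shannon: float
    gini_simpson: float
    log_base: LogBase = "bits"


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Full S versus the PR2-collapsed form evaluated at the same ``a``."""

    s_full: float
    s_reduced: float
    difference: float  # s_reduced - s_full, signed
    a_used: float


def genome_order_index(comp: BaseComposition) -> float:
    """S = a² + c² + g² + t²; lies in [0.25, 1]."""
    return comp.a**2 + comp.c**2 + comp.g**2 + comp.t**2


def shannon_entropy(comp: BaseComposition, log_base: LogBase = "bits") -> float:
    """H = −Σ p·log p with the convention 0·log 0 = 0."""
    return -sum(p * _log(p, log_base) for p in comp.as_array() if p > 0.0)


def alpha_order_entropy(comp: BaseComposition, alpha: float) -> float:
    """Tsallis-form alpha-order entropy (Σ pᵅ − 1)/(1 − α), alpha > 0, ≠ 1.

    As alpha → 1 this converges to the natural-log Shannon entropy; at
    alpha = 2 it equals the Gini–Simpson index 1 − S exactly.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use shannon_entropy")
    return (sum(p**alpha for p in comp.as_array() if p > 0.0) - 1.0) / (1.0 - alpha)


def gini_simpson(comp: BaseComposition) -> float:
    """Gini–Simpson index 1 − S: probability two independent draws differ."""
    return 1.0 - genome_order_index(comp)


def reduced_index_pr2(a: float) -> float:
    """S collapsed to one variable under exact PR2 (a = t, c = g, a + c = ½):

        S_red(a) = 2a² + 2(½ − a)².

    Valid only under those constraints; compare with the full S via
    :func:`index_discrepancy` to see how far a real composition strays.
    """
    if not 0.0 <= a <= 0.5:
        raise ValueError(f"a = {a} outside [0, 0.5]")
    return 2.0 * a**2 + 2.0 * (0.5 - a) ** 2


def reduced_entropy_pr2(a: float, log_base: LogBase = "bits") -> float:
    """Shannon H collapsed under exact PR2: −2a·log a − 2(½−a)·log(½−a)."""
    if not 0.0 <= a <= 0.5:
        raise ValueError(f"a = {a} outside [0, 0.5]")
    h = 0.0
    for p in (a, 0.5 - a):
        if p > 0.0:
            h -= 2.0 * p * _log(p, log_base)
    return h


def index_discrepancy(comp: BaseComposition) -> DiscrepancyRecord:
    """Gap between the full S and the PR2-collapsed S_red(comp.a).

    Zero exactly when the composition satisfies a = t, c = g and a + c = ½;
    nonzero otherwise — the collapse discards the PR2 deviations.
    """
    s_full = genome_order_index(comp)
    s_red = reduced_index_pr2(comp.a)
    return DiscrepancyRecord(
        s_full=s_full, s_reduced=s_red, difference=s_red - s_full, a_used=comp.a
    )


def index_bundle(comp: BaseComposition, log_base: LogBase = "bits") -> IndexBundle:
    """All three scalar indices of one composition in a single record."""
    s = genome_order_index(comp)
    return IndexBundle(
        s=s,
        shannon=shannon_entropy(comp, log_base),
        gini_simpson=1.0 - s,
        log_base=log_base,
    )
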
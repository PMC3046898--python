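"""Batch per-genome statistics: composition tables, variance decomposition of
the Z-curve coordinates, inscribed-sphere census and shifted-exponential
modelling of the order-index distribution.

For a cohort of genomes this module reproduces, at any scale, the standard
cross-genome analyses: a per-record table of length, composition, GC
content, S, Shannon H, the reduced mapping point and the sphere verdict;
the attribution of compositional variance to the x (purine/pyrimidine),
y (amino/keto) and z (GC) coordinates, both as raw per-coordinate variance
fractions and as PCA eigenvalue fractions; a census of points inside versus
outside the inscribed sphere, optionally under a wrong radius to reproduce
the consequences of mixing coordinate systems; and the maximum-likelihood
fit of a shifted exponential (support anchored at the theoretical minimum
S = 0.25) to a sample of order-index values.

Audit metadata for the published 235-bacterial-genome cohort (plasmid
accessions that are not genomes, and two corrected GC contents) is exposed
as constants for use with user-downloaded data; nothing here fetches
anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .composition import BaseComposition, count_bases, frequencies
from .geometry import S_THRESHOLD, ReducedPoint, reduced_point
from .indices import genome_order_index, shannon_entropy

__all__ = [
    "VarianceDecomposition",
    "ExponentialFit",
    "SphereCensus",
    "cohort_table",
    "variance_decomposition",
    "sphere_census",
    "fit_shifted_exponential",
    "s_h_correlation",
    "PLASMID_IDS",
    "GC_CORRECTIONS",
]

#: Accessions in the published 235-record table that are plasmids, not
#: genomes; the `cohort` CLI can exclude them via --exclude-ids.
PLASMID_IDS = frozenset(
    {
        "NC_007410", "NC_006873", "NC_004943", "NC_003080", "NC_007414",
        "NC_007515", "NC_007801", "NC_007483", "NC_007274", "NC_007336",
        "NC_007901", "NC_007641", "NC_006855", "NC_007608", "NC_005951",
        "NC_006663", "NC_005229", "NC_004554",
    }
)

#: Corrected GC contents (percent) for two accessions whose published values
#: were wrong; verifiable only against the downloaded sequences.
GC_CORRECTIONS = {
    "NC_006347": 43.27,  # B. fragilis YCH46
    "NC_003030": 30.93,  # C. acetobutylicum ATCC 824
}

COHORT_COLUMNS = [
    "length", "a", "c", "g", "t", "gc", "s", "h", "x", "y", "z", "inside",
]

RecordInput = Union[
    tuple[str, str],
    tuple[str, BaseComposition],
    tuple[str, BaseComposition, int],
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Variance shares of the three mapping coordinates across a cohort.

    ``fractions_by_coordinate`` attributes variance to the named x/y/z
    axes directly; ``pca_eigenfractions`` are the eigenvalue shares of the
    centered covariance matrix, in descending order.  Both are reported
    because "variance accounted for by the z coordinate" admits either
    reading; under near-exact PR2 they nearly coincide, since x and y are
    then pinned near zero.
    """

    fractions_by_coordinate: tuple[float, float, float]
    pca_eigenfractions: tuple[float, float, float]
    n: int


@dataclass(frozen=True)
class ExponentialFit:
    """MLE of a shifted exponential for order-index values.

    The lower bound is fixed at the theoretical minimum S = 0.25 rather
    than estimated, so lambda_hat = 1 / mean(S − 0.25).
    """

    lambda_hat: float
    lower_bound: float
    n: int


@dataclass(frozen=True)
class SphereCensus:
    """Counts of cohort points inside/outside the inscribed sphere."""

    n_inside: int
    n_outside: int
    outside_fraction: float
    radius_used: Optional[float]  # None for the canonical S < 1/3 criterion


def _record_row(item: RecordInput) -> tuple[str, Optional[int], BaseComposition]:
    if len(item) == 2:
        rid, payload = item
        extra = None
    else:
        rid, payload, extra = item
    if isinstance(payload, BaseComposition):
        return str(rid), extra, payload
    if isinstance(payload, str):
        counts = count_bases(payload)
        return str(rid), len(payload), frequencies(counts)
    raise TypeError(
        f"record {rid!r}: expected a sequence string or BaseComposition, "
        f"got {type(payload).__name__}"
    )


def cohort_table(records: Iterable[RecordInput]) -> pd.DataFrame:
    """Per-record statistics table indexed by id.

    ``records`` are ``(id, sequence)``, ``(id, composition)`` or
    ``(id, composition, length)`` tuples.  Columns: length, the four
    frequencies, gc, s, h (bits), the reduced point x/y/z and the
    inscribed-sphere flag ``inside`` (S < 1/3).
    """
    rows = {}
    lengths = {}
    for item in records:
        rid, length, comp = _record_row(item)
        if rid in rows:
            raise ValueError(f"duplicate record id {rid!r}")
        pt = reduced_point(comp)
        s = genome_order_index(comp)
        rows[rid] = {
            "a": comp.a, "c": comp.c, "g": comp.g, "t": comp.t,
            "gc": comp.gc,
            "s": s,
            "h": shannon_entropy(comp, "bits"),
            "x": pt.x, "y": pt.y, "z": pt.z,
            "inside": s < S_THRESHOLD,
        }
        lengths[rid] = length
    if not rows:
        raise ValueError("empty cohort")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.insert(0, "length", pd.Series(lengths, dtype="Int64"))
    table.index.name = "id"
    return table[COHORT_COLUMNS]


def _as_point_array(
    points: Union[Sequence[ReducedPoint], np.ndarray, pd.DataFrame]
) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        arr = points[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        first = points[0] if len(points) else None
        if isinstance(first, ReducedPoint):
            arr = np.array([p.as_tuple() for p in points], dtype=float)
        else:
            arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("points must be an (n, 3) collection")
    return arr


def variance_decomposition(
    points: Union[Sequence[ReducedPoint], np.ndarray, pd.DataFrame]
) -> VarianceDecomposition:
    """Per-coordinate variance fractions and PCA eigenfractions of a cohort.

    Uses the unscaled covariance matrix (all three coordinates share units).
    The leading eigenfraction is always at least the largest coordinate
    fraction, by PCA optimality.
    """
    arr = _as_point_array(points)
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    variances = arr.var(axis=0, ddof=1)
    total = variances.sum()
    if total <= 0:
        raise ValueError("degenerate cohort: zero total variance")
    cov = np.cov(arr, rowvar=False, ddof=1)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return VarianceDecomposition(
        fractions_by_coordinate=tuple(variances / total),
        pca_eigenfractions=tuple(eigvals / eigvals.sum()),
        n=n,
    )


def sphere_census(
    table: pd.DataFrame, radius_override: Optional[float] = None
) -> SphereCensus:
    """Count cohort members inside/outside the inscribed sphere.

    Default criterion: S < 1/3 (matches the per-record ``inside`` flag).
    With ``radius_override`` r0, the criterion becomes RMS distance < r0 in
    the reduced system — e.g. r0 = 1/4 reproduces the inflated outside
    count that results from pairing reduced coordinates with the
    original-system radius.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    if radius_override is None:
        inside = table["s"].to_numpy() < S_THRESHOLD
    else:
        if radius_override <= 0:
            raise ValueError("radius_override must be positive")
        xyz = table[["x", "y", "z"]].to_numpy(dtype=float)
        rms = np.sqrt((xyz**2).sum(axis=1) / 3.0)
        inside = rms < radius_override
    n_inside = int(inside.sum())
    n_outside = int(len(inside) - n_inside)
    return SphereCensus(
        n_inside=n_inside,
        n_outside=n_outside,
        outside_fraction=n_outside / len(inside),
        radius_used=radius_override,
    )


def fit_shifted_exponential(s_values: Sequence[float]) -> ExponentialFit:
    """MLE lambda for S ~ 0.25 + Exponential(lambda).

    The support is anchored at the theoretical minimum 0.25, so the MLE is
    simply the reciprocal mean excess: lambda_hat = 1 / mean(S − 0.25).
    """
    arr = np.asarray(list(s_values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to fit")
    if np.any(arr < 0.25):
        raise ValueError("order-index values below the theoretical minimum 0.25")
    mean_excess = float(np.mean(arr - 0.25))
    if mean_excess <= 0:
        raise ValueError("degenerate sample: all values at the lower bound")
    return ExponentialFit(lambda_hat=1.0 / mean_excess, lower_bound=0.25, n=arr.size)


def s_h_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of the per-record order index and Shannon entropy.

    Across genomes the two move in opposite directions (both are smooth
    functions of compositional spread with opposed monotonicity), so the
    correlation is strongly negative for any cohort with GC variation.
    """
    s = table["s"].to_numpy(dtype=float)
    h = table["h"].to_numpy(dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 records")
    if np.std(s) == 0 or np.std(h) == 0:
        raise ValueError("degenerate cohort: zero variance in s or h")
    return float(np.corrcoef(s, h)[0, 1])
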
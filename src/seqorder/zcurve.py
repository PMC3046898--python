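"""Cumulative Z-curve representation of DNA sequences.

The Z-curve is the 3D walk whose n-th point holds the running base-count
differences after n bases:

    x_n = (A+G) − (C+T)   purine vs pyrimidine
    y_n = (A+C) − (G+T)   amino vs keto
    z_n = (A+T) − (G+C)   weak vs strong hydrogen bonding

Each base contributes one of four unit step vectors (A → +1,+1,+1;
C → −1,+1,−1; G → +1,−1,−1; T → −1,−1,+1), so the walk is an exact integer
object: coordinates share the parity of n, the signed step pattern uniquely
identifies the base, and the curve is invertible back to the sequence.  The
endpoint divided by the length equals the reduced-system mapping point of
the sequence's composition.

Coordinates are kept as integer count differences rather than frequencies;
frequency-normalized views are derived where needed.  Ambiguous bases step
(0, 0, 0) so that real genomes with N runs remain mappable, but such tracks
are flagged non-strict and refuse reconstruction, since uniqueness is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .composition import BaseComposition, count_bases, frequencies
from .geometry import ReducedPoint, reduced_point
from .indices import genome_order_index

__all__ = [
    "ZCurveTrack",
    "WindowProfile",
    "zcurve",
    "reconstruct",
    "disparity_curves",
    "windowed_profile",
]

logger = logging.getLogger(__name__)

# step vectors: each base's reduced-system coordinates evaluated on itself
_STEP_BY_BASE = {
    "A": (1, 1, 1),
    "C": (-1, 1, -1),
    "G": (1, -1, -1),
    "T": (-1, -1, 1),
}
_BASE_BY_STEP = {v: k for k, v in _STEP_BY_BASE.items()}

# vectorized lookup tables over ASCII codes (U shares T's row)
_DX = np.zeros(128, dtype=np.int64)
_DY = np.zeros(128, dtype=np.int64)
_DZ = np.zeros(128, dtype=np.int64)
_STRICT = np.zeros(128, dtype=bool)
for _b, (_dx, _dy, _dz) in {**_STEP_BY_BASE, "U": _STEP_BY_BASE["T"]}.items():
    for _ch in (_b, _b.lower()):
        _o = ord(_ch)
        _DX[_o], _DY[_o], _DZ[_o], _STRICT[_o] = _dx, _dy, _dz, True


@dataclass(frozen=True)
class ZCurveTrack:
    """Cumulative Z-curve coordinates after each of N bases.

    ``source_alphabet_strict`` is True iff every input character was an
    unambiguous A/C/G/T (or U); only strict tracks can be reconstructed.
    """

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    source_alphabet_strict: bool

    @property
    def length(self) -> int:
        return len(self.xs)

    def steps(self) -> np.ndarray:
        """(N, 3) array of per-base step vectors (first differences)."""
        coords = np.column_stack([self.xs, self.ys, self.zs])
        return np.diff(coords, axis=0, prepend=np.zeros((1, 3), dtype=np.int64))

    def endpoint(self) -> tuple[int, int, int]:
        if self.length == 0:
            return (0, 0, 0)
        return (int(self.xs[-1]), int(self.ys[-1]), int(self.zs[-1]))

    def endpoint_as_reduced_point(self) -> ReducedPoint:
        """Endpoint divided by N: the composition's reduced mapping point."""
        if self.length == 0:
            raise ValueError("empty track has no normalized endpoint")
        ex, ey, ez = self.endpoint()
        n = self.length
        return ReducedPoint(ex / n, ey / n, ez / n)

    def to_frame(self) -> pd.DataFrame:
        """Per-position table (1-based): position, base, x, y, z.

        The base column is decoded from the step vectors; ambiguous steps
        render as 'N'.
        """
        bases = [
            _BASE_BY_STEP.get((int(dx), int(dy), int(dz)), "N")
            for dx, dy, dz in self.steps()
        ]
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "base": bases,
                "x": self.xs,
                "y": self.ys,
                "z": self.zs,
            }
        )


@dataclass(frozen=True)
class WindowProfile:
    """Sliding-window composition profile.

    ``table`` has one row per window with 1-based inclusive ``start``/``end``
    positions, the window's (a, c, g, t), its order index ``s`` and its
    reduced-system point (x, y, z).
    """

    window_length: int
    step: int
    table: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.table)


def zcurve(seq: str) -> ZCurveTrack:
    """Build the cumulative Z-curve of ``seq``.

    Case-insensitive; U is treated as T.  Ambiguous characters contribute a
    zero step and clear the strict flag.
    """
    codes = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = np.where(codes < 128, codes, 0)
    strict = bool(np.all(_STRICT[codes])) if len(codes) else True
    return ZCurveTrack(
        xs=np.cumsum(_DX[codes]),
        ys=np.cumsum(_DY[codes]),
        zs=np.cumsum(_DZ[codes]),
        source_alphabet_strict=strict,
    )


def reconstruct(track: ZCurveTrack) -> str:
    """Invert a strict Z-curve track back to its sequence.

    Each step's sign pattern identifies one base; any step that is not one
    of the four valid vectors (including the zero step of an ambiguous
    base) is an error, as is a non-strict track.
    """
    if not track.source_alphabet_strict:
        raise ValueError(
            "track contains ambiguous-base steps; reconstruction is not unique"
        )
    out = []
    for dx, dy, dz in track.steps():
        key = (int(dx), int(dy), int(dz))
        base = _BASE_BY_STEP.get(key)
        if base is None:
            raise ValueError(f"step {key} is not a valid Z-curve step vector")
        out.append(base)
    return "".join(out)


def disparity_curves(track: ZCurveTrack) -> pd.DataFrame:
    """Per-position disparity series, 1-based index.

    Columns: ``purine_pyrimidine`` (x), ``amino_keto`` (y) and
    ``weak_strong`` (z, the negative of the cumulative GC excess).
    """
    return pd.DataFrame(
        {
            "purine_pyrimidine": track.xs,
            "amino_keto": track.ys,
            "weak_strong": track.zs,
        },
        index=pd.RangeIndex(1, track.length + 1, name="position"),
    )


def windowed_profile(
    seq: str,
    window_length: int,
    step: int,
    min_window: Optional[int] = None,
) -> WindowProfile:
    """Per-window composition, order index and reduced point along ``seq``.

    Windows start at 1, 1+step, 1+2·step, …; a trailing partial window is
    included only if its length reaches ``min_window`` (default: the full
    ``window_length``, i.e. no partial windows).  Windows with no
    informative bases get NaN statistics with a warning.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if min_window is None:
        min_window = window_length
    n = len(seq)
    rows = []
    start = 0
    while start < n:
        end = min(start + window_length, n)
        if end - start < min_window:
            break
        sub = seq[start:end]
        counts = count_bases(sub)
        if counts.total_acgt == 0:
            logger.warning("window %d-%d has no A/C/G/T bases", start + 1, end)
            comp = None
        else:
            comp = frequencies(counts)
        pt = reduced_point(comp) if comp else None
        rows.append(
            {
                "start": start + 1,
                "end": end,
                "a": comp.a if comp else np.nan,
                "c": comp.c if comp else np.nan,
                "g": comp.g if comp else np.nan,
                "t": comp.t if comp else np.nan,
                "s": genome_order_index(comp) if comp else np.nan,
                "x": pt.x if pt else np.nan,
                "y": pt.y if pt else np.nan,
                "z": pt.z if pt else np.nan,
            }
        )
        start += step
    if not rows:
        logger.warning(
            "sequence of length %d yields no windows at window_length=%d, "
            "min_window=%d",
            n,
            window_length,
            min_window,
        )
    columns = ["start", "end", "a", "c", "g", "t", "s", "x", "y", "z"]
    return WindowProfile(
        window_length=window_length,
        step=step,
        table=pd.DataFrame(rows, columns=columns),
    )
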
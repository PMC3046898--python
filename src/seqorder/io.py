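"""FASTA input (plain or gzipped) and TSV table output."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from Bio import SeqIO

__all__ = ["SequenceRecord", "read_fasta", "write_table"]

logger = logging.getLogger(__name__)

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    sequence: str


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Parse a FASTA file (gzip detected by magic bytes) into records.

    The record id is the first whitespace-delimited token of the header.
    Content before the first header is an error; duplicate ids are an
    error; empty-sequence records are retained with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        # SeqIO silently skips leading non-header content; reject it explicitly
        pos = handle.tell()
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: content before the first FASTA header"
                    )
                break
        handle.seek(pos)
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).replace(" ", "").replace("\t", "")
            if not seq:
                logger.warning("%s: record %r has an empty sequence", path, rec.id)
            records.append(
                SequenceRecord(id=rec.id, description=rec.description, sequence=seq)
            )
    return records


def write_table(
    rows: Union[pd.DataFrame, Sequence[dict]],
    path: Union[str, Path],
    float_format: str | None = None,
) -> None:
    """Write a table as TSV with a deterministic column order.

    ``rows`` is a DataFrame (written with its index when named) or a list
    of dicts, which must all share the same keys.  ``float_format`` (e.g.
    ``"%.3f"``) applies display rounding; by default floats are written at
    full repr precision.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
        index = frame.index.name is not None
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for i, row in enumerate(rows):
                if list(row.keys()) != keys:
                    raise ValueError(f"ragged rows: row {i} keys differ from row 0")
            frame = pd.DataFrame(rows, columns=keys)
        else:
            frame = pd.DataFrame()
        index = False
    frame.to_csv(path, sep="\t", index=index, float_format=float_format)
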
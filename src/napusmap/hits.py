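"""BLAST outfmt-6 tabular hit tables.

Similarity searches themselves are upstream of this package; their
12-column tabular output is the interface.  Hits are carried in a pandas
DataFrame with the standard columns plus three derived ones:

* ``strand`` -- '+' or '-', decoded from sstart > send;
* ``tstart``/``tend`` -- target span as 0-based half-open ascending
  coordinates (the file's 1-based inclusive, possibly descending,
  coordinates are preserved in sstart/send);
* ``evalue_exponent`` -- log10 of the e-value, the scale used everywhere
  internally to avoid float underflow.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_MIN_EXPONENT = -400.0  # stand-in for log10(0) when a tool prints evalue 0


class HitFormatError(ValueError):
    """A hit file row cannot be parsed."""


@dataclasses.dataclass(frozen=True)
class HitRecord:
    """A single similarity hit (coordinates 0-based half-open, ascending)."""

    query_id: str
    target_id: str
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    evalue_exponent: float
    bitscore: float


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    minus = df["sstart"] > df["send"]
    df["strand"] = np.where(minus, "-", "+")
    lo = np.minimum(df["sstart"], df["send"])
    hi = np.maximum(df["sstart"], df["send"])
    df["tstart"] = lo - 1          # 1-based inclusive -> 0-based half-open
    df["tend"] = hi
    with np.errstate(divide="ignore"):
        df["evalue_exponent"] = np.where(
            df["evalue"] > 0, np.log10(df["evalue"]), _MIN_EXPONENT
        )
    return df


def hit_frame(records: list[dict]) -> pd.DataFrame:
    """Build a derived hit table from raw outfmt-6 style row dicts."""
    df = pd.DataFrame.from_records(records, columns=OUTFMT6_COLUMNS)
    return _derive(df)


def load_hits(path: str | Path, best_only: bool = False) -> pd.DataFrame:
    """Read a 12-column BLAST tabular file.

    Minus-strand rows (sstart > send) are normalised to ascending
    ``tstart``/``tend`` plus a strand flag.  With ``best_only`` each query
    keeps its single best hit: lowest e-value, then highest bitscore,
    then lexicographically smallest target id, then smallest target start.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS, dtype=str,
                     comment="#")
    if df.isna().any(axis=None):
        lineno = int(df.isna().any(axis=1).idxmax()) + 1
        raise HitFormatError(f"{path}:{lineno}: expected 12 tab-separated columns")
    numeric_int = ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"]
    numeric_float = ["pident", "evalue", "bitscore"]
    for col in numeric_int + numeric_float:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise HitFormatError(
                f"{path}:{lineno}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = converted.astype(int if col in numeric_int else float)
    df = _derive(df)
    if best_only:
        df = best_hits(df)
    return df


def best_hits(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic best hit per query (see :func:`load_hits` tie-breaks)."""
    if df.empty:
        return df
    ordered = df.sort_values(
        by=["qseqid", "evalue", "bitscore", "sseqid", "tstart"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("qseqid", as_index=False, sort=True).head(1).reset_index(drop=True)


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    """Write the 12 outfmt-6 columns (minus strand re-encoded as sstart > send)."""
    df[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
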
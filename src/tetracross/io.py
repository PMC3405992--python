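"""CSV and configuration I/O with validation.

Schemas (comma-delimited, UTF-8, required header):

* tetrad table (wide): ``tetrad_id, s1_<m1>, s1_<m2>, ..., s4_<mk>, qc``
  with 0/1 marker-presence entries; rows that do not segregate 2:2 for
  every marker are marked ``qc=aberrant`` on read, never dropped silently.
* interval counts: ``interval, PD, TT, NPD`` (thousands separators such
  as "11,672" are accepted on read, never written).
* cytology: ``cell_id, genotype, chiasmata, univalents``.
* summary: ``group, mean, sd, n`` (chiasma or foci summaries).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
import yaml

from .tetrads import IntervalCounts

log = logging.getLogger("tetracross")

__all__ = [
    "ParseError",
    "marker_names_from_header",
    "read_tetrad_csv",
    "write_tetrad_csv",
    "read_counts_csv",
    "read_cytology_csv",
    "write_cytology_csv",
    "read_summary_csv",
    "load_config",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending row and column."""


_SPORE_COL = re.compile(r"^s([1-4])_(.+)$")


def marker_names_from_header(columns: list[str]) -> list[str]:
    """Marker names in spore-column order, validated for a full 4-spore set."""
    per_spore: dict[int, list[str]] = {1: [], 2: [], 3: [], 4: []}
    for c in columns:
        m = _SPORE_COL.match(c)
        if m:
            per_spore[int(m.group(1))].append(m.group(2))
    markers = per_spore[1]
    if not markers:
        raise ParseError("no spore columns (s1_<marker> ...) found in header")
    for s in (2, 3, 4):
        if per_spore[s] != markers:
            raise ParseError(
                f"spore {s} columns {per_spore[s]} do not match spore 1 {markers}"
            )
    return markers


def read_tetrad_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a wide tetrad table.

    Marker-presence values must be 0 or 1; a violation raises
    :class:`ParseError` naming the row and column.  Rows violating 2:2
    segregation for any marker are marked ``qc=aberrant`` (and counted in
    the log), not dropped.
    """
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    if "tetrad_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'tetrad_id'")
    markers = marker_names_from_header(list(df.columns))
    spore_cols = [f"s{s}_{m}" for s in range(1, 5) for m in markers]
    for col in spore_cols:
        vals = df[col].str.strip()
        bad = ~vals.isin(["0", "1"])
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: invalid value {df.at[row, col]!r} in column {col!r}, "
                f"row {row + 2} (expected 0 or 1)"
            )
        df[col] = vals.astype(int)
    # 2:2 segregation per marker
    ok = pd.Series(True, index=df.index)
    for m in markers:
        ok &= sum(df[f"s{s}_{m}"] for s in range(1, 5)) == 2
    df["qc"] = ok.map({True: "ok", False: "aberrant"})
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("%s: %d aberrant (non-2:2) tetrads flagged", path, n_bad)
    return df


def write_tetrad_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def _parse_count(value: object, path: Path, row: int, col: str) -> int:
    s = str(value).strip().replace(",", "")
    try:
        f = float(s)
    except ValueError:
        raise ParseError(f"{path}: non-numeric count {value!r} at row {row}, column {col!r}")
    if f < 0 or f != int(f):
        raise ParseError(
            f"{path}: count must be a non-negative integer, got {value!r} "
            f"at row {row}, column {col!r}"
        )
    return int(f)


def read_counts_csv(path: str | Path) -> list[IntervalCounts]:
    """Read per-interval PD/TT/NPD counts; n is the row sum (must be > 0).

    An optional ``genotype`` column is folded into the interval id as
    ``"<interval>:<genotype>"``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    for col in ("interval", "PD", "TT", "NPD"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out = []
    for i, row in df.iterrows():
        iv = str(row["interval"]).strip()
        if "genotype" in df.columns and str(row["genotype"]).strip():
            iv = f"{iv}:{str(row['genotype']).strip()}"
        counts = IntervalCounts(
            iv,
            *(_parse_count(row[c], path, int(i) + 2, c) for c in ("PD", "TT", "NPD")),
        )
        if counts.n == 0:
            raise ParseError(f"{path}: interval {iv!r} has n = 0 classified tetrads")
        out.append(counts)
    return out


def read_cytology_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("cell_id", "genotype", "chiasmata", "univalents"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def write_cytology_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_summary_csv(path: str | Path) -> pd.DataFrame:
    """Read a ``group, mean, sd, n`` summary table."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("group", "mean", "sd", "n"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return df


def load_config(path: str | Path) -> dict:
    """Load a structured (YAML) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg
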
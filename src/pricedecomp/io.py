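"""CSV round-trips for every table in the pipeline.

All tables are UTF-8 CSV with a header row, no index column, and empty
fields for missing values.  Provenance (seed, config hash, counts) is
embedded as ``# key=value`` comment lines before the header; readers skip
and optionally return them.

The period-author matrix is serialized long-form — one row per non-missing
cell (period_start, author_id, trait, value, observed_flag) — with the grid
geometry in the comment header, which round-trips the matrix losslessly
including the distinction between observed and interpolated cells.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .periods import PeriodAuthorMatrix, PeriodGrid

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "read_works",
]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with optional ``# key=value`` header lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_table(
    path: str | Path, required: tuple[str, ...] = ()
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV written by :func:`write_table`; returns (frame, meta).

    Raises a ``ValueError`` naming the file and the missing column when a
    required column is absent.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            lines.append(line)
    if not lines:
        raise ValueError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("".join(lines)), float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r} (line 1)")
    return df, meta


def read_works(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a works table, validating its schema and trait-value ranges."""
    df, meta = read_table(path, required=("work_id", "author_id", "year"))
    from .periods import trait_columns

    for col in trait_columns(df):
        vals = df[col]
        if vals.isna().all():
            raise ValueError(f"{path}: trait column {col!r} is entirely empty")
        bad = vals.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"{path}: trait column {col!r} has values outside [0, 1]")
    return df, meta


def write_matrix(
    matrix: PeriodAuthorMatrix, path: str | Path, meta: dict | None = None
) -> None:
    """Serialize a period-author matrix long-form (one row per filled cell)."""
    rows = []
    observed = matrix.observed
    for trait, frame in matrix.values.items():
        stacked = frame.stack()
        obs = observed.stack().reindex(stacked.index)
        for (period, author), value in stacked.items():
            rows.append(
                {
                    "period_start": int(period),
                    "author_id": author,
                    "trait": trait,
                    "value": value,
                    "observed_flag": int(bool(obs.loc[(period, author)])),
                }
            )
    df = pd.DataFrame(
        rows, columns=["period_start", "author_id", "trait", "value", "observed_flag"]
    )
    full_meta = {
        "grid_start": matrix.grid.start_year,
        "grid_end": matrix.grid.end_year,
        "grid_width": matrix.grid.width,
        "interpolated": int(matrix.interpolated),
    }
    full_meta.update(meta or {})
    write_table(df, path, full_meta)


def read_matrix(path: str | Path) -> PeriodAuthorMatrix:
    """Inverse of :func:`write_matrix` (lossless on values, mask and grid)."""
    df, meta = read_table(
        path, required=("period_start", "author_id", "trait", "value", "observed_flag")
    )
    grid = PeriodGrid(
        start_year=int(meta["grid_start"]),
        end_year=int(meta["grid_end"]),
        width=int(meta["grid_width"]),
    )
    starts = pd.Index(grid.period_starts, name="period_start")
    authors = np.sort(df["author_id"].unique())
    values: dict[str, pd.DataFrame] = {}
    for trait, sub in df.groupby("trait", sort=True):
        frame = sub.pivot(index="period_start", columns="author_id", values="value")
        values[str(trait)] = frame.reindex(index=starts, columns=authors)
    obs_rows = df.drop_duplicates(["period_start", "author_id"])[
        ["period_start", "author_id", "observed_flag"]
    ]
    observed = (
        obs_rows.pivot(index="period_start", columns="author_id", values="observed_flag")
        .reindex(index=starts, columns=authors)
        .fillna(0)
        .astype(bool)
    )
    return PeriodAuthorMatrix(
        grid=grid,
        values=values,
        observed=observed,
        interpolated=bool(int(meta.get("interpolated", "0"))),
    )
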
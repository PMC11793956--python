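"""Construction of the period-author matrix.

The decomposition operates on a panel of per-period, per-author mean trait
values: the timeline is cut into fixed-width periods (5 years by default),
each author's works within a period are averaged per trait, authors observed
in only one period are dropped, and interior gaps in an author's career are
filled by linear interpolation (no extrapolation beyond the first/last
observed period).

Periods are half-open intervals [start, start + width), labeled by their
start year.  Interpolated cells remain distinguishable from observed cells
through the ``observed`` mask.

Also provides the adapters for externally derived topic tables: averaging
chunk-level topic proportions up to books, and uniform per-period subsampling
of a works table to counter uneven temporal coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WorkRecord",
    "PeriodGrid",
    "PeriodAuthorMatrix",
    "aggregate_chunks",
    "uniform_sample",
    "build_matrix",
    "drop_single_period_authors",
    "interpolate_gaps",
    "trait_columns",
]

logger = logging.getLogger(__name__)

_META_COLUMNS = frozenset({"work_id", "author_id", "year", "book_id", "chunk_id"})


@dataclass(frozen=True)
class WorkRecord:
    """One work: author, publication year and trait values in [0, 1]."""

    work_id: int | str
    author_id: int | str
    year: float
    trait_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.year):
            raise ValueError("year must be finite")
        for name, v in self.trait_values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait {name!r} value {v} outside [0, 1]")


@dataclass(frozen=True)
class PeriodGrid:
    """Evenly spaced half-open periods [start, start+width) covering a window."""

    start_year: int
    end_year: int
    width: int = 5

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if (self.end_year - self.start_year) % self.width != 0:
            raise ValueError("(end_year - start_year) must be divisible by width")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")

    @property
    def n_periods(self) -> int:
        return (self.end_year - self.start_year) // self.width

    @property
    def period_starts(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year, self.width)

    def period_index(self, year: np.ndarray | float) -> np.ndarray:
        """Index of the period containing each year (may fall outside grid)."""
        return np.floor(
            (np.asarray(year, dtype=float) - self.start_year) / self.width
        ).astype(int)


def trait_columns(works: pd.DataFrame) -> list[str]:
    """Names of the trait columns of a works (or chunks) table."""
    return [c for c in works.columns if c not in _META_COLUMNS]


@dataclass
class PeriodAuthorMatrix:
    """Periods x authors panel of trait values, plus the observation mask.

    ``values`` maps each trait name to a DataFrame indexed by period start
    year with one column per author; missing cells are NaN.  ``observed`` is
    a boolean frame of the same shape marking cells backed by actual works —
    it is recorded at build time and never altered by interpolation.
    """

    grid: PeriodGrid
    values: dict[str, pd.DataFrame]
    observed: pd.DataFrame
    interpolated: bool = False

    @property
    def traits(self) -> list[str]:
        return list(self.values)

    @property
    def authors(self) -> list:
        return list(self.observed.columns)

    def active_mask(self) -> pd.DataFrame:
        """Boolean periods x authors frame of activity.

        Before interpolation, active == observed.  After interpolation, an
        author is active in every period from their first to their last
        observed one (interior gaps were filled).
        """
        if not self.interpolated:
            return self.observed.copy()
        first = next(iter(self.values.values()))
        return first.notna()


def aggregate_chunks(chunks: pd.DataFrame) -> pd.DataFrame:
    """Average chunk-level topic proportions up to one row per book.

    ``chunks`` has columns book_id, chunk_id and one column per topic; the
    result has one row per book with the unweighted mean of each topic over
    that book's chunks.
    """
    if chunks.empty:
        return chunks.drop(columns=["chunk_id"], errors="ignore").iloc[0:0]
    traits = trait_columns(chunks)
    vals = chunks[traits].to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ValueError("chunk trait values must lie in [0, 1]")
    out = chunks.groupby("book_id", as_index=False, sort=True)[traits].mean()
    return out


def uniform_sample(
    works: pd.DataFrame,
    grid: PeriodGrid,
    n_per_period: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simple random sample of at most ``n_per_period`` works per period.

    Counters uneven temporal coverage before any pooled model fit.  Periods
    with fewer than ``n_per_period`` works keep everything.  Sampling is
    without replacement and deterministic given the generator state.
    """
    if n_per_period < 1:
        raise ValueError("n_per_period must be >= 1")
    idx = grid.period_index(works["year"].to_numpy())
    keep_parts = []
    for p in range(grid.n_periods):
        rows = works.index[idx == p]
        if len(rows) > n_per_period:
            rows = rng.choice(rows, size=n_per_period, replace=False)
        keep_parts.append(np.sort(rows))
    keep = np.concatenate(keep_parts) if keep_parts else np.empty(0, dtype=int)
    return works.loc[np.sort(keep)]


def build_matrix(
    works: pd.DataFrame,
    grid: PeriodGrid,
    on_out_of_grid: str = "drop",
) -> PeriodAuthorMatrix:
    """Bin works into periods and average trait values per author-period cell.

    Cell (p, a) holds the mean trait value over author a's works with year in
    [p_start, p_start + width); cells with no works are NaN.  Works outside
    the grid are dropped with a logged count (``on_out_of_grid="drop"``) or
    raise (``"error"``).
    """
    traits = trait_columns(works)
    idx = grid.period_index(works["year"].to_numpy())
    inside = (idx >= 0) & (idx < grid.n_periods)
    n_out = int((~inside).sum())
    if n_out:
        if on_out_of_grid == "error":
            raise ValueError(f"{n_out} works fall outside the period grid")
        logger.info("dropped %d works outside the period grid", n_out)
    w = works.loc[inside].copy()
    w["_period"] = grid.period_starts[idx[inside]]

    authors = np.sort(w["author_id"].unique())
    starts = pd.Index(grid.period_starts, name="period_start")
    cell_means = w.groupby(["_period", "author_id"], sort=True)[traits].mean()
    values: dict[str, pd.DataFrame] = {}
    for t in traits:
        frame = cell_means[t].unstack("author_id")
        frame = frame.reindex(index=starts, columns=authors)
        values[t] = frame
    if traits:
        observed = values[traits[0]].notna()
    else:
        counts = w.groupby(["_period", "author_id"]).size().unstack("author_id")
        observed = counts.reindex(index=starts, columns=authors).notna()
    observed.index = starts
    return PeriodAuthorMatrix(grid=grid, values=values, observed=observed)


def drop_single_period_authors(matrix: PeriodAuthorMatrix) -> PeriodAuthorMatrix:
    """Remove authors observed (pre-interpolation) in exactly one period.

    A single observed period gives no within-author change and no anchor pair
    for interpolation.  Idempotent.
    """
    n_obs = matrix.observed.sum(axis=0)
    keep = n_obs[n_obs >= 2].index
    dropped = len(matrix.observed.columns) - len(keep)
    if dropped:
        logger.info("dropped %d single-period authors", dropped)
    return PeriodAuthorMatrix(
        grid=matrix.grid,
        values={t: v[keep].copy() for t, v in matrix.values.items()},
        observed=matrix.observed[keep].copy(),
        interpolated=matrix.interpolated,
    )


def interpolate_gaps(matrix: PeriodAuthorMatrix) -> PeriodAuthorMatrix:
    """Fill interior career gaps by linear interpolation on period index.

    For each author and trait, missing cells strictly between the first and
    last observed period are interpolated linearly; nothing is extrapolated
    outside the observed span.  The observation mask is preserved verbatim so
    filled cells remain distinguishable.
    """
    values = {
        t: v.interpolate(method="linear", axis=0, limit_area="inside")
        for t, v in matrix.values.items()
    }
    return PeriodAuthorMatrix(
        grid=matrix.grid,
        values=values,
        observed=matrix.observed.copy(),
        interpolated=True,
    )
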
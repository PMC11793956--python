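"""Stochastic simulation of author careers.

The demographic model: authors enter a population at entry years drawn
uniformly over a calendar window, remain active for a Gompertz-distributed
career length, and publish works at the event times of a homogeneous Poisson
process over their career.  Productivity rates are heterogeneous across
authors (exponentially distributed), so the marginal work counts are
geometric-like rather than Poisson.

The Gompertz law is parameterized by a dimensionless shape ``eta`` and a
per-year rate ``b`` with survival function

    S(t) = exp(-eta * (exp(b*t) - 1)),

the standard demographic form with exponentially increasing hazard
``eta*b*exp(b*t)``.  With the defaults eta=1/20 and b=1/17 and a career-start
age of 19 years this yields human-like lifespans of about 63 +/- 17 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "AuthorCareer",
    "sample_career_lengths",
    "generate_work_times",
    "simulate_population",
    "count_active",
    "population_to_frames",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the demographic simulation.

    Attributes
    ----------
    n_authors:
        Number of authors to simulate (>= 1).
    entry_window:
        Calendar interval ``(start, end)`` over which entry years are drawn
        i.i.d. uniform.
    career_start_age:
        Age (years) at which an author may publish a first work; an author's
        birth year is ``entry_year - career_start_age``.
    gompertz_eta, gompertz_b:
        Shape (dimensionless) and rate (1/year) of the Gompertz career-length
        law.
    career_model:
        ``"gompertz"`` for the realistic heterogeneous career lengths,
        ``"fixed"`` for a degenerate population in which every career lasts
        exactly ``fixed_career_length`` years, or ``"uniform"`` for lengths
        uniform on ``[1, 2*fixed_career_length - 1]`` (same mean, bounded
        spread).
    fixed_career_length:
        Career length (years) used by the ``fixed`` and ``uniform`` models.
    productivity_mean:
        Mean of the exponential distribution of per-author Poisson work rates
        (works per year).  The default 0.1 is one work per decade.
    seed:
        Seed for the simulation's random generator; identical seeds give
        identical populations.
    """

    n_authors: int = 10_000
    entry_window: tuple[float, float] = (1850.0, 2000.0)
    career_start_age: float = 19.0
    gompertz_eta: float = 1.0 / 20.0
    gompertz_b: float = 1.0 / 17.0
    career_model: Literal["gompertz", "fixed", "uniform"] = "gompertz"
    fixed_career_length: float = 44.0
    productivity_mean: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_authors < 1:
            raise ValueError("n_authors must be >= 1")
        lo, hi = self.entry_window
        if not lo < hi:
            raise ValueError("entry_window start must precede end")
        for name in ("gompertz_eta", "gompertz_b", "fixed_career_length",
                     "career_start_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.productivity_mean < 0:
            raise ValueError("productivity_mean must be >= 0")
        if self.career_model not in ("gompertz", "fixed", "uniform"):
            raise ValueError(f"unknown career_model {self.career_model!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class AuthorCareer:
    """One simulated author: entry, span, productivity and work times."""

    author_id: int
    entry_year: float
    career_length: float
    productivity_rate: float
    birth_year: float = field(default=float("nan"))
    work_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def exit_year(self) -> float:
        return self.entry_year + self.career_length


def sample_career_lengths(
    n: int, eta: float, b: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` i.i.d. Gompertz career lengths by inverse-CDF sampling.

    With survival S(t) = exp(-eta*(e^{b t} - 1)) the inverse CDF applied to a
    uniform variate U is

        T = (1/b) * ln(1 - ln(U) / eta).

    U is uniform on (0, 1); U -> 1 gives T -> 0 and U -> 0 gives long careers.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if eta <= 0 or b <= 0:
        raise ValueError("eta and b must be > 0")
    # Map uniform on [0,1) to (0,1] so log() never sees 0.
    u = 1.0 - rng.random(n)
    return np.log1p(-np.log(u) / eta) / b


def generate_work_times(career: AuthorCareer, rng: np.random.Generator) -> np.ndarray:
    """Poisson-process work times over one career, sorted ascending.

    Draws N ~ Poisson(rate * length), then places the N events i.i.d. uniform
    on [entry, entry + length] — the conditional law of a homogeneous Poisson
    process given its event count.
    """
    if career.career_length <= 0:
        raise ValueError("career_length must be > 0")
    if career.productivity_rate < 0:
        raise ValueError("productivity_rate must be >= 0")
    n = rng.poisson(career.productivity_rate * career.career_length)
    if n == 0:
        return np.empty(0)
    times = career.entry_year + rng.random(n) * career.career_length
    times.sort()
    return times


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[AuthorCareer]:
    """Simulate a full author population under ``config``.

    Entry years are i.i.d. uniform on the entry window; career lengths follow
    the configured model; productivity rates are i.i.d. exponential with mean
    ``productivity_mean``; work times follow per-author Poisson processes.
    Deterministic given ``config.seed`` (when ``rng`` is not supplied).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_authors
    lo, hi = config.entry_window
    entry = lo + rng.random(n) * (hi - lo)
    if config.career_model == "gompertz":
        length = sample_career_lengths(n, config.gompertz_eta, config.gompertz_b, rng)
    elif config.career_model == "fixed":
        length = np.full(n, float(config.fixed_career_length))
    else:  # uniform: same mean as fixed, spread over [1, 2*mean - 1]
        half = config.fixed_career_length - 1.0
        if half < 0:
            raise ValueError("fixed_career_length must be >= 1 for uniform model")
        length = config.fixed_career_length + (2.0 * rng.random(n) - 1.0) * half
    rate = rng.exponential(config.productivity_mean, n)

    # Vectorized Poisson-process sampling: one batch of counts, one batch of
    # uniforms, split per author.  Same law as generate_work_times per career.
    counts = rng.poisson(rate * length)
    flat = rng.random(int(counts.sum()))
    offsets = np.concatenate(([0], np.cumsum(counts)))

    population: list[AuthorCareer] = []
    for i in range(n):
        u = flat[offsets[i]:offsets[i + 1]]
        times = entry[i] + u * length[i]
        times.sort()
        population.append(
            AuthorCareer(
                author_id=i,
                entry_year=float(entry[i]),
                career_length=float(length[i]),
                productivity_rate=float(rate[i]),
                birth_year=float(entry[i] - config.career_start_age),
                work_times=times,
            )
        )
    return population


def count_active(population: Sequence[AuthorCareer], year: float) -> int:
    """Number of authors whose career interval contains ``year``."""
    return sum(1 for a in population if a.entry_year <= year <= a.exit_year)


def population_to_frames(
    population: Sequence[AuthorCareer],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate a population as (authors, works) DataFrames.

    The authors table has one row per author (author_id, entry_year,
    career_length, birth_year, productivity_rate); the works table one row per
    work (work_id, author_id, year), ordered by author then time.
    """
    authors = pd.DataFrame(
        {
            "author_id": [a.author_id for a in population],
            "entry_year": [a.entry_year for a in population],
            "career_length": [a.career_length for a in population],
            "birth_year": [a.birth_year for a in population],
            "productivity_rate": [a.productivity_rate for a in population],
        }
    )
    n_works = sum(len(a.work_times) for a in population)
    author_col = np.empty(n_works, dtype=np.int64)
    year_col = np.empty(n_works, dtype=float)
    pos = 0
    for a in population:
        k = len(a.work_times)
        author_col[pos:pos + k] = a.author_id
        year_col[pos:pos + k] = a.work_times
        pos += k
    works = pd.DataFrame(
        {
            "work_id": np.arange(n_works, dtype=np.int64),
            "author_id": author_col,
            "year": year_col,
        }
    )
    return authors, works
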
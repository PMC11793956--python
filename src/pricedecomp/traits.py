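"""Generative processes that assign a binary trait (topic) to simulated works.

Two processes are built in:

* single-cohort — authors whose careers *begin* near a focal year adopt the
  trait and use it consistently across their whole career.  Adoption
  probability follows a Gaussian kernel on entry year.
* disruptive-event — a trait spikes at an external event year (a war, say)
  and decays exponentially afterwards, regardless of where authors are in
  their careers.

Both operate on a works table (columns work_id, author_id, year) and return a
copy with an added 0/1 trait column.  A generic hook (`assign_custom_trait`)
accepts any per-work probability rule so further processes can be plugged in
without touching this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .careers import AuthorCareer

__all__ = [
    "CohortProcessParams",
    "DisruptiveProcessParams",
    "assign_cohort_trait",
    "assign_disruptive_trait",
    "assign_custom_trait",
    "cohort_adoption_probability",
    "disruptive_probability",
]


@dataclass(frozen=True)
class CohortProcessParams:
    """Single-cohort process: adoption concentrated around a focal entry year.

    ``max_adopt_prob`` is the adoption probability for an author entering
    exactly at ``focal_entry_year``; it falls off as a Gaussian with standard
    deviation ``kernel_sd`` (years).  Adopters use the trait in each work
    independently with ``within_author_use_prob``; non-adopters never do.
    """

    focal_entry_year: float = 1925.0
    kernel_sd: float = 10.0
    max_adopt_prob: float = 0.9
    within_author_use_prob: float = 0.95

    def __post_init__(self) -> None:
        if self.kernel_sd <= 0:
            raise ValueError("kernel_sd must be > 0")
        for p in ("max_adopt_prob", "within_author_use_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must lie in [0, 1]")


@dataclass(frozen=True)
class DisruptiveProcessParams:
    """Disruptive-event process: probability peaks at the event, then decays.

    Works published before ``event_year`` carry the trait with
    ``baseline_prob``; from the event onwards the probability is
    ``baseline + (peak - baseline) * exp(-(t - event)/decay_scale)``.
    """

    event_year: float = 1915.0
    decay_scale: float = 10.0
    peak_prob: float = 0.9
    baseline_prob: float = 0.01

    def __post_init__(self) -> None:
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be > 0")
        if not 0.0 <= self.baseline_prob <= self.peak_prob <= 1.0:
            raise ValueError("need 0 <= baseline_prob <= peak_prob <= 1")


def _entry_years(population: Sequence[AuthorCareer], works: pd.DataFrame) -> np.ndarray:
    entry = {a.author_id: a.entry_year for a in population}
    missing = set(works["author_id"]) - entry.keys()
    if missing:
        raise KeyError(
            f"works reference unknown authors: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return works["author_id"].map(entry).to_numpy(dtype=float)


def cohort_adoption_probability(
    entry_year: np.ndarray | float, params: CohortProcessParams
) -> np.ndarray | float:
    """Gaussian-kernel adoption probability as a function of entry year."""
    z = (np.asarray(entry_year, dtype=float) - params.focal_entry_year) / params.kernel_sd
    return params.max_adopt_prob * np.exp(-0.5 * z * z)


def disruptive_probability(
    year: np.ndarray | float, params: DisruptiveProcessParams
) -> np.ndarray | float:
    """Per-work trait probability under the disruptive-event process."""
    t = np.asarray(year, dtype=float)
    decayed = params.baseline_prob + (params.peak_prob - params.baseline_prob) * np.exp(
        -(t - params.event_year) / params.decay_scale
    )
    return np.where(t < params.event_year, params.baseline_prob, decayed)


def assign_cohort_trait(
    population: Sequence[AuthorCareer],
    works: pd.DataFrame,
    params: CohortProcessParams,
    rng: np.random.Generator,
    column: str = "trait",
) -> pd.DataFrame:
    """Assign a binary trait under the single-cohort process.

    Each author adopts once, with probability given by the Gaussian kernel on
    their entry year; an adopter's works then carry the trait independently
    with the within-author use probability.  Usage is time-invariant within a
    career, which is the signature of a cohort-driven trait.
    """
    _entry_years(population, works)  # referential-integrity check
    ids = np.array([a.author_id for a in population])
    p_adopt = cohort_adoption_probability(
        np.array([a.entry_year for a in population]), params
    )
    adopted = dict(zip(ids.tolist(), (rng.random(len(ids)) < p_adopt).tolist()))
    out = works.copy()
    author_adopted = out["author_id"].map(adopted).to_numpy(dtype=bool)
    use = rng.random(len(out)) < params.within_author_use_prob
    out[column] = (author_adopted & use).astype(np.int8)
    return out


def assign_disruptive_trait(
    population: Sequence[AuthorCareer],
    works: pd.DataFrame,
    params: DisruptiveProcessParams,
    rng: np.random.Generator,
    column: str = "trait",
) -> pd.DataFrame:
    """Assign a binary trait under the disruptive-event process.

    Works carry the trait independently with a probability that depends only
    on the publication year: the baseline before the event, an exponentially
    decaying excess afterwards.  Career stage plays no role.
    """
    _entry_years(population, works)
    out = works.copy()
    p = disruptive_probability(out["year"].to_numpy(), params)
    out[column] = (rng.random(len(out)) < p).astype(np.int8)
    return out


def assign_custom_trait(
    population: Sequence[AuthorCareer],
    works: pd.DataFrame,
    rule: Callable[[AuthorCareer, float, np.random.Generator], float],
    rng: np.random.Generator,
    column: str = "trait",
) -> pd.DataFrame:
    """Extensibility hook: assign a trait via an arbitrary per-work rule.

    ``rule(author, work_year, rng)`` returns the trait value for one work
    (binary or any value in [0, 1]).  Slower than the built-in vectorized
    processes; intended for prototyping additional generative models.
    """
    _entry_years(population, works)
    by_id = {a.author_id: a for a in population}
    out = works.copy()
    out[column] = [
        rule(by_id[aid], yr, rng)
        for aid, yr in zip(out["author_id"], out["year"])
    ]
    return out
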
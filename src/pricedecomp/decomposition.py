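"""Price-equation partition of period-to-period trait change.

For each consecutive pair of periods, the change in the population-mean
trait value decomposes exactly into three demographic effects.  Writing
``n`` for the earlier-period roster size, ``r = |continuing|/n``,
``e = |exiting|/n``, ``i = |entering|/n`` and ``R = n_to/n`` for the growth
rate, the identity is

    R * (mean_to - mean_from) =   i * (mean_entrants - mean_from)   # entrance
                                - e * (mean_exiters  - mean_from)   # exit
                                + r * mean_individual_change        # individual

where ``mean_individual_change`` averages (value_to - value_from) over the
continuing individuals.  The entrance and exit terms are covariances between
the trait and the entry/exit indicators; centering both on the *earlier*
period's mean is the unique convention under which the three terms sum
exactly to R * delta-mean.  The identity holds to machine precision for any
panel, which every function here preserves and the test-suite asserts.

A positive entrance effect means arrivals over-express the trait relative to
the incumbent mean; a positive exit effect means leavers under-express it; a
positive individual effect means continuing individuals increase their own
values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .periods import PeriodAuthorMatrix

__all__ = [
    "PairDecomposition",
    "TraitDecomposition",
    "EffectWeights",
    "classify_transition",
    "decompose_pair",
    "decompose_trait",
    "relative_weights",
    "aggregate_weights",
    "effects_frame",
    "weights_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairDecomposition:
    """All rates, means and effects for one consecutive period pair.

    ``lhs_check`` is R * (mean_to - mean_from); the three effects sum to it
    exactly (up to floating-point rounding).
    """

    period_from: int
    period_to: int
    n_from: int
    n_to: int
    n_continue: int
    n_enter: int
    n_exit: int
    r: float
    e: float
    i: float
    R: float
    mean_from: float
    mean_to: float
    mean_entrants: float
    mean_exiters: float
    mean_individual_change: float
    effect_entrance: float
    effect_exit: float
    effect_individual: float
    lhs_check: float

    @property
    def residual(self) -> float:
        """Identity residual: effect sum minus R * delta-mean."""
        return (
            self.effect_entrance + self.effect_exit + self.effect_individual
            - self.lhs_check
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TraitDecomposition:
    """Per-period trajectory and per-pair effects for one trait."""

    trait: str
    trajectory: pd.Series  # mean trait value over active authors, per period
    pairs: list[PairDecomposition]

    def totals(self) -> dict[str, float]:
        """Summed absolute magnitude of each effect across all pairs."""
        return {
            "entrance": sum(abs(p.effect_entrance) for p in self.pairs),
            "exit": sum(abs(p.effect_exit) for p in self.pairs),
            "individual": sum(abs(p.effect_individual) for p in self.pairs),
        }


@dataclass(frozen=True)
class EffectWeights:
    """Relative magnitudes of the three effects for one trait (sum to 1)."""

    trait: str
    w_entrance: float
    w_exit: float
    w_individual: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w_entrance, self.w_exit, self.w_individual)


def _activity(matrix: PeriodAuthorMatrix) -> pd.DataFrame:
    return matrix.active_mask()


def classify_transition(
    matrix: PeriodAuthorMatrix, period_index: int
) -> tuple[pd.Index, pd.Index, pd.Index, dict[str, float]]:
    """Split the roster at a period boundary and compute demographic rates.

    Returns (continuing, entering, exiting) author indexes for the transition
    from period ``period_index`` to its successor, plus the rates
    ``{"r", "e", "i", "R"}`` relative to the earlier roster.  Raises if the
    earlier roster is empty (rates undefined).
    """
    active = _activity(matrix)
    if not 0 <= period_index < matrix.grid.n_periods - 1:
        raise IndexError("period_index must have a successor within the grid")
    a0 = active.iloc[period_index]
    a1 = active.iloc[period_index + 1]
    continuing = active.columns[a0 & a1]
    entering = active.columns[~a0 & a1]
    exiting = active.columns[a0 & ~a1]
    n_from = int(a0.sum())
    n_to = int(a1.sum())
    if n_from == 0:
        raise ZeroDivisionError(
            f"empty roster in period {period_index}: transition rates undefined"
        )
    rates = {
        "r": len(continuing) / n_from,
        "e": len(exiting) / n_from,
        "i": len(entering) / n_from,
        "R": n_to / n_from,
    }
    return continuing, entering, exiting, rates


def decompose_pair(
    matrix: PeriodAuthorMatrix, trait: str, period_index: int
) -> PairDecomposition:
    """Decompose one consecutive period pair for one trait."""
    if trait not in matrix.values:
        raise KeyError(f"trait {trait!r} not in matrix (has {matrix.traits})")
    continuing, entering, exiting, rates = classify_transition(matrix, period_index)
    v = matrix.values[trait]
    row0 = v.iloc[period_index]
    row1 = v.iloc[period_index + 1]
    n_to = len(continuing) + len(entering)
    mean_from = float(row0.mean())  # skips NaN: mean over the active roster
    mean_to = float(row1.mean()) if n_to else math.nan
    mean_entrants = float(row1[entering].mean()) if len(entering) else math.nan
    mean_exiters = float(row0[exiting].mean()) if len(exiting) else math.nan
    delta = row1[continuing] - row0[continuing]
    mean_change = float(delta.mean()) if len(continuing) else 0.0

    r, e, i, R = rates["r"], rates["e"], rates["i"], rates["R"]
    effect_entrance = i * (mean_entrants - mean_from) if len(entering) else 0.0
    effect_exit = -e * (mean_exiters - mean_from) if len(exiting) else 0.0
    effect_individual = r * mean_change
    starts = matrix.grid.period_starts
    return PairDecomposition(
        period_from=int(starts[period_index]),
        period_to=int(starts[period_index + 1]),
        n_from=int(len(continuing) + len(exiting)),
        n_to=int(len(continuing) + len(entering)),
        n_continue=len(continuing),
        n_enter=len(entering),
        n_exit=len(exiting),
        r=r,
        e=e,
        i=i,
        R=R,
        mean_from=mean_from,
        mean_to=mean_to,
        mean_entrants=mean_entrants,
        mean_exiters=mean_exiters,
        mean_individual_change=mean_change,
        effect_entrance=effect_entrance,
        effect_exit=effect_exit,
        effect_individual=effect_individual,
        # R*(mean_to - mean_from); when the later roster is empty this is
        # exactly 0 (R = 0 and n_to*mean_to vanishes), not 0 * NaN
        lhs_check=R * (mean_to - mean_from) if n_to else 0.0,
    )


def decompose_trait(matrix: PeriodAuthorMatrix, trait: str) -> TraitDecomposition:
    """Decompose a trait's full trajectory into per-pair effects.

    Pairs whose earlier roster is empty are skipped with a warning (their
    rates are undefined); all other consecutive pairs appear exactly once, in
    period order.
    """
    if matrix.grid.n_periods < 2:
        raise ValueError("need at least two periods to decompose")
    v = matrix.values[trait]
    trajectory = v.mean(axis=1)
    pairs: list[PairDecomposition] = []
    for p in range(matrix.grid.n_periods - 1):
        try:
            pairs.append(decompose_pair(matrix, trait, p))
        except ZeroDivisionError:
            logger.warning(
                "skipping pair %d-%d of trait %r: empty earlier roster",
                matrix.grid.period_starts[p],
                matrix.grid.period_starts[p + 1],
                trait,
            )
    return TraitDecomposition(trait=trait, trajectory=trajectory, pairs=pairs)


def relative_weights(td: TraitDecomposition) -> EffectWeights | None:
    """Relative magnitude of each effect: absolute sums normalized to 1.

    w_k = sum_pairs |effect_k| / sum over all effects.  Returns None (with a
    warning) when every effect of every pair is zero.
    """
    totals = td.totals()
    denom = sum(totals.values())
    if denom == 0.0:
        logger.warning("trait %r has all-zero effects: weights undefined", td.trait)
        return None
    return EffectWeights(
        trait=td.trait,
        w_entrance=totals["entrance"] / denom,
        w_exit=totals["exit"] / denom,
        w_individual=totals["individual"] / denom,
    )


def aggregate_weights(weights: list[EffectWeights]) -> dict[str, float]:
    """Component-wise mean and sample s.d. of effect weights across traits.

    Also reports the combined cohort share (entrance + exit means).  With a
    single triple the s.d. is reported as 0.0 and flagged.
    """
    defined = [w for w in weights if w is not None]
    if not defined:
        raise ValueError("no defined weight triples to aggregate")
    arr = np.array([w.as_tuple() for w in defined])  # columns: entrance, exit, indiv
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(defined) > 1 else np.zeros(3)
    return {
        "n_traits": len(defined),
        "mean_entrance": float(mean[0]),
        "mean_exit": float(mean[1]),
        "mean_individual": float(mean[2]),
        "sd_entrance": float(sd[0]),
        "sd_exit": float(sd[1]),
        "sd_individual": float(sd[2]),
        "cohort_share": float(mean[0] + mean[1]),
        "sd_is_degenerate": len(defined) == 1,
    }


def effects_frame(decompositions: list[TraitDecomposition]) -> pd.DataFrame:
    """Long-format effects table: one row per (trait, period pair)."""
    rows = []
    for td in decompositions:
        for p in td.pairs:
            row = {"trait": td.trait}
            row.update(p.to_dict())
            row["residual"] = p.residual
            rows.append(row)
    return pd.DataFrame(rows)


def weights_frame(weights: list[EffectWeights]) -> pd.DataFrame:
    """Weights table: one row per trait with defined weights."""
    return pd.DataFrame(
        [
            {
                "trait": w.trait,
                "w_entrance": w.w_entrance,
                "w_exit": w.w_exit,
                "w_individual": w.w_individual,
            }
            for w in weights
            if w is not None
        ]
    )
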
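"""Data layers for the three standard visualizations.

* decomposition plot — the trait's empirical trajectory with signed effect
  bars anchored on it, so each period-to-period move is visibly sliced into
  entrance, individual-change and exit contributions;
* ternary (simplex) scatter — one barycentric point per trait giving the
  relative magnitudes of the three effects;
* Lexis histogram — 2-D counts of works by publication year and author age.

Every function here is a pure transformation of already-computed tables into
plot-ready layers; rendering to PNG/SVG is a thin matplotlib adapter on top
and is never required for analysis.  Tests assert on layers, not pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import EffectWeights, TraitDecomposition

__all__ = [
    "DecompositionPlotLayers",
    "TernaryPoint",
    "decomposition_plot_layers",
    "ternary_coordinates",
    "lexis_histogram",
    "render_decomposition_plot",
]

# Stacking order of the signed bars within one period pair (fixed for
# reproducibility: positives stack upward in this order, negatives downward).
EFFECT_ORDER = ("entrance", "individual", "exit")


@dataclass
class DecompositionPlotLayers:
    """Plot-ready layers: the trajectory line plus one bar per (pair, effect).

    ``bars`` columns: period_to (anchor), effect, height (signed effect
    value), bottom and top (stacked extents, baselined on the trajectory
    value at the anchor period).
    """

    trajectory: pd.Series
    bars: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass(frozen=True)
class TernaryPoint:
    """Barycentric effect weights with their planar coordinates.

    Corner convention: entrance at (0, 0), individual at (1, 0), exit at
    (1/2, sqrt(3)/2).  Any rotation of the triangle is purely cosmetic.
    """

    trait: str
    w_entrance: float
    w_exit: float
    w_individual: float
    x: float
    y: float


def decomposition_plot_layers(td: TraitDecomposition) -> DecompositionPlotLayers:
    """Stack each pair's signed effects on the trajectory at the later period.

    Positive effects stack upward from the trajectory value at ``period_to``
    in the order entrance, individual, exit; negative ones stack downward in
    the same order.  Bar heights equal the effects exactly, so the signed
    heights of one pair's bars sum to R * delta-mean for that pair.
    """
    if not td.pairs:
        raise ValueError("trait decomposition has no pairs to plot")
    rows = []
    for p in td.pairs:
        base = float(td.trajectory.loc[p.period_to])
        effects = {
            "entrance": p.effect_entrance,
            "individual": p.effect_individual,
            "exit": p.effect_exit,
        }
        up = base
        down = base
        for k in EFFECT_ORDER:
            h = effects[k]
            if h >= 0:
                bottom, top = up, up + h
                up += h
            else:
                bottom, top = down + h, down
                down += h
            rows.append(
                {
                    "period_to": p.period_to,
                    "effect": k,
                    "height": h,
                    "bottom": bottom,
                    "top": top,
                }
            )
    return DecompositionPlotLayers(
        trajectory=td.trajectory.copy(), bars=pd.DataFrame(rows)
    )


def ternary_coordinates(weights: EffectWeights) -> TernaryPoint:
    """Map an effect-weight triple to planar coordinates on the simplex."""
    w_e, w_x, w_i = weights.w_entrance, weights.w_exit, weights.w_individual
    x = w_i + 0.5 * w_x
    y = (math.sqrt(3.0) / 2.0) * w_x
    return TernaryPoint(
        trait=weights.trait,
        w_entrance=w_e,
        w_exit=w_x,
        w_individual=w_i,
        x=x,
        y=y,
    )


def lexis_histogram(
    works: pd.DataFrame,
    author_birth_years: dict | pd.Series,
    year_bin: int = 5,
    age_bin: int = 5,
) -> tuple[pd.DataFrame, int]:
    """2-D counts of works by publication-year bin and author-age bin.

    Age at publication is ``floor(year - birth_year)``.  Works whose author
    has no birth year are excluded and counted in the second return value.
    Bins are half-open, labeled by their lower edge.  The histogram total
    equals the number of works with a known birth year.
    """
    birth = works["author_id"].map(dict(author_birth_years))
    known = birth.notna()
    n_excluded = int((~known).sum())
    w = works.loc[known]
    age = np.floor(w["year"].to_numpy() - birth[known].to_numpy(dtype=float))
    year_lab = (np.floor(w["year"].to_numpy() / year_bin) * year_bin).astype(int)
    age_lab = (np.floor(age / age_bin) * age_bin).astype(int)
    counts = (
        pd.DataFrame({"year_bin": year_lab, "age_bin": age_lab})
        .groupby(["age_bin", "year_bin"])
        .size()
        .unstack("year_bin", fill_value=0)
        .sort_index()
    )
    return counts, n_excluded


def render_decomposition_plot(layers: DecompositionPlotLayers, path: str) -> None:
    """Render layers to an image file (thin matplotlib adapter)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"entrance": "#e08214", "individual": "#7f3b08", "exit": "#8073ac"}
    fig, ax = plt.subplots(figsize=(8, 4))
    traj = layers.trajectory
    ax.plot(traj.index, traj.to_numpy(), color="black", lw=2, zorder=3)
    width = 0.8 * (traj.index[1] - traj.index[0]) if len(traj) > 1 else 1.0
    for _, row in layers.bars.iterrows():
        ax.bar(
            row["period_to"],
            row["top"] - row["bottom"],
            bottom=row["bottom"],
            width=width,
            color=colors[row["effect"]],
            alpha=0.7,
            zorder=2,
        )
    ax.set_xlabel("period")
    ax.set_ylabel("trait frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
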
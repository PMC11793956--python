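"""End-to-end pipeline: simulate -> traits -> matrix -> decompose -> weights.

Each simulated trait gets its own freshly simulated author population (seeded
from a spawn of the run seed, so runs are deterministic and traits are
independent).  The pipeline writes the effects table, the weights table, the
ternary coordinates and a summary JSON (per-effect mean/s.d. weights and the
combined cohort share) into an output directory, alongside the exact config
that produced them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .careers import simulate_population, population_to_frames
from .config import RunConfig, config_hash
from .decomposition import (
    EffectWeights,
    TraitDecomposition,
    aggregate_weights,
    decompose_trait,
    effects_frame,
    relative_weights,
    weights_frame,
)
from .io import write_table
from .periods import build_matrix, drop_single_period_authors, interpolate_gaps
from .plots import ternary_coordinates
from .traits import assign_cohort_trait, assign_disruptive_trait

__all__ = ["simulate_trait_decomposition", "run_pipeline", "weights_from_effects"]

logger = logging.getLogger(__name__)


def simulate_trait_decomposition(
    config: RunConfig, process: str, seed: int, trait_name: str = "trait"
) -> TraitDecomposition:
    """Simulate one population, assign one trait, decompose its trajectory.

    ``process`` is ``"cohort"`` or ``"disruptive"``.  The population is drawn
    under ``config.simulator`` (with ``seed`` in place of its seed), works
    are labeled by the requested generative process, binned on
    ``config.grid``, single-period authors dropped, interior gaps
    interpolated, and the trait decomposed pair by pair.
    """
    rng = np.random.default_rng(seed)
    population = simulate_population(config.simulator.with_seed(seed), rng)
    _, works = population_to_frames(population)
    if process == "cohort":
        works = assign_cohort_trait(population, works, config.cohort, rng,
                                    column=trait_name)
    elif process == "disruptive":
        works = assign_disruptive_trait(population, works, config.disruptive, rng,
                                        column=trait_name)
    else:
        raise ValueError(f"unknown process {process!r}")
    matrix = build_matrix(works[["work_id", "author_id", "year", trait_name]],
                          config.grid)
    matrix = interpolate_gaps(drop_single_period_authors(matrix))
    return decompose_trait(matrix, trait_name)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full simulate-and-decompose study; write all tables + summary.

    Simulates ``n_cohort_traits`` cohort-process traits and
    ``n_disruptive_traits`` disruptive-process traits, each on its own
    population, and writes effects.csv, weights.csv, ternary.csv,
    summary.json and config.yaml to ``out_dir``.  Deterministic given
    ``config.seed``.  Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash, "seed": config.seed}
    n_total = config.n_cohort_traits + config.n_disruptive_traits
    seeds = np.random.SeedSequence(config.seed).generate_state(n_total) % (2**31)

    decomps: list[TraitDecomposition] = []
    weights: list[EffectWeights] = []
    processes = ["cohort"] * config.n_cohort_traits + (
        ["disruptive"] * config.n_disruptive_traits
    )
    with _stage("simulate+decompose"):
        for k, process in enumerate(processes):
            name = f"{process}_{k:03d}"
            td = simulate_trait_decomposition(config, process, int(seeds[k]), name)
            decomps.append(td)
            w = relative_weights(td)
            if w is not None:
                weights.append(w)

    with _stage("write tables"):
        eff = effects_frame(decomps)
        write_table(eff, out / "effects.csv", meta)
        wf = weights_frame(weights)
        wf["process"] = [w.trait.rsplit("_", 1)[0] for w in weights]
        write_table(wf, out / "weights.csv", meta)
        tern = pd.DataFrame(
            [vars(ternary_coordinates(w)) for w in weights]
        )
        write_table(tern, out / "ternary.csv", meta)

    with _stage("summarize"):
        summary = {"config_hash": chash, "seed": config.seed}
        summary["all_traits"] = aggregate_weights(weights)
        for process in ("cohort", "disruptive"):
            sub = [w for w in weights if w.trait.startswith(process)]
            if sub:
                summary[process] = aggregate_weights(sub)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2), encoding="utf-8"
        )
        config.to_yaml(out / "config.yaml")
    logger.info("pipeline wrote %d traits to %s (config %s)", n_total, out, chash)
    return summary


def weights_from_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-trait relative weights from a long-form effects table."""
    sums = effects.groupby("trait")[
        ["effect_entrance", "effect_exit", "effect_individual"]
    ].agg(lambda s: s.abs().sum())
    denom = sums.sum(axis=1)
    keep = denom > 0
    out = pd.DataFrame(
        {
            "trait": sums.index[keep],
            "w_entrance": (sums["effect_entrance"] / denom)[keep].to_numpy(),
            "w_exit": (sums["effect_exit"] / denom)[keep].to_numpy(),
            "w_individual": (sums["effect_individual"] / denom)[keep].to_numpy(),
        }
    ).reset_index(drop=True)
    return out
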
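import numpy as np
import pandas as pd
import pytest

from pricedecomp import PeriodGrid, build_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def works_from_cells(cells, grid_width=5):
    """Build a works table with one work per (author, period_start, value) cell."""
    rows = [
        {"work_id": k, "author_id": a, "year": float(p) + grid_width / 2, "trait": v}
        for k, (a, p, v) in enumerate(cells)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def worked_example_matrix():
    """Six-author, two-period roster: A,B,C persist, D exits, E,F enter.

    Trait values chosen so the pair decomposition can be checked by hand:
    period-1 mean 0.25, period-2 mean 0.3, growth rate R = 5/4.
    """
    cells = [
        ("A", 1900, 0.2), ("B", 1900, 0.4), ("C", 1900, 0.0), ("D", 1900, 0.4),
        ("A", 1905, 0.3), ("B", 1905, 0.5), ("C", 1905, 0.1),
        ("E", 1905, 0.6), ("F", 1905, 0.0),
    ]
    grid = PeriodGrid(1900, 1910, 5)
    return build_matrix(works_from_cells(cells), grid)


def random_panel_matrix(rng, n_authors=4, n_periods=3, grid_start=1900, width=5):
    """Random small period-author matrix via the real construction pipeline.

    Each author is observed in a random contiguous-ish subset of periods (at
    least two, possibly with interior gaps) with uniform trait values.
    """
    cells = []
    for a in range(n_authors):
        periods = rng.permutation(n_periods)[: rng.integers(2, n_periods + 1)]
        for p in np.sort(periods):
            cells.append((f"a{a}", grid_start + width * int(p), float(rng.random())))
    works = works_from_cells(cells, width)
    grid = PeriodGrid(grid_start, grid_start + width * n_periods, width)
    return build_matrix(works, grid)


def brute_force_pair_effects(values_from, values_to):
    """Independent direct-summation oracle for one period pair.

    ``values_from`` / ``values_to`` map author -> trait value for the authors
    active in each period.  Effects are computed as plain per-individual sums
    over the earlier roster size, with no rates or covariance algebra:

        entrance   = sum_{j in enter} (v_to[j]  - mean_from) / n_from
        exit       = -sum_{j in exit} (v_from[j] - mean_from) / n_from
        individual = sum_{j in cont}  (v_to[j]  - v_from[j]) / n_from
    """
    roster0 = set(values_from)
    roster1 = set(values_to)
    n_from = len(roster0)
    mean_from = sum(values_from.values()) / n_from
    entrance = sum(values_to[j] - mean_from for j in roster1 - roster0) / n_from
    exit_ = -sum(values_from[j] - mean_from for j in roster0 - roster1) / n_from
    individual = sum(values_to[j] - values_from[j] for j in roster0 & roster1) / n_from
    return entrance, exit_, individual
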
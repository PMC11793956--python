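import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pricedecomp import (
    EffectWeights,
    PeriodGrid,
    RunConfig,
    aggregate_weights,
    build_matrix,
    classify_transition,
    decompose_pair,
    decompose_trait,
    relative_weights,
    simulate_trait_decomposition,
)
from pricedecomp.decomposition import TraitDecomposition, PairDecomposition

from conftest import brute_force_pair_effects, random_panel_matrix, works_from_cells


class TestClassifyTransition:
    def test_worked_example_rates(self, worked_example_matrix):
        cont, ent, ext, rates = classify_transition(worked_example_matrix, 0)
        assert set(cont) == {"A", "B", "C"}
        assert set(ent) == {"E", "F"}
        assert set(ext) == {"D"}
        assert rates == {"r": 3 / 4, "e": 1 / 4, "i": 2 / 4, "R": 5 / 4}

    def test_identical_rosters(self):
        m = build_matrix(
            works_from_cells([("a", 1900, 0.1), ("a", 1905, 0.2),
                              ("b", 1900, 0.3), ("b", 1905, 0.4)]),
            PeriodGrid(1900, 1910, 5),
        )
        _, _, _, rates = classify_transition(m, 0)
        assert rates["e"] == 0 and rates["i"] == 0 and rates["R"] == 1

    def test_complete_turnover(self):
        cells = [("a", 1900, 0.1), ("b", 1900, 0.2),
                 ("c", 1905, 0.3), ("d", 1905, 0.4), ("e", 1905, 0.5)]
        # keep all authors by skipping the single-period filter (direct build)
        m = build_matrix(works_from_cells(cells), PeriodGrid(1900, 1910, 5))
        _, _, _, rates = classify_transition(m, 0)
        assert rates == {"r": 0.0, "e": 1.0, "i": 3 / 2, "R": 3 / 2}

    def test_empty_roster_raises(self):
        m = build_matrix(
            works_from_cells([("a", 1905, 0.1), ("a", 1910, 0.2)]),
            PeriodGrid(1900, 1915, 5),
        )
        with pytest.raises(ZeroDivisionError):
            classify_transition(m, 0)


class TestDecomposePair:
    def test_worked_example_effects(self, worked_example_matrix):
        p = decompose_pair(worked_example_matrix, "trait", 0)
        assert p.mean_from == pytest.approx(0.25)
        assert p.mean_to == pytest.approx(0.3)
        assert p.effect_entrance == pytest.approx(0.025)
        assert p.effect_exit == pytest.approx(-0.0375)
        assert p.effect_individual == pytest.approx(0.075)
        assert p.lhs_check == pytest.approx(1.25 * 0.05)
        assert abs(p.residual) < 1e-12

    def test_constant_trait_gives_zero_effects(self):
        cells = [(a, p, 0.4) for a in "abc" for p in (1900, 1905)] + [
            ("d", 1900, 0.4), ("e", 1905, 0.4)
        ]
        m = build_matrix(works_from_cells(cells), PeriodGrid(1900, 1910, 5))
        p = decompose_pair(m, "trait", 0)
        assert p.effect_entrance == pytest.approx(0.0, abs=1e-15)
        assert p.effect_exit == pytest.approx(0.0, abs=1e-15)
        assert p.effect_individual == pytest.approx(0.0, abs=1e-15)

    def test_closed_cohort_reduces_to_individual_change(self):
        cells = [("a", 1900, 0.1), ("a", 1905, 0.5),
                 ("b", 1900, 0.3), ("b", 1905, 0.7)]
        m = build_matrix(works_from_cells(cells), PeriodGrid(1900, 1910, 5))
        p = decompose_pair(m, "trait", 0)
        assert p.r == 1.0 and p.R == 1.0
        assert p.effect_entrance == 0.0 and p.effect_exit == 0.0
        assert p.effect_individual == pytest.approx(p.mean_to - p.mean_from)

    def test_unknown_trait(self, worked_example_matrix):
        with pytest.raises(KeyError):
            decompose_pair(worked_example_matrix, "nope", 0)

    def test_exit_term_equals_population_covariance(self, rng):
        # cov(exit indicator, trait) over the earlier roster, population
        # normalization, equals e * (mean_exiters - mean_from) exactly
        for _ in range(20):
            m = random_panel_matrix(rng, n_authors=6, n_periods=3)
            try:
                _, _, exiting, rates = classify_transition(m, 0)
            except ZeroDivisionError:
                continue
            row0 = m.values["trait"].iloc[0].dropna()
            if row0.empty:
                continue
            indicator = row0.index.isin(exiting).astype(float)
            cov = np.mean(indicator * row0.to_numpy()) - indicator.mean() * row0.mean()
            p = decompose_pair(m, "trait", 0)
            assert -cov == pytest.approx(p.effect_exit, abs=1e-14)


class TestBruteForceEquivalence:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_panels_match_direct_summation(self, seed):
        rng = np.random.default_rng(seed)
        m = random_panel_matrix(rng, n_authors=4, n_periods=2)
        v = m.values["trait"]
        v0 = v.iloc[0].dropna().to_dict()
        v1 = v.iloc[1].dropna().to_dict()
        if not v0:
            return
        ent, ext, ind = brute_force_pair_effects(v0, v1)
        p = decompose_pair(m, "trait", 0)
        assert p.effect_entrance == pytest.approx(ent, abs=1e-12)
        assert p.effect_exit == pytest.approx(ext, abs=1e-12)
        assert p.effect_individual == pytest.approx(ind, abs=1e-12)
        assert abs(p.residual) < 1e-12


class TestDecomposeTrait:
    def test_three_periods_two_pairs(self, rng):
        m = random_panel_matrix(rng, n_authors=5, n_periods=3)
        td = decompose_trait(m, "trait")
        assert len(td.pairs) == 2
        assert [(p.period_from, p.period_to) for p in td.pairs] == [
            (1900, 1905), (1905, 1910)
        ]

    def test_cohort_process_dominated_by_turnover_effects(self):
        td = simulate_trait_decomposition(RunConfig(), "cohort", seed=21)
        w = relative_weights(td)
        assert w.w_entrance > w.w_individual
        assert w.w_entrance + w.w_exit > 0.6
        # rising phase driven by positive entrance, falling by negative ones
        rise = max(td.pairs, key=lambda p: p.lhs_check)
        fall = min(td.pairs, key=lambda p: p.lhs_check)
        assert rise.effect_entrance > 0
        assert fall.effect_entrance < 0

    def test_disruptive_process_dominated_by_individual_change(self):
        td = simulate_trait_decomposition(RunConfig(), "disruptive", seed=22)
        w = relative_weights(td)
        assert w.w_individual > 0.5
        spike = max(td.pairs, key=lambda p: p.lhs_check)
        assert spike.effect_individual > 0
        assert spike.effect_individual > abs(spike.effect_exit)


def _fake_td(effects):
    pairs = []
    for k, (ent, ext, ind) in enumerate(effects):
        pairs.append(
            PairDecomposition(
                period_from=1900 + 5 * k, period_to=1905 + 5 * k,
                n_from=2, n_to=2, n_continue=2, n_enter=0, n_exit=0,
                r=1.0, e=0.0, i=0.0, R=1.0,
                mean_from=0.0, mean_to=0.0, mean_entrants=np.nan,
                mean_exiters=np.nan, mean_individual_change=0.0,
                effect_entrance=ent, effect_exit=ext, effect_individual=ind,
                lhs_check=ent + ext + ind,
            )
        )
    traj = pd.Series(0.0, index=range(1900, 1910 + 5 * len(effects), 5))
    return TraitDecomposition("t", traj, pairs)


class TestRelativeWeights:
    def test_pure_individual_change(self):
        w = relative_weights(_fake_td([(0.0, 0.0, 0.3), (0.0, 0.0, -0.1)]))
        assert w.as_tuple() == (0.0, 0.0, 1.0)

    def test_normalization(self):
        w = relative_weights(_fake_td([(2.0, -1.0, 0.5), (0.0, 0.0, 0.5)]))
        assert w.as_tuple() == pytest.approx((0.5, 0.25, 0.25))

    def test_invariant_to_pair_order(self):
        effects = [(0.1, -0.2, 0.05), (-0.3, 0.0, 0.15), (0.0, 0.1, -0.1)]
        a = relative_weights(_fake_td(effects))
        b = relative_weights(_fake_td(effects[::-1]))
        assert a.as_tuple() == pytest.approx(b.as_tuple())

    def test_all_zero_effects_undefined(self):
        assert relative_weights(_fake_td([(0.0, 0.0, 0.0)])) is None


class TestAggregateWeights:
    def test_single_triple(self):
        w = EffectWeights("t", 0.5, 0.2, 0.3)
        agg = aggregate_weights([w])
        assert agg["mean_entrance"] == pytest.approx(0.5)
        assert agg["sd_entrance"] == 0.0
        assert agg["sd_is_degenerate"]

    def test_two_triples(self):
        ws = [EffectWeights("a", 1, 0, 0), EffectWeights("b", 0, 0, 1)]
        agg = aggregate_weights(ws)
        assert agg["mean_entrance"] == pytest.approx(0.5)
        assert agg["mean_exit"] == pytest.approx(0.0)
        assert agg["mean_individual"] == pytest.approx(0.5)
        assert agg["cohort_share"] == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_weights([])
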
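"""Dominance classification and sequential ICERs."""

import math

import numpy as np
import pytest

from neocea.config import DEFAULT_BASELINE_PRETERM_CORRECT as BASELINE
from neocea.effectiveness import Strategy
from neocea.frontier import (
    STATUS_DOMINATED,
    STATUS_EXTENDED,
    STATUS_NONDOMINATED,
    StrategyOutcome,
    classify_dominance,
    default_strategies,
    evaluate_strategies,
    frontier_table,
    sequential_icers,
)

# Published sequential-analysis statuses for the 2500 g-lower-limit family.
EXPECTED_STATUS = {
    "no GA algorithm use": STATUS_NONDOMINATED,
    "2500-2600 g BW": STATUS_EXTENDED,
    "2500-2700 g BW": STATUS_EXTENDED,
    "2500-2800 g BW": STATUS_EXTENDED,
    "2500-2900 g BW": STATUS_NONDOMINATED,
    "2500-3000 g BW": STATUS_DOMINATED,
    "2500-3100 g BW": STATUS_DOMINATED,
    "2500-3200 g BW": STATUS_EXTENDED,
    "2500-3300 g BW": STATUS_NONDOMINATED,
    "2500-3400 g BW": STATUS_DOMINATED,
    "2500-3500 g BW": STATUS_DOMINATED,
    "2500-3600 g BW": STATUS_DOMINATED,
    "2500-3700 g BW": STATUS_DOMINATED,
    "2500-3800 g BW": STATUS_DOMINATED,
    "2500-3900 g BW": STATUS_DOMINATED,
    "2500-4000 g BW": STATUS_DOMINATED,
    "all infants": STATUS_DOMINATED,
}


@pytest.fixture(scope="module")
def classified(cohort, components):
    strategies = default_strategies(high_max_g=4000)
    outcomes = evaluate_strategies(cohort, components, strategies, BASELINE)
    return classify_dominance(outcomes)


class TestSequentialAnalysis:
    def test_statuses_label_for_label(self, classified):
        got = {o.strategy.label: o.status for o in classified}
        assert got == EXPECTED_STATUS

    def test_frontier_members_and_sequential_icers(self, classified):
        frontier = sorted(
            (o for o in classified if o.status == STATUS_NONDOMINATED),
            key=lambda o: o.effect,
        )
        assert [o.strategy.label for o in frontier] == [
            "no GA algorithm use", "2500-2900 g BW", "2500-3300 g BW",
        ]
        chain = sequential_icers(frontier)
        assert math.isnan(chain[0][1])
        assert chain[1][1] == pytest.approx(5625, rel=5e-3)
        assert chain[2][1] == pytest.approx(16_550, rel=5e-3)
        icers = [v for _, v in chain[1:]]
        assert icers == sorted(icers)  # frontier convexity

    def test_narrow_range_extended_dominance_via_pair(self, classified):
        narrow = next(o for o in classified if o.strategy.label == "2500-2600 g BW")
        a, b = narrow.extended_dominated_via
        assert {a.label, b.label} == {"no GA algorithm use", "2500-2900 g BW"}

    def test_baseline_and_all_infants_anchors(self, classified):
        base = next(o for o in classified if o.strategy.kind == "none")
        assert base.cost_usd == 0.0 and base.effect == pytest.approx(BASELINE)
        allx = next(o for o in classified if o.strategy.kind == "all")
        assert allx.cost_usd == pytest.approx(100_031.0)
        assert allx.icer_vs_baseline == pytest.approx(8336, rel=5e-3)

    def test_range_costs_match_tested_volume(self, classified, components):
        narrow = next(o for o in classified if o.strategy.label == "2500-2900 g BW")
        # 493 infants tested annually in [2500, 2900)
        expected = components.ongoing_annual_usd + 493 * components.per_sample_usd
        assert narrow.cost_usd == pytest.approx(expected)
        assert narrow.cost_usd == pytest.approx(60_000, rel=5e-3)


class TestEdgeCases:
    def test_duplicate_strategies_rejected(self, cohort, components):
        dup = [Strategy("none"), Strategy("none")]
        with pytest.raises(ValueError, match="duplicate"):
            evaluate_strategies(cohort, components, dup, BASELINE)

    def test_single_strategy_is_nondominated(self):
        outcomes = [StrategyOutcome(Strategy("none"), 0.0, 10.0)]
        classify_dominance(outcomes)
        assert outcomes[0].status == STATUS_NONDOMINATED

    def test_exact_tie_keeps_narrower_range(self):
        outcomes = [
            StrategyOutcome(Strategy("range", 2500, 2600), 100.0, 5.0),
            StrategyOutcome(Strategy("range", 2500, 3000), 100.0, 5.0),
        ]
        classify_dominance(outcomes)
        by_label = {o.strategy.label: o for o in outcomes}
        assert by_label["2500-2600 g BW"].status == STATUS_NONDOMINATED
        wide = by_label["2500-3000 g BW"]
        assert wide.status == STATUS_DOMINATED
        assert wide.dominated_by.label == "2500-2600 g BW"

    def test_sequential_icers_reject_effect_ties(self):
        outcomes = [
            StrategyOutcome(Strategy("range", 2500, 2600), 0.0, 5.0),
            StrategyOutcome(Strategy("range", 2500, 2700), 10.0, 5.0),
        ]
        with pytest.raises(ValueError, match="tied|degenerate"):
            sequential_icers(outcomes)

    def test_zero_sequential_icer_for_equal_costs(self):
        outcomes = [
            StrategyOutcome(Strategy("range", 2500, 2600), 50.0, 5.0),
            StrategyOutcome(Strategy("range", 2500, 2700), 50.0, 6.0),
        ]
        chain = sequential_icers(outcomes)
        assert chain[1][1] == 0.0

    def test_frontier_table_columns(self, classified):
        tab = frontier_table(classified)
        assert list(tab.columns) == [
            "strategy", "cost_usd", "effect", "icer_vs_baseline",
            "sequential_icer", "status", "note",
        ]
        assert len(tab) == len(classified)


def oracle_frontier(points):
    """Exhaustive lower-convex-hull membership test (independent oracle).

    A point is on the frontier iff no other point weakly dominates it and no
    pair of points brackets it below: for bracketing pair (a, b) with
    effect_a < effect < effect_b, the interpolated cost at its effect is
    strictly lower.
    """
    keep = []
    for i, (e, c) in enumerate(points):
        dominated = any(
            (co <= c and eo >= e and (co < c or eo > e))
            for j, (eo, co) in enumerate(points) if j != i
        )
        if dominated:
            continue
        extended = False
        for j, (ea, ca) in enumerate(points):
            for k, (eb, cb) in enumerate(points):
                if j == k or not (ea < e < eb):
                    continue
                interp = ca + (cb - ca) * (e - ea) / (eb - ea)
                if interp < c:
                    extended = True
        if not extended:
            keep.append(i)
    return set(keep)


class TestAgainstExhaustiveOracle:
    @pytest.mark.parametrize("trial", range(50))
    def test_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(2, 13)
        points = list(zip(rng.uniform(0, 100, n), rng.uniform(0, 1e5, n)))
        outcomes = [
            StrategyOutcome(Strategy("range", 2500, 2600 + 100 * i), c, e)
            for i, (e, c) in enumerate(points)
        ]
        classify_dominance(outcomes)
        got = {
            i for i, o in enumerate(outcomes) if o.status == STATUS_NONDOMINATED
        }
        assert got == oracle_frontier(points)
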
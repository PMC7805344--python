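"""Sequential cost-effectiveness analysis over birthweight-range strategies.

Each strategy applies the metabolic algorithm inside one birthweight window
(or to nobody / everybody).  Strategies are compared on annual cost and
annual preterm infants correctly identified:

- *strict dominance*: another strategy costs no more and is at least as
  effective, with at least one inequality strict;
- *extended dominance*: the strategy lies above the lower convex hull of the
  (effect, cost) cloud — a mix of a cheaper and a more effective strategy
  would beat it, i.e. its incremental ICER exceeds that of the next step up
  the frontier;
- the survivors form the efficiency frontier, reported with sequential
  ICERs (cost per extra correct classification between consecutive
  frontier members), which are strictly increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import PercentileTable
from .costs import CostComponents, annual_cost
from .effectiveness import Strategy, strategy_effect

__all__ = [
    "StrategyOutcome",
    "evaluate_strategies",
    "classify_dominance",
    "sequential_icers",
    "frontier_table",
    "default_strategies",
]

STATUS_NONDOMINATED = "nondominated"
STATUS_DOMINATED = "dominated"
STATUS_EXTENDED = "extended_dominated"


@dataclass
class StrategyOutcome:
    """One strategy's cost, effect and (after classification) dominance status."""

    strategy: Strategy
    cost_usd: float
    effect: float
    status: str = STATUS_NONDOMINATED
    dominated_by: Strategy | None = None
    extended_dominated_via: tuple[Strategy, Strategy] | None = None
    icer_vs_baseline: float = math.nan
    sequential_icer: float = math.nan


def default_strategies(
    low_g: int = 2500, high_min_g: int = 2600, high_max_g: int = 5000,
    step_g: int = 100,
) -> list[Strategy]:
    """Baseline, the canonical 2500 g-lower-limit range family, and all-infants."""
    ranges = [
        Strategy("range", low_g, hi)
        for hi in range(high_min_g, high_max_g + 1, step_g)
    ]
    return [Strategy("none"), *ranges, Strategy("all")]


def evaluate_strategies(
    cohort: pd.DataFrame,
    components: CostComponents,
    strategies: list[Strategy],
    baseline_correct: float,
    table: PercentileTable | None = None,
    annualization_factor: float = 1.0 / 3.0,
    include_setup: bool = False,
) -> list[StrategyOutcome]:
    """Annual cost and effect per strategy.

    Cost: the volume-independent ongoing cost plus the per-sample cost for
    the annualized number of infants tested inside the strategy's window
    (zero for the no-algorithm baseline, which runs no program).  Effect:
    :func:`neocea.effectiveness.strategy_effect` with ``baseline_correct``
    as the no-algorithm anchor.
    """
    if not strategies:
        raise ValueError("no strategies given")
    if len(set(strategies)) != len(strategies):
        raise ValueError("duplicate strategies")
    bw = cohort["birthweight_g"]
    outcomes = []
    for strat in strategies:
        if strat.kind == "none":
            cost = 0.0
        else:
            if strat.kind == "all":
                n_raw = len(cohort)
            else:
                n_raw = int(((bw >= strat.bw_low_g) & (bw < strat.bw_high_g)).sum())
            cost = annual_cost(
                components, n_raw * annualization_factor, include_setup
            )
        effect = strategy_effect(
            cohort, strat, baseline_correct, table, annualization_factor
        )
        outcomes.append(StrategyOutcome(strategy=strat, cost_usd=cost, effect=effect))
    return outcomes


def _fill_baseline_icers(outcomes: list[StrategyOutcome]) -> None:
    baseline = next(
        (o for o in outcomes if o.strategy.kind == "none"),
        min(outcomes, key=lambda o: (o.cost_usd, o.effect)),
    )
    for o in outcomes:
        if o is baseline:
            o.icer_vs_baseline = math.nan
        else:
            d_eff = o.effect - baseline.effect
            o.icer_vs_baseline = (
                (o.cost_usd - baseline.cost_usd) / d_eff if d_eff else math.nan
            )


def classify_dominance(outcomes: list[StrategyOutcome]) -> list[StrategyOutcome]:
    """Fill dominance statuses, baseline ICERs and sequential ICERs in place.

    Exact cost-and-effect ties are broken in favour of the simpler strategy
    (narrower birthweight window); the wider one is marked dominated.
    """
    if not outcomes:
        raise ValueError("no strategy outcomes")
    _fill_baseline_icers(outcomes)

    for o in outcomes:
        o.status = STATUS_NONDOMINATED
        o.dominated_by = None
        o.extended_dominated_via = None
        o.sequential_icer = math.nan

    # Strict dominance (with the narrower-range tie-break).
    for a in outcomes:
        dominators = []
        for b in outcomes:
            if a is b:
                continue
            if b.cost_usd <= a.cost_usd and b.effect >= a.effect:
                strict = b.cost_usd < a.cost_usd or b.effect > a.effect
                if strict or b.strategy.width_g < a.strategy.width_g:
                    dominators.append(b)
        if dominators:
            a.status = STATUS_DOMINATED
            a.dominated_by = min(
                dominators, key=lambda b: (b.cost_usd, -b.effect)
            ).strategy

    # Extended dominance: iteratively drop frontier candidates whose
    # incremental ICER exceeds the next candidate's (lower convex hull).
    survivors = [o for o in outcomes if o.status == STATUS_NONDOMINATED]
    survivors.sort(key=lambda o: (o.effect, o.cost_usd))
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        for i in range(1, len(survivors) - 1):
            prev, cur, nxt = survivors[i - 1], survivors[i], survivors[i + 1]
            icer_in = (cur.cost_usd - prev.cost_usd) / (cur.effect - prev.effect)
            icer_out = (nxt.cost_usd - cur.cost_usd) / (nxt.effect - cur.effect)
            if icer_in >= icer_out:
                cur.status = STATUS_EXTENDED
                del survivors[i]
                changed = True
                break

    # Report each excluded strategy against the *final* frontier members
    # bracketing its effect (the pair whose mix outperforms it).
    for o in outcomes:
        if o.status != STATUS_EXTENDED:
            continue
        below = [s for s in survivors if s.effect < o.effect]
        above = [s for s in survivors if s.effect > o.effect]
        if below and above:
            o.extended_dominated_via = (below[-1].strategy, above[0].strategy)

    for prev, cur in zip(survivors, survivors[1:]):
        cur.sequential_icer = (cur.cost_usd - prev.cost_usd) / (
            cur.effect - prev.effect
        )
    return outcomes


def sequential_icers(
    frontier_outcomes: list[StrategyOutcome],
) -> list[tuple[Strategy, float]]:
    """Sequential ICERs between consecutive members of an effect-sorted,
    nondominated strategy list (first member anchors the chain, NaN)."""
    for o in frontier_outcomes:
        if o.status != STATUS_NONDOMINATED:
            raise ValueError(f"{o.strategy.label} is not on the frontier")
    for a, b in zip(frontier_outcomes, frontier_outcomes[1:]):
        if b.effect == a.effect:
            raise ValueError("tied effects on the frontier are degenerate")
        if b.effect < a.effect:
            raise ValueError("frontier outcomes must be sorted by effect")
    out = [(frontier_outcomes[0].strategy, math.nan)]
    for a, b in zip(frontier_outcomes, frontier_outcomes[1:]):
        out.append((b.strategy, (b.cost_usd - a.cost_usd) / (b.effect - a.effect)))
    return out


def frontier_table(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Flatten classified outcomes into the frontier report table."""
    rows = []
    for o in outcomes:
        note = ""
        if o.status == STATUS_DOMINATED and o.dominated_by is not None:
            note = f"dominated by {o.dominated_by.label}"
        elif o.status == STATUS_EXTENDED and o.extended_dominated_via:
            a, b = o.extended_dominated_via
            note = f"extended dominance via {a.label} and {b.label}"
        rows.append(
            {
                "strategy": o.strategy.label,
                "cost_usd": o.cost_usd,
                "effect": o.effect,
                "icer_vs_baseline": o.icer_vs_baseline,
                "sequential_icer": o.sequential_icer,
                "status": o.status,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
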
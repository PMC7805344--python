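"""Pipeline orchestration: deterministic and probabilistic result bundles.

Every bundle is written as CSV/JSON files whose JSON summary embeds the
configuration hash, package version and seed so runs are traceable; result
files are never silently overwritten.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    build_fixture_cohort,
    default_cohort_spec,
    default_percentile_table,
    read_cohort,
    sample_cohort,
)
from .config import RunConfig
from .costs import annual_cost, exact_total_profile, printed_profile
from .effectiveness import cohort_effects
from .frontier import (
    classify_dominance,
    default_strategies,
    evaluate_strategies,
    frontier_table,
)
from .psa import bc_interval, ceac, icer, psa_delta_cost, run_psa

logger = logging.getLogger("neocea")

__all__ = ["resolve_cohort", "resolve_components", "run_deterministic",
           "run_psa_bundle"]


def resolve_components(config: RunConfig):
    return printed_profile() if config.cost_profile == "printed" else exact_total_profile()


def resolve_cohort(config: RunConfig) -> pd.DataFrame:
    spec = default_cohort_spec(overlap_rule=config.overlap_rule)
    if config.cohort_source == "fixture":
        return build_fixture_cohort(spec)
    if config.cohort_source == "sample":
        config.validate(stochastic=True)
        return sample_cohort(spec, config.cohort_n, seed=config.seed)
    return read_cohort(config.cohort_source)


def _fresh_path(out_dir: Path, name: str, force: bool) -> Path:
    path = out_dir / name
    if path.exists() and not force:
        raise FileExistsError(
            f"{path} exists; refusing to overwrite (pass force/--force)"
        )
    return path


def _write_summary(out_dir: Path, config: RunConfig, payload: dict, force: bool):
    payload = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "seed": config.seed,
        **payload,
    }
    path = _fresh_path(out_dir, "summary.json", force)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def run_deterministic(config: RunConfig, out_dir, force: bool = False) -> dict:
    """Point estimates: cost totals, effect summaries, ICERs, frontier report."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = resolve_cohort(config)
    components = resolve_components(config)
    table = default_percentile_table()

    n_tested_annual = len(cohort) / 3.0
    cost_excl = annual_cost(components, n_tested_annual, include_setup=False)
    cost_incl = annual_cost(components, n_tested_annual, include_setup=True)

    effects, rows = {}, []
    for outcome in ("preterm", "sga"):
        per_alg = {}
        for algorithm in ("metabolic", "basic"):
            s = cohort_effects(cohort, algorithm, outcome, table=table)
            per_alg[algorithm] = s
            rows.append(
                {
                    "outcome": outcome,
                    "algorithm": algorithm,
                    "n_true_annual": s.n_true,
                    "n_correct_annual": s.n_correct,
                    "pct_correct": s.pct_correct,
                }
            )
        effects[outcome] = per_alg["metabolic"].n_correct - per_alg["basic"].n_correct
    pd.DataFrame(rows).to_csv(_fresh_path(out_dir, "effects.csv", force), index=False)

    icers = {
        f"icer_{outcome}_{label}": icer(cost, effects[outcome])
        for outcome in ("preterm", "sga")
        for label, cost in (("excl_setup", cost_excl), ("incl_setup", cost_incl))
    }

    frontier_section = {}
    strategies = config.strategies
    if strategies is None:
        strategies = default_strategies()
    if strategies:
        outcomes = evaluate_strategies(
            cohort, components, strategies, config.baseline_correct, table=table
        )
        classify_dominance(outcomes)
        ftab = frontier_table(outcomes)
        ftab.to_csv(_fresh_path(out_dir, "frontier.csv", force), index=False)
        frontier_section = {
            "n_strategies": len(outcomes),
            "frontier": ftab[ftab.status == "nondominated"]["strategy"].tolist(),
        }
    else:
        logger.info("empty strategy list; frontier section omitted")

    summary = {
        "n_tested_annual": n_tested_annual,
        "annual_cost_excl_setup_usd": cost_excl,
        "annual_cost_incl_setup_usd": cost_incl,
        "delta_effect_preterm_annual": effects["preterm"],
        "delta_effect_sga_annual": effects["sga"],
        **icers,
        **frontier_section,
    }
    return _write_summary(out_dir, config, summary, force)


def run_psa_bundle(config: RunConfig, out_dir, force: bool = False) -> dict:
    """PSA bundle: replicate draws, bias-corrected CIs and both CEACs."""
    config.validate(stochastic=True)
    if config.n_reps < 5000:
        logger.warning(
            "n_reps=%d is below the 5000 replications used for stable "
            "estimates; intervals may be noisy", config.n_reps,
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = resolve_cohort(config)
    components = resolve_components(config)
    table = default_percentile_table()

    draws = run_psa(
        cohort, components, n_reps=config.n_reps, seed=config.seed, table=table
    )
    draws.to_csv(_fresh_path(out_dir, "psa_draws.csv", force), index=False)

    n_tested_annual = len(cohort) / 3.0
    points = {
        False: annual_cost(components, n_tested_annual, include_setup=False),
        True: annual_cost(components, n_tested_annual, include_setup=True),
    }
    intervals = {}
    for include_setup in (False, True):
        tag = "incl_setup" if include_setup else "excl_setup"
        ci = bc_interval(psa_delta_cost(draws, include_setup), points[include_setup])
        intervals[f"delta_cost_{tag}"] = {
            "point": points[include_setup], "lower": ci.lower, "upper": ci.upper,
        }
    for outcome in ("preterm", "sga"):
        col = draws[f"delta_effect_{outcome}"]
        point = cohort_effects(cohort, "metabolic", outcome, table=table).n_correct \
            - cohort_effects(cohort, "basic", outcome, table=table).n_correct
        ci = bc_interval(col, point)
        intervals[f"delta_effect_{outcome}"] = {
            "point": point, "lower": ci.lower, "upper": ci.upper,
        }

    ceac_frames = []
    for outcome in ("preterm", "sga"):
        curve = ceac(draws, outcome, config.include_setup, config.wtp_grid)
        curve.insert(0, "outcome", outcome)
        ceac_frames.append(curve)
    ceac_df = pd.concat(ceac_frames, ignore_index=True)
    ceac_df.to_csv(_fresh_path(out_dir, "ceac.csv", force), index=False)

    summary = {
        "n_reps": config.n_reps,
        "include_setup_in_ceac": config.include_setup,
        "intervals": intervals,
    }
    return _write_summary(out_dir, config, summary, force)
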
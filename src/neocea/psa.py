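"""Incremental cost-effectiveness statistics and probabilistic sensitivity
analysis (PSA).

Deterministic layer: the incremental cost-effectiveness ratio (ICER) and
net monetary benefit (NMB) identities.

Probabilistic layer: uncertainty in the clinical effect is propagated by a
nonparametric bootstrap of the per-infant cohort.  The cohort is an
observation *pool* whose counts are ``1 / annualization_factor`` program
years; each replicate simulates one year by drawing the annual number of
infants tested (pool size x annualization factor) with replacement, so the
per-annum correct-classification differences are counted directly on the
resample.  Each cost component is drawn from a gamma distribution
moment-matched to its mean with a standard error of 10% of the mean
(shape = 1/se_fraction^2 = 100, scale = mean x se_fraction^2).  Each of the
5000 default replicates yields one incremental-cost / incremental-effect
pair; summaries are bias-corrected (BC) bootstrap confidence intervals and
cost-effectiveness acceptability curves (CEACs).

Random-number discipline: a single seeded generator; per replicate the cost
draws are consumed first (one vector per component, drawn up front for the
whole run), then the bootstrap index rows in replicate order, so a fixed
seed reproduces the draw sequence exactly regardless of chunking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PercentileTable, default_percentile_table
from .costs import CostComponents
from .effectiveness import (
    PRETERM_PREDICTED_BOUND_WK,
    PRETERM_ULTRASOUND_CUTOFF_WK,
)

__all__ = [
    "GammaParams",
    "BootstrapCI",
    "icer",
    "nmb",
    "gamma_parameters",
    "run_psa",
    "bc_interval",
    "ceac",
    "psa_delta_cost",
]

#: Replication count used for stable cost and effect estimates.
DEFAULT_N_REPS = 5000

_BOOT_CHUNK = 512  # replicates per indexing block; does not affect the stream


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale of a moment-matched gamma cost distribution."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale


@dataclass(frozen=True)
class BootstrapCI:
    """A bias-corrected bootstrap confidence interval."""

    level: float
    lower: float
    upper: float
    z0: float


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio: extra cost per extra correct
    classification.  Undefined (NaN) when the incremental effect is zero."""
    if delta_effect == 0:
        return math.nan
    return delta_cost / delta_effect


def nmb(wtp: float, delta_cost: float, delta_effect: float) -> float:
    """Incremental net monetary benefit at willingness-to-pay ``wtp``.

    Positive exactly when ``wtp`` exceeds the ICER (for a positive
    incremental effect).
    """
    return wtp * delta_effect - delta_cost


def gamma_parameters(mean: float, se_fraction: float = 0.10) -> GammaParams:
    """Gamma shape/scale matching ``mean`` with SE = ``se_fraction`` x mean."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    if se_fraction <= 0:
        raise ValueError("se_fraction must be positive")
    return GammaParams(shape=1.0 / se_fraction**2, scale=mean * se_fraction**2)


def _correct_signs(cohort: pd.DataFrame, table: PercentileTable):
    """Per-record metabolic-minus-basic correctness (+1/0/-1), both outcomes.

    Restricted to suitable samples (zeros elsewhere) so bootstrap sums over
    resampled record indices reproduce the cohort-level count differences.
    """
    suitable = cohort["sample_suitable"].to_numpy(dtype=bool)
    us = cohort["ga_ultrasound_wk"].to_numpy(dtype=float)
    bw = cohort["birthweight_g"].to_numpy(dtype=float)
    metab = cohort["ga_metabolic_wk"].to_numpy(dtype=float)
    basic = cohort["ga_basic_wk"].to_numpy(dtype=float)

    pre_true = suitable & (us < PRETERM_ULTRASOUND_CUTOFF_WK)
    with np.errstate(invalid="ignore"):
        pre_m = pre_true & (metab <= PRETERM_PREDICTED_BOUND_WK)
        pre_b = pre_true & (basic <= PRETERM_PREDICTED_BOUND_WK)
        sga_true = suitable & (bw < table.p10(np.where(np.isnan(us), 37.0, us)))
        sga_true &= ~np.isnan(us)
        p10_m = table.p10(np.where(np.isnan(metab), 37.0, metab))
        p10_b = table.p10(np.where(np.isnan(basic), 37.0, basic))
        sga_m = sga_true & ~np.isnan(metab) & ((bw < p10_m) == sga_true)
        sga_b = sga_true & ~np.isnan(basic) & ((bw < p10_b) == sga_true)
    d_pre = pre_m.astype(np.int64) - pre_b.astype(np.int64)
    d_sga = sga_m.astype(np.int64) - sga_b.astype(np.int64)
    return d_pre, d_sga


def run_psa(
    cohort: pd.DataFrame,
    components: CostComponents,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    table: PercentileTable | None = None,
    annualization_factor: float = 1.0 / 3.0,
    resample_size: int | None = None,
) -> pd.DataFrame:
    """Joint bootstrap / Monte-Carlo replicates of incremental cost and effect.

    Each replicate draws ``resample_size`` infants with replacement from the
    cohort pool — by default the annual screening volume,
    ``round(len(cohort) x annualization_factor)`` — so the suitable-sample
    count varies and the metabolic-minus-basic correct-classification
    differences are per-annum counts of the simulated year.  (For a cohort
    that already represents one year, ``annualization_factor=1`` gives the
    classic same-size bootstrap.)  The ongoing, per-sample and setup cost
    components are drawn independently from their gamma distributions; the
    incremental annual cost is ``ongoing + n_tested x per_sample`` with
    ``n_tested`` the annual volume, and the setup draw is returned
    separately so downstream summaries can include or exclude it.

    Returns a frame with columns ``replicate_id``, ``delta_cost_usd``
    (setup excluded), ``setup_cost_usd``, ``delta_effect_preterm`` and
    ``delta_effect_sga``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for a reproducible PSA")
    if table is None:
        table = default_percentile_table()
    components.validate()

    rng = np.random.default_rng(seed)
    se = components.se_fraction

    def draws(mean: float) -> np.ndarray:
        p = gamma_parameters(mean, se)
        return rng.gamma(p.shape, p.scale, size=n_reps)

    ongoing = draws(components.ongoing_annual_usd)
    per_sample = draws(components.per_sample_usd)
    setup = draws(components.setup_total_usd)

    d_pre, d_sga = _correct_signs(cohort, table)
    n = len(cohort)
    if resample_size is None:
        resample_size = round(n * annualization_factor)
    if resample_size < 1:
        raise ValueError("resample_size must be >= 1")
    n_tested_annual = resample_size
    de_pre = np.empty(n_reps)
    de_sga = np.empty(n_reps)
    for start in range(0, n_reps, _BOOT_CHUNK):
        stop = min(start + _BOOT_CHUNK, n_reps)
        idx = rng.integers(0, n, size=(stop - start, resample_size))
        de_pre[start:stop] = d_pre[idx].sum(axis=1)
        de_sga[start:stop] = d_sga[idx].sum(axis=1)

    return pd.DataFrame(
        {
            "replicate_id": np.arange(n_reps),
            "delta_cost_usd": ongoing + n_tested_annual * per_sample,
            "setup_cost_usd": setup,
            "delta_effect_preterm": de_pre,
            "delta_effect_sga": de_sga,
        }
    )


def psa_delta_cost(draws: pd.DataFrame, include_setup: bool) -> np.ndarray:
    """Per-replicate incremental annual cost, with or without setup."""
    cost = draws["delta_cost_usd"].to_numpy(dtype=float)
    if include_setup:
        cost = cost + draws["setup_cost_usd"].to_numpy(dtype=float)
    return cost


def bc_interval(
    draws, point_estimate: float, level: float = 0.95
) -> BootstrapCI:
    """Bias-corrected (BC) percentile bootstrap interval.

    The bias constant is z0 = Phi^-1(#{draws < point_estimate} / n); the
    bounds are the empirical quantiles at Phi(2 z0 -/+ z_(1+level)/2).  No
    acceleration correction is applied (BC, not BCa).  Degenerate draw sets
    (all values identical) collapse to a zero-width interval.
    """
    values = np.asarray(draws, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 bootstrap draws")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if np.all(values == values[0]):
        return BootstrapCI(level=level, lower=float(values[0]),
                           upper=float(values[0]), z0=0.0)
    prop = np.mean(values < point_estimate)
    # Guard the normal quantile against empty/full tails.
    prop = min(max(prop, 0.5 / values.size), 1 - 0.5 / values.size)
    z0 = stats.norm.ppf(prop)
    z_alpha = stats.norm.ppf(0.5 + level / 2)
    lo_q = stats.norm.cdf(2 * z0 - z_alpha)
    hi_q = stats.norm.cdf(2 * z0 + z_alpha)
    lower, upper = np.quantile(values, [lo_q, hi_q])
    return BootstrapCI(level=level, lower=float(lower), upper=float(upper),
                       z0=float(z0))


def ceac(
    draws: pd.DataFrame,
    outcome: str,
    include_setup: bool,
    wtp_grid,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each threshold the probability is the fraction of PSA replicates with
    strictly positive incremental net monetary benefit.  Setup costs are
    included by default in reported curves (see the methods note).
    """
    if outcome not in ("preterm", "sga"):
        raise ValueError(f"unknown outcome {outcome!r}")
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if draws.empty:
        raise ValueError("no PSA draws")
    cost = psa_delta_cost(draws, include_setup)
    effect = draws[f"delta_effect_{outcome}"].to_numpy(dtype=float)
    benefit = grid[:, None] * effect[None, :] - cost[None, :]
    prob = (benefit > 0).mean(axis=1)
    return pd.DataFrame({"wtp_usd": grid, "probability": prob})
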
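"""Classification-correctness rules and strategy-restricted effects.

Two screening outcomes are scored against ultrasound-dated truth:

Preterm
    An infant is truly preterm when ultrasound GA < 37 weeks.  An algorithm
    identifies the infant correctly, to within one week of the 37-week
    dichotomy, when its predicted GA is no more than 38 weeks.
SGA (small for gestational age)
    An infant is SGA when birthweight falls strictly below the 10th
    percentile of weight at its GA.  An algorithm classifies SGA correctly
    when the SGA status implied by its predicted GA concurs with the status
    implied by the ultrasound GA; the reported metric counts concordance
    among truly-SGA infants only.

All cohort-level counts are restricted to infants with suitable samples
(the metabolic estimate exists only for those) and multiplied by the
cohort's annualization factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PercentileTable, default_percentile_table

__all__ = [
    "Strategy",
    "EffectSummary",
    "PRETERM_ULTRASOUND_CUTOFF_WK",
    "PRETERM_PREDICTED_BOUND_WK",
    "ALL_INFANTS_INCREMENT_FLOOR_G",
    "is_preterm_correct",
    "is_sga",
    "is_sga_correct",
    "cohort_effects",
    "strategy_effect",
]

#: True preterm status: ultrasound GA strictly before 37 completed weeks.
PRETERM_ULTRASOUND_CUTOFF_WK = 37.0
#: Correct identification: predicted GA of no more than 38 weeks.  The bound
#: is inclusive by default ("no more than"); pass ``predicted_inclusive=False``
#: for the strict reading.  Fixture cohorts place predictions away from the
#: boundary, so both readings agree on them.
PRETERM_PREDICTED_BOUND_WK = 38.0

#: Birthweight floor for the whole-cohort strategy's effect increment.  The
#: sequential analysis credits the metabolic algorithm's gains only at and
#: above 2500 g: below that, low birthweight alone flags the infant and the
#: clinical-variables algorithm is already the better preterm classifier, so
#: its classification is retained there even when every infant is tested.
ALL_INFANTS_INCREMENT_FLOOR_G = 2500


@dataclass(frozen=True)
class Strategy:
    """Where the metabolic algorithm is applied.

    ``none``: nowhere (basic algorithm only); ``all``: every infant tested;
    ``range``: infants with birthweight in ``[bw_low_g, bw_high_g)`` grams.
    """

    kind: str
    bw_low_g: int | None = None
    bw_high_g: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "all", "range"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "range":
            if self.bw_low_g is None or self.bw_high_g is None:
                raise ValueError("range strategy requires bw_low_g and bw_high_g")
            if not self.bw_low_g < self.bw_high_g:
                raise ValueError("range strategy requires bw_low_g < bw_high_g")
        elif self.bw_low_g is not None or self.bw_high_g is not None:
            raise ValueError(f"{self.kind!r} strategy takes no birthweight bounds")

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "no GA algorithm use"
        if self.kind == "all":
            return "all infants"
        return f"{self.bw_low_g}-{self.bw_high_g} g BW"

    @property
    def width_g(self) -> int:
        """Range width in grams; used only to break exact cost/effect ties."""
        if self.kind == "range":
            return self.bw_high_g - self.bw_low_g
        return 0 if self.kind == "none" else 10**9


@dataclass(frozen=True)
class EffectSummary:
    """Annualized counts for one (algorithm, outcome) pair."""

    n_true: float
    n_correct: float

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_true if self.n_true else math.nan


def _predicted_ga(record, algorithm: str):
    if algorithm not in ("metabolic", "basic"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    value = record[f"ga_{algorithm}_wk"]
    return None if pd.isna(value) else float(value)


def is_preterm_correct(
    record, algorithm: str, *, predicted_inclusive: bool = True
) -> bool | None:
    """Correct preterm identification for one record, or ``None`` if not
    evaluable (missing prediction — excluded from counts, not scored wrong)."""
    predicted = _predicted_ga(record, algorithm)
    if predicted is None:
        return None
    if record["ga_ultrasound_wk"] >= PRETERM_ULTRASOUND_CUTOFF_WK:
        return False
    if predicted_inclusive:
        return predicted <= PRETERM_PREDICTED_BOUND_WK
    return predicted < PRETERM_PREDICTED_BOUND_WK


def is_sga(birthweight_g, ga_wk, table: PercentileTable) -> bool:
    """Strictly below the interpolated 10th-percentile weight at ``ga_wk``."""
    return bool(birthweight_g < table.p10(ga_wk))


def is_sga_correct(record, algorithm: str, table: PercentileTable) -> bool | None:
    """SGA concordance between predicted-GA and ultrasound-GA classification.

    Symmetric in the two GAs.  ``None`` when the prediction is missing.
    """
    predicted = _predicted_ga(record, algorithm)
    if predicted is None:
        return None
    bw = record["birthweight_g"]
    return is_sga(bw, predicted, table) == is_sga(bw, record["ga_ultrasound_wk"], table)


def _restrict(cohort: pd.DataFrame, bw_range) -> pd.DataFrame:
    sub = cohort[cohort["sample_suitable"].astype(bool)]
    if bw_range is not None:
        lo, hi = bw_range
        mask = sub["birthweight_g"] >= lo
        if hi is not None:
            mask &= sub["birthweight_g"] < hi
        sub = sub[mask]
    return sub


def cohort_effects(
    cohort: pd.DataFrame,
    algorithm: str,
    outcome: str,
    table: PercentileTable | None = None,
    annualization_factor: float = 1.0 / 3.0,
    bw_range: tuple[int, int | None] | None = None,
    predicted_inclusive: bool = True,
) -> EffectSummary:
    """Annualized true and correctly-classified counts for one algorithm.

    Counts are restricted to suitable samples and, optionally, to the
    closed-open birthweight window ``bw_range`` = ``(low_g, high_g)`` (a
    ``None`` upper bound means unbounded).
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if outcome not in ("preterm", "sga"):
        raise ValueError(f"unknown outcome {outcome!r}")
    if algorithm not in ("metabolic", "basic"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if table is None:
        table = default_percentile_table()
    sub = _restrict(cohort, bw_range)
    predicted = sub[f"ga_{algorithm}_wk"].to_numpy(dtype=float)
    us = sub["ga_ultrasound_wk"].to_numpy(dtype=float)
    if outcome == "preterm":
        true_mask = us < PRETERM_ULTRASOUND_CUTOFF_WK
        if predicted_inclusive:
            hit = predicted <= PRETERM_PREDICTED_BOUND_WK
        else:
            hit = predicted < PRETERM_PREDICTED_BOUND_WK
    else:
        bw = sub["birthweight_g"].to_numpy(dtype=float)
        true_mask = bw < table.p10(us)
        hit = (bw < table.p10(predicted)) == true_mask
    evaluable = ~np.isnan(predicted)
    n_true = int(true_mask.sum())
    n_correct = int((true_mask & evaluable & hit).sum())
    f = annualization_factor
    return EffectSummary(n_true=n_true * f, n_correct=n_correct * f)


def _increment(cohort, table, factor, bw_range, predicted_inclusive) -> float:
    kwargs = dict(
        table=table,
        annualization_factor=factor,
        bw_range=bw_range,
        predicted_inclusive=predicted_inclusive,
    )
    metab = cohort_effects(cohort, "metabolic", "preterm", **kwargs)
    basic = cohort_effects(cohort, "basic", "preterm", **kwargs)
    return metab.n_correct - basic.n_correct


def strategy_effect(
    cohort: pd.DataFrame,
    strategy: Strategy,
    baseline_correct: float,
    table: PercentileTable | None = None,
    annualization_factor: float = 1.0 / 3.0,
    predicted_inclusive: bool = True,
) -> float:
    """Annual preterm infants correctly identified under a strategy.

    ``baseline_correct`` is the no-algorithm correct count — a model input,
    not derived from the cohort.  A range strategy adds the in-range
    metabolic-minus-basic increment to the baseline; the all-infants
    strategy adds the increment accumulated at and above
    :data:`ALL_INFANTS_INCREMENT_FLOOR_G` (see that constant's note).
    """
    if baseline_correct < 0:
        raise ValueError("baseline_correct must be nonnegative")
    if strategy.kind == "none":
        return baseline_correct
    if strategy.kind == "range":
        bw_range = (strategy.bw_low_g, strategy.bw_high_g)
    else:
        bw_range = (ALL_INFANTS_INCREMENT_FLOOR_G, None)
    return baseline_correct + _increment(
        cohort, table, annualization_factor, bw_range, predicted_inclusive
    )
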
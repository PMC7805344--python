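"""Run configuration: loading, validation and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .effectiveness import Strategy

__all__ = ["RunConfig", "ConfigError", "load_run_config"]

#: Annual preterm infants correctly identified with no GA algorithm in use —
#: the anchor of the sequential analysis, a model input (142/3 per annum).
DEFAULT_BASELINE_PRETERM_CORRECT = 142.0 / 3.0

_DEFAULT_WTP_GRID = list(range(0, 30001, 500))


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every failure found."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the cohort itself."""

    cohort_source: str = "fixture"  # fixture | sample | a CSV path
    cohort_n: int | None = None  # sample mode only
    cost_profile: str = "exact_total"  # exact_total | printed
    overlap_rule: str = "maximal"
    baseline_correct: float = DEFAULT_BASELINE_PRETERM_CORRECT
    n_reps: int = 5000
    seed: int | None = None
    include_setup: bool = True
    wtp_grid: list[float] = field(default_factory=lambda: list(_DEFAULT_WTP_GRID))
    strategies: list[Strategy] | None = None  # None -> canonical family

    def validate(self, stochastic: bool = False) -> None:
        problems = []
        if self.cost_profile not in ("exact_total", "printed"):
            problems.append(f"unknown cost_profile {self.cost_profile!r}")
        if self.overlap_rule not in ("maximal", "minimal", "independent"):
            problems.append(f"unknown overlap_rule {self.overlap_rule!r}")
        if self.baseline_correct < 0:
            problems.append("baseline_correct must be nonnegative")
        if self.n_reps < 1:
            problems.append("n_reps must be >= 1")
        if stochastic and self.seed is None:
            problems.append("a seed is mandatory for stochastic runs")
        if self.cohort_source == "sample" and not self.cohort_n:
            problems.append("sample cohort_source requires cohort_n")
        if self.wtp_grid is not None:
            grid = list(self.wtp_grid)
            if not grid:
                problems.append("wtp_grid must be nonempty")
            elif sorted(grid) != grid:
                problems.append("wtp_grid must be sorted ascending")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.strategies is not None:
            d["strategies"] = [dataclasses.asdict(s) for s in self.strategies]
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _parse_strategy(item) -> Strategy:
    if isinstance(item, str):
        if item in ("none", "all"):
            return Strategy(item)
        raise ConfigError(f"unknown strategy shorthand {item!r}")
    if isinstance(item, dict):
        return Strategy(
            kind=item.get("kind", "range"),
            bw_low_g=item.get("bw_low_g"),
            bw_high_g=item.get("bw_high_g"),
        )
    raise ConfigError(f"cannot parse strategy {item!r}")


def load_run_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, collecting all validation errors."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("run config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "strategies" in data and data["strategies"] is not None:
        data["strategies"] = [_parse_strategy(s) for s in data["strategies"]]
    config = RunConfig(**data)
    config.validate()
    return config
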
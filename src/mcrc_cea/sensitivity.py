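"""Sensitivity analyses.

One-way deterministic sensitivity (tornado): each parameter is pushed to its
low and high value with everything else held at base, the full pipeline is
re-run, and entries are ranked by outcome spread.

Monte Carlo: first-order microsimulation samples individual patient paths
through the three states at fixed parameters (n individuals per trial,
means per trial); second-order mode additionally redraws selected strategy
parameters each trial from user-specified distributions.  All randomness
flows from a single seed; per-trial substreams are derived from
(seed, trial index), so runs are reproducible and trials independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import Field, model_validator

from .cea_analysis import cost_per_qaly as _cpq, icer as _icer
from .costing import StateCostProfile, build_state_costs
from .markov_engine import monthly_discount_factor
from .parameters import (
    AnalysisConfig,
    ConfigError,
    ModelSettings,
    StrategyDefinition,
    StrictModel,
    get_by_path,
    set_by_path,
)
from .pipeline import evaluate_analysis
from .transitions import Structure, TransitionMatrix, build_transition_matrix


class ParamRange(StrictModel):
    path: str
    low: float
    high: float
    base: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "ParamRange":
        if self.low > self.high:
            raise ValueError(f"low > high for {self.path}")
        if self.base is not None and not (self.low <= self.base <= self.high):
            raise ValueError(f"base outside [low, high] for {self.path}")
        return self


class Outcome(StrictModel):
    """What the tornado measures: a strategy's cost/QALY (or totals), or the
    ICER of an intervention/comparator pair."""

    kind: Literal["cost_per_qaly", "total_cost", "total_qaly", "icer"]
    strategy: Optional[str] = None
    intervention: Optional[str] = None
    comparator: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Outcome":
        if self.kind == "icer":
            if not (self.intervention and self.comparator):
                raise ValueError("icer outcome needs intervention and comparator")
        elif not self.strategy:
            raise ValueError(f"{self.kind} outcome needs a strategy name")
        return self


@dataclass
class TornadoEntry:
    path: str
    outcome_at_low: float
    outcome_at_high: float
    outcome_at_base: float
    spread: float


class PSAConfig(StrictModel):
    n_individuals: int = Field(ge=1, default=10_000)
    n_trials: int = Field(ge=1, default=1_000)
    seed: int = 0
    mode: Literal["first_order", "second_order"] = "first_order"
    distributions: Optional[dict[str, dict]] = None

    @model_validator(mode="after")
    def _check(self) -> "PSAConfig":
        if self.mode == "second_order" and not self.distributions:
            raise ValueError("second_order mode requires parameter distributions")
        return self


def evaluate_outcome(
    config: AnalysisConfig, outcome: Outcome, structure: Structure = "progression_required"
) -> float:
    results = {o.name: o for o in evaluate_analysis(config, mode="engine", structure=structure)}
    if outcome.kind == "icer":
        try:
            i = results[outcome.intervention]
            c = results[outcome.comparator]
        except KeyError as exc:
            raise ConfigError(f"outcome references unknown strategy {exc}") from exc
        value = _icer((i.total_cost, i.total_qaly), (c.total_cost, c.total_qaly), decimals=None)
        if value is None:
            raise ValueError("ICER undefined (zero QALY difference) at this parameter setting")
        return value
    try:
        r = results[outcome.strategy]
    except KeyError as exc:
        raise ConfigError(f"outcome references unknown strategy {exc}") from exc
    if outcome.kind == "total_cost":
        return r.total_cost
    if outcome.kind == "total_qaly":
        return r.total_qaly
    return _cpq(r.total_cost, r.total_qaly, decimals=None)


def one_way_dsa(
    config: AnalysisConfig,
    ranges: list[ParamRange],
    outcome: Outcome,
    structure: Structure = "progression_required",
) -> list[TornadoEntry]:
    """Tornado analysis: deterministic low/high re-runs per parameter,
    everything else at base; entries sorted by descending spread."""
    base_value = evaluate_outcome(config, outcome, structure)
    entries = []
    for rng_ in ranges:
        get_by_path(config, rng_.path)  # fail early with a clear message
        lo = evaluate_outcome(set_by_path(config, rng_.path, rng_.low), outcome, structure)
        hi = evaluate_outcome(set_by_path(config, rng_.path, rng_.high), outcome, structure)
        entries.append(
            TornadoEntry(
                path=rng_.path,
                outcome_at_low=lo,
                outcome_at_high=hi,
                outcome_at_base=base_value,
                spread=abs(hi - lo),
            )
        )
    entries.sort(key=lambda e: (-e.spread, e.path))
    return entries


def default_ranges(config: AnalysisConfig, rel: float = 0.20) -> list[ParamRange]:
    """±20% ranges around base for the influential parameters of every
    strategy (medians, utilities, transition probabilities, major costs),
    used when no range file is supplied.  Utilities are capped at 1 and the
    derived transition probabilities are varied via overrides."""
    ranges: list[ParamRange] = []
    for s in config.strategies:
        pre = f"strategies.{s.name}"
        matrix = build_transition_matrix(s.survival, overrides=None)
        numeric = {
            f"{pre}.utilities.stable": (s.utilities.stable, 1.0),
            f"{pre}.utilities.progressive": (s.utilities.progressive, s.utilities.stable),
            f"{pre}.costs.progression_cost_per_month": (s.costs.progression_cost_per_month, None),
            f"{pre}.costs.admin_monitoring_cost_per_cycle": (s.costs.admin_monitoring_cost_per_cycle, None),
            f"{pre}.costs.backbone_cost_per_admin": (s.costs.backbone_cost_per_admin, None),
            f"{pre}.transition_overrides.p_sd_to_pd": (matrix.p_sd_to_pd, 1.0),
            f"{pre}.transition_overrides.p_pd_to_dead": (matrix.p_pd_to_dead, 1.0),
        }
        for i, entry in enumerate(s.dosing):
            numeric[f"{pre}.dosing.{i}.unit_price_usd_per_mg"] = (entry.unit_price_usd_per_mg, None)
        for path, (base, cap) in numeric.items():
            lo = base * (1 - rel)
            hi = base * (1 + rel) if cap is None else min(base * (1 + rel), cap)
            ranges.append(ParamRange(path=path, low=lo, high=hi, base=base))
    ranges.append(
        ParamRange(
            path="settings.discount.annual_rate",
            low=0.0,
            high=0.05,
            base=config.settings.discount.annual_rate,
        )
    )
    return ranges


def _draw(rng: np.random.Generator, spec: dict) -> float:
    dist = spec.get("dist")
    if dist == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if dist == "normal":
        return float(rng.normal(spec["mean"], spec["sd"]))
    if dist == "beta":
        return float(rng.beta(spec["alpha"], spec["beta"]))
    raise ValueError(f"unknown distribution {dist!r}")


def _apply_draws(strategy: StrategyDefinition, draws: dict[str, float]) -> StrategyDefinition:
    data = strategy.model_dump()
    for path, value in draws.items():
        node = data
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[int(part)] if isinstance(node, list) else node[part]
        if isinstance(node, list):
            node[int(parts[-1])] = value
        else:
            node[parts[-1]] = value
    return StrategyDefinition.model_validate(data)


def _simulate_trial(
    rng: np.random.Generator,
    matrix: TransitionMatrix,
    costs: StateCostProfile,
    utilities,
    settings: ModelSettings,
    n: int,
) -> tuple[float, float]:
    states = np.zeros(n, dtype=np.int8)  # 0 sd, 1 pd, 2 dead
    cost = np.zeros(n)
    qaly = np.zeros(n)
    p1, p13, p2 = matrix.p_sd_to_pd, matrix.p_sd_to_dead, matrix.p_pd_to_dead
    for t in range(settings.horizon_cycles):
        sd = states == 0
        pd_ = states == 1
        if not (sd.any() or pd_.any()):
            break
        dfac = monthly_discount_factor(settings.discount, t)
        c_sd = costs.cost_sd_first_cycle if t == 0 else costs.cost_sd_per_cycle
        cost[sd] += c_sd * dfac
        cost[pd_] += costs.cost_pd_per_cycle * dfac
        qaly[sd] += utilities.stable / 12.0 * dfac
        qaly[pd_] += utilities.progressive / 12.0 * dfac
        u = rng.random(n)
        states = states.copy()
        states[pd_ & (u < p2)] = 2
        states[sd & (u < p1)] = 1
        states[sd & (u >= p1) & (u < p1 + p13)] = 2
    return float(cost.mean()), float(qaly.mean())


def microsimulate(
    strategy: StrategyDefinition,
    matrix: TransitionMatrix,
    costs: StateCostProfile,
    settings: ModelSettings,
    psa: PSAConfig,
    structure: Structure = "progression_required",
) -> pd.DataFrame:
    """Monte Carlo simulation: per-trial mean (cost, QALY) over
    ``psa.n_individuals`` sampled patient paths.

    first_order: parameters fixed; trial-to-trial spread is pure sampling
    noise around the cohort-trace expectation.  second_order: strategy
    parameters are redrawn each trial from ``psa.distributions`` (dotted
    paths into the strategy), capturing parameter uncertainty.
    """
    rows = []
    for trial in range(psa.n_trials):
        rng = np.random.default_rng([psa.seed, trial])
        m, c = matrix, costs
        util = strategy.utilities
        if psa.mode == "second_order":
            draws = {path: _draw(rng, spec) for path, spec in psa.distributions.items()}
            s2 = _apply_draws(strategy, draws)
            m = build_transition_matrix(s2.survival, structure, s2.transition_overrides)
            c = build_state_costs(s2)
            util = s2.utilities
        mean_cost, mean_qaly = _simulate_trial(rng, m, c, util, settings, psa.n_individuals)
        rows.append((trial, mean_cost, mean_qaly))
    df = pd.DataFrame(rows, columns=["trial", "mean_cost", "mean_qaly"])
    df.attrs["seed"] = psa.seed
    df.attrs["n_individuals"] = psa.n_individuals
    df.attrs["mode"] = psa.mode
    return df
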
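"""Synthetic strategy generation with known ground truth.

Emulates the structure of the real inputs — exponential-like time-to-event
summarized by medians (PFS, and OS as PFS plus a positive post-progression
offset), decomposable per-cycle cost schedules, and utility-weighted state
occupancy — with all parameters drawn uniformly within user ranges from a
seeded generator.  Each generated strategy satisfies every input invariant
by construction, and the ground-truth record carries the closed-form
expected discounted cost/QALY plus the true efficiency frontier, so every
pipeline stage can be tested without external data.

The uniform draws are test scaffolding, not a scientific claim about
parameter distributions.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import Field, model_validator

from .cea_analysis import classify_dominance
from .costing import DAYS_PER_MONTH, build_state_costs
from .markov_engine import closed_form_expectation
from .parameters import (
    AEProfile,
    AnalysisConfig,
    CostSchedule,
    ModelSettings,
    SocietalCosts,
    StrategyDefinition,
    StrictModel,
    SurvivalSummary,
    UtilitySet,
)
from .transitions import build_transition_matrix, median_to_monthly_prob


class SyntheticSpec(StrictModel):
    n_strategies: int = Field(ge=1, default=10)
    median_pfs_range: tuple[float, float] = (2.0, 20.0)
    median_os_offset_range: tuple[float, float] = (2.0, 30.0)  # OS - PFS, months
    monthly_drug_cost_range: tuple[float, float] = (1000.0, 15000.0)
    admin_cost_range: tuple[float, float] = (0.0, 1000.0)
    progression_cost_range: tuple[float, float] = (1000.0, 10000.0)
    u_stable_range: tuple[float, float] = (0.6, 0.95)
    u_progressive_range: tuple[float, float] = (0.3, 0.8)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticSpec":
        for name in (
            "median_pfs_range",
            "median_os_offset_range",
            "monthly_drug_cost_range",
            "admin_cost_range",
            "progression_cost_range",
            "u_stable_range",
            "u_progressive_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low > high")
            if name.startswith("median") and lo <= 0:
                raise ValueError(f"{name}: medians must be positive")
            if name.startswith("u_") and not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name}: utilities must lie in [0, 1]")
            if name.endswith("cost_range") and lo < 0:
                raise ValueError(f"{name}: costs must be non-negative")
        return self


def generate_strategies(
    spec: SyntheticSpec, settings: Optional[ModelSettings] = None
) -> tuple[list[StrategyDefinition], pd.DataFrame]:
    """Draw a synthetic strategy set and its ground truth.

    Returns (strategies, ground_truth) where ground_truth has one row per
    strategy with the closed-form expected discounted cost and QALY under
    ``settings`` (defaults: 3% annual discount) and an ``on_frontier`` flag
    from dominance classification of those expectations.
    """
    if settings is None:
        settings = ModelSettings()
    rng = np.random.default_rng(spec.seed)
    strategies = []
    for i in range(spec.n_strategies):
        pfs = float(rng.uniform(*spec.median_pfs_range))
        offset = float(rng.uniform(*spec.median_os_offset_range))
        drug_monthly = float(rng.uniform(*spec.monthly_drug_cost_range))
        admin = float(rng.uniform(*spec.admin_cost_range))
        prog = float(rng.uniform(*spec.progression_cost_range))
        u_stable = float(rng.uniform(*spec.u_stable_range))
        u_prog_hi = min(spec.u_progressive_range[1], u_stable)
        u_prog_lo = min(spec.u_progressive_range[0], u_prog_hi)
        u_prog = float(rng.uniform(u_prog_lo, u_prog_hi))
        strategies.append(
            StrategyDefinition(
                name=f"SYN-{i:03d}",
                biomarker_policy="extended_RAS_wt",
                biologic="Cetux" if i % 2 == 0 else "Bev",
                backbone="pooled",
                survival=SurvivalSummary(median_pfs_months=pfs, median_os_months=pfs + offset),
                dosing=[],
                costs=CostSchedule(
                    backbone_cost_per_admin=drug_monthly * 14.0 / DAYS_PER_MONTH,
                    backbone_schedule_days=14,
                    admin_monitoring_cost_per_cycle=admin,
                    societal=SocietalCosts(
                        travel_cost_per_visit=0.0, absenteeism_cost_per_day=0.0
                    ),
                    progression_cost_per_month=prog,
                    pd_visits_per_month=0.0,
                ),
                ae=AEProfile(arm="Cetux" if i % 2 == 0 else "Bev", events=[]),
                utilities=UtilitySet(stable=u_stable, progressive=u_prog),
            )
        )
    rows = []
    for s in strategies:
        matrix = build_transition_matrix(s.survival)
        costs = build_state_costs(s)
        ec, eq = closed_form_expectation(matrix, costs, s.utilities, settings.discount)
        rows.append((s.name, ec, eq))
    _, frontier = classify_dominance(rows)
    on_frontier = {r.name for r in frontier}
    truth = pd.DataFrame(rows, columns=["name", "expected_cost", "expected_qaly"])
    truth["on_frontier"] = truth["name"].isin(on_frontier)
    truth.attrs["seed"] = spec.seed
    return strategies, truth


def to_config(
    strategies: list[StrategyDefinition], settings: Optional[ModelSettings] = None
) -> AnalysisConfig:
    """Wrap generated strategies as a loadable/serializable analysis config."""
    return AnalysisConfig(
        settings=settings or ModelSettings(),
        strategies=strategies,
        provenance={"strategies.*": "synthetic draw [assumed]"},
    )


def exponential_event_sampler(median: float, seed: int, n: int) -> np.ndarray:
    """Exponential time-to-event draws with the stated median (months);
    the continuous counterpart of the median-to-probability conversion."""
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=median / math.log(2.0), size=n)


def estimate_monthly_prob_from_times(times: np.ndarray, method: str = "geometric_mle") -> float:
    """Recover the per-cycle transition probability from sampled event times.

    geometric_mle (default): discretize into monthly cycles (ceil) — exact
    exponential discretization is geometric with p = 1 - 0.5^(1/median) —
    and take the MLE 1/mean(cycles).  empirical_median: plug the continuous
    empirical median into the median-to-probability formula.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("no event times supplied")
    if method == "geometric_mle":
        cycles = np.maximum(np.ceil(times), 1.0)
        return 1.0 / float(cycles.mean())
    if method == "empirical_median":
        return median_to_monthly_prob(float(np.median(times)))
    raise ValueError(f"unknown method {method!r}")
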
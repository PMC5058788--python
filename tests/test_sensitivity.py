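"""Tornado (one-way DSA) and Monte Carlo microsimulation."""

import numpy as np
import pytest

from mcrc_cea.cea_analysis import icer
from mcrc_cea.costing import build_state_costs
from mcrc_cea.markov_engine import run_cohort
from mcrc_cea.parameters import ConfigError, DiscountSpec, ModelSettings, set_by_path
from mcrc_cea.pipeline import evaluate_analysis
from mcrc_cea.sensitivity import (
    Outcome,
    ParamRange,
    PSAConfig,
    default_ranges,
    microsimulate,
    one_way_dsa,
)
from mcrc_cea.synthetic_data import SyntheticSpec, generate_strategies, to_config
from mcrc_cea.transitions import TransitionMatrix, build_transition_matrix


def test_raising_stable_utility_raises_qaly(analysis1):
    """Pushing u(stable) of RAS-Cetux from 0.85 to 0.89 must raise its QALY
    total and leave cost unchanged."""
    out_q = Outcome(kind="total_qaly", strategy="RAS-Cetux")
    entries = one_way_dsa(
        analysis1,
        [ParamRange(path="strategies.RAS-Cetux.utilities.stable", low=0.85, high=0.89, base=0.85)],
        out_q,
    )
    e = entries[0]
    assert e.outcome_at_high > e.outcome_at_low
    assert e.outcome_at_low == e.outcome_at_base  # low end is the base value
    out_c = Outcome(kind="total_cost", strategy="RAS-Cetux")
    c = one_way_dsa(
        analysis1,
        [ParamRange(path="strategies.RAS-Cetux.utilities.stable", low=0.85, high=0.89, base=0.85)],
        out_c,
    )[0]
    assert c.spread == 0.0


def test_degenerate_range_zero_spread(analysis1):
    entries = one_way_dsa(
        analysis1,
        [ParamRange(path="strategies.RAS-Bev.utilities.progressive", low=0.65, high=0.65, base=0.65)],
        Outcome(kind="cost_per_qaly", strategy="RAS-Bev"),
    )
    assert entries[0].spread == 0.0


def test_dsa_at_base_reproduces_base_bit_identically(analysis1):
    outcome = Outcome(kind="icer", intervention="RAS-Cetux", comparator="RAS-Bev")
    ranges = [
        ParamRange(path=r.path, low=r.base, high=r.base, base=r.base)
        for r in default_ranges(analysis1)
    ]
    entries = one_way_dsa(analysis1, ranges, outcome)
    for e in entries:
        assert e.outcome_at_low == e.outcome_at_base  # exact float equality
        assert e.outcome_at_high == e.outcome_at_base
        assert e.spread == 0.0


def test_irrelevant_parameter_has_zero_spread(analysis1):
    """The comparator's AE unit cost cannot move the intervention's cost/QALY."""
    entries = one_way_dsa(
        analysis1,
        [ParamRange(path="strategies.RAS-Bev.ae.events.0.unit_cost_usd", low=0.0, high=1000.0)],
        Outcome(kind="cost_per_qaly", strategy="RAS-Cetux"),
    )
    assert entries[0].spread == 0.0


def test_unresolvable_path_names_the_path(analysis1):
    with pytest.raises(ConfigError, match="no.such"):
        one_way_dsa(
            analysis1,
            [ParamRange(path="strategies.RAS-Bev.no.such", low=0.0, high=1.0)],
            Outcome(kind="total_cost", strategy="RAS-Bev"),
        )


def test_icer_spread_matches_brute_force_two_point():
    """Synthetic 2-strategy model: tornado ICER spread equals an independent
    two-point re-evaluation varying the comparator's death probability."""
    strategies, _ = generate_strategies(SyntheticSpec(n_strategies=2, seed=3))
    config = to_config(strategies, ModelSettings(horizon_cycles=900, stop_dead_fraction=1 - 1e-6))
    comp = strategies[1].name
    path = f"strategies.{comp}.transition_overrides.p_pd_to_dead"
    base_p = build_transition_matrix(strategies[1].survival).p_pd_to_dead
    lo, hi = 0.8 * base_p, 1.2 * base_p
    outcome = Outcome(kind="icer", intervention=strategies[0].name, comparator=comp)
    entry = one_way_dsa(config, [ParamRange(path=path, low=lo, high=hi, base=base_p)], outcome)[0]

    def brute(p):
        cfg = set_by_path(config, path, p)
        res = {o.name: o for o in evaluate_analysis(cfg, mode="engine")}
        i, c = res[strategies[0].name], res[comp]
        return icer((i.total_cost, i.total_qaly), (c.total_cost, c.total_qaly), decimals=None)

    assert entry.outcome_at_low == pytest.approx(brute(lo), rel=1e-12)
    assert entry.outcome_at_high == pytest.approx(brute(hi), rel=1e-12)
    assert entry.spread == pytest.approx(abs(brute(hi) - brute(lo)), rel=1e-12)


def test_tornado_sorted_by_spread(analysis1):
    entries = one_way_dsa(
        analysis1,
        default_ranges(analysis1)[:6],
        Outcome(kind="cost_per_qaly", strategy="KRAS-Cetux"),
    )
    spreads = [e.spread for e in entries]
    assert spreads == sorted(spreads, reverse=True)


# --- Monte Carlo -----------------------------------------------------------


def _fixture_model(analysis1, name="RAS-Bev"):
    s = analysis1.strategy(name)
    matrix = build_transition_matrix(s.survival)
    costs = build_state_costs(s)
    return s, matrix, costs


def test_same_seed_identical_draws(analysis1):
    s, matrix, costs = _fixture_model(analysis1)
    psa = PSAConfig(n_individuals=200, n_trials=5, seed=11)
    a = microsimulate(s, matrix, costs, analysis1.settings, psa)
    b = microsimulate(s, matrix, costs, analysis1.settings, psa)
    assert a.equals(b)
    c = microsimulate(s, matrix, costs, analysis1.settings, psa.model_copy(update={"seed": 12}))
    assert not a.equals(c)


def test_degenerate_matrix_zero_variance(analysis1):
    """Certain death after one SD cycle: every individual accrues exactly
    u_stable/12 QALY, so trial means have zero variance."""
    s, _, costs = _fixture_model(analysis1)
    matrix = TransitionMatrix(p_sd_to_pd=0.0, p_sd_to_dead=1.0, p_pd_to_dead=1.0)
    psa = PSAConfig(n_individuals=100, n_trials=8, seed=0)
    draws = microsimulate(s, matrix, costs, analysis1.settings, psa)
    assert draws["mean_qaly"].std() == 0.0
    assert draws["mean_qaly"].iloc[0] == pytest.approx(s.utilities.stable / 12.0, abs=1e-12)


def test_first_order_grand_mean_converges_to_cohort(analysis1):
    """Microsimulation grand means within 3 SE of the cohort-trace totals
    (the cohort trace is the expectation oracle)."""
    s, matrix, costs = _fixture_model(analysis1)
    settings = analysis1.settings.model_copy(update={"stop_dead_fraction": 1 - 1e-12})
    psa = PSAConfig(n_individuals=2000, n_trials=20, seed=5)
    with pytest.warns(UserWarning):
        trace = run_cohort(s, matrix, costs, settings)
    draws = microsimulate(s, matrix, costs, settings, psa)
    for col, target in (("mean_cost", trace.total_cost), ("mean_qaly", trace.total_qaly)):
        grand = draws[col].mean()
        se = draws[col].std(ddof=1) / np.sqrt(len(draws))
        assert abs(grand - target) <= 3 * se, f"{col}: {grand} vs {target} (se {se})"


def test_second_order_requires_distributions():
    with pytest.raises(ValueError, match="distributions"):
        PSAConfig(mode="second_order")


def test_second_order_redraws_parameters(analysis1):
    s, matrix, costs = _fixture_model(analysis1)
    psa = PSAConfig(
        n_individuals=100,
        n_trials=6,
        seed=2,
        mode="second_order",
        distributions={"utilities.stable": {"dist": "uniform", "low": 0.75, "high": 0.85}},
    )
    draws = microsimulate(s, matrix, costs, analysis1.settings, psa)
    # parameter noise on top of sampling noise: trial means must differ
    assert draws["mean_qaly"].nunique() > 1
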
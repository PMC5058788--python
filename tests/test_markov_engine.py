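"""Cohort engine: discounting, conservation, forced-transition traces, and
agreement with the closed-form expectation."""

import warnings

import numpy as np
import pytest

from mcrc_cea.costing import build_state_costs
from mcrc_cea.markov_engine import closed_form_expectation, monthly_discount_factor, run_cohort
from mcrc_cea.parameters import DiscountSpec, ModelSettings
from mcrc_cea.synthetic_data import SyntheticSpec, generate_strategies
from mcrc_cea.transitions import TransitionMatrix, build_transition_matrix

LONG = ModelSettings(horizon_cycles=3000, stop_dead_fraction=1 - 1e-12)
NO_DISCOUNT = ModelSettings(
    horizon_cycles=3000, stop_dead_fraction=1 - 1e-12, discount=DiscountSpec(annual_rate=0.0)
)


def test_discount_factor_closed_forms():
    spec = DiscountSpec(annual_rate=0.03)
    assert monthly_discount_factor(spec, 0) == 1.0
    assert monthly_discount_factor(spec, 12) == pytest.approx(1 / 1.03, abs=1e-12)
    assert monthly_discount_factor(DiscountSpec(annual_rate=0.0), 500) == 1.0
    with pytest.raises(ValueError):
        monthly_discount_factor(spec, -1)


def test_simple_monthly_conversion_differs_from_compound():
    simple = DiscountSpec(annual_rate=0.03, conversion="simple_monthly")
    compound = DiscountSpec(annual_rate=0.03)
    assert monthly_discount_factor(simple, 12) == pytest.approx((1 + 0.03 / 12) ** -12, abs=1e-12)
    assert monthly_discount_factor(simple, 12) < monthly_discount_factor(compound, 12)


def _synthetic_one(seed=0):
    strategies, _ = generate_strategies(SyntheticSpec(n_strategies=1, seed=seed))
    return strategies[0]


def test_forced_transitions_one_cycle_each_state():
    """p(sd->pd)=1, p(pd->dead)=1: one undiscounted cycle in each state."""
    s = _synthetic_one()
    matrix = TransitionMatrix(p_sd_to_pd=1.0, p_sd_to_dead=0.0, p_pd_to_dead=1.0)
    trace = run_cohort(s, matrix, build_state_costs(s), NO_DISCOUNT)
    assert len(trace.df) == 2
    assert trace.df["occupancy_dead"].iloc[-1] == pytest.approx(0.0)  # start-of-cycle occupancy
    assert trace.total_qaly == pytest.approx(
        (s.utilities.stable + s.utilities.progressive) / 12.0, abs=1e-12
    )


def test_occupancies_conserved_and_dead_monotone(analysis1):
    s = analysis1.strategy("RAS-Bev")
    trace = run_cohort(
        s, build_transition_matrix(s.survival), build_state_costs(s), analysis1.settings
    )
    occ = trace.df[["occupancy_sd", "occupancy_pd", "occupancy_dead"]].to_numpy()
    assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
    assert (np.diff(trace.df["occupancy_dead"]) >= -1e-15).all()
    assert trace.total_cost == pytest.approx(trace.df["cycle_cost"].sum(), abs=1e-6)
    assert trace.total_qaly == pytest.approx(trace.df["cycle_qaly"].sum(), abs=1e-9)


def test_undiscounted_life_months_match_geometric_means(analysis1):
    """Zero discount, long horizon: mean lifetime = 1/p1 + 1/p2 cycles."""
    s = analysis1.strategy("RAS-Bev")
    matrix = build_transition_matrix(s.survival)
    trace = run_cohort(s, matrix, build_state_costs(s), NO_DISCOUNT)
    life_months = 12.0 * (
        trace.df["cycle_qaly"].sum()
        - trace.df["occupancy_pd"].mul(0).sum()  # qaly = (sd*u_s + pd*u_p)/12
    )
    sd_months = trace.df["occupancy_sd"].sum()
    pd_months = trace.df["occupancy_pd"].sum()
    assert sd_months == pytest.approx(1.0 / matrix.p_sd_to_pd, rel=0.005)
    assert pd_months == pytest.approx(1.0 / matrix.p_pd_to_dead, rel=0.005)
    assert life_months > 0


def test_closed_form_trivial_half_probabilities():
    s = _synthetic_one()
    matrix = TransitionMatrix(p_sd_to_pd=0.5, p_sd_to_dead=0.0, p_pd_to_dead=0.5)
    costs = build_state_costs(s)
    _, qaly = closed_form_expectation(
        matrix, costs, s.utilities, DiscountSpec(annual_rate=0.0)
    )
    # two expected cycles in each state
    assert qaly == pytest.approx((2 * s.utilities.stable + 2 * s.utilities.progressive) / 12.0, abs=1e-12)


def test_closed_form_zero_utilities_zero_qaly(analysis1):
    s = analysis1.strategy("RAS-Bev")
    u = s.utilities.model_copy(update={"stable": 0.0, "progressive": 0.0})
    matrix = build_transition_matrix(s.survival)
    _, qaly = closed_form_expectation(matrix, build_state_costs(s), u, DiscountSpec())
    assert qaly == 0.0


def test_discounting_strictly_shrinks_totals(analysis1):
    s = analysis1.strategy("KRAS-Cetux")
    matrix = build_transition_matrix(s.survival)
    costs = build_state_costs(s)
    disc = run_cohort(s, matrix, costs, LONG)
    undisc = run_cohort(s, matrix, costs, NO_DISCOUNT)
    assert disc.total_cost < undisc.total_cost
    assert disc.total_qaly < undisc.total_qaly


def test_engine_matches_closed_form_over_synthetic_draws():
    """Engine totals vs analytic geometric-series expectation, 100 draws, 0.1%."""
    strategies, _ = generate_strategies(SyntheticSpec(n_strategies=100, seed=42))
    for s in strategies:
        matrix = build_transition_matrix(s.survival)
        costs = build_state_costs(s)
        trace = run_cohort(s, matrix, costs, LONG)
        ec, eq = closed_form_expectation(matrix, costs, s.utilities, LONG.discount)
        assert trace.total_cost == pytest.approx(ec, rel=1e-3)
        assert trace.total_qaly == pytest.approx(eq, rel=1e-3)


def test_closed_form_direct_death_series_matches_engine():
    s = _synthetic_one(seed=7)
    matrix = build_transition_matrix(s.survival, structure="direct_death")
    costs = build_state_costs(s)
    trace = run_cohort(s, matrix, costs, LONG)
    ec, eq = closed_form_expectation(matrix, costs, s.utilities, LONG.discount)
    assert trace.total_cost == pytest.approx(ec, rel=1e-3)
    assert trace.total_qaly == pytest.approx(eq, rel=1e-3)


def test_horizon_insensitive_beyond_stop_threshold(analysis1):
    s = analysis1.strategy("RAS-Bev")
    matrix = build_transition_matrix(s.survival)
    costs = build_state_costs(s)
    base = run_cohort(s, matrix, costs, ModelSettings(horizon_cycles=600, stop_dead_fraction=0.99999))
    double = run_cohort(s, matrix, costs, ModelSettings(horizon_cycles=1200, stop_dead_fraction=0.99999))
    assert double.total_cost == pytest.approx(base.total_cost, rel=1e-4)
    assert double.total_qaly == pytest.approx(base.total_qaly, rel=1e-4)


def test_nonterminating_settings_warn_and_cap_at_horizon():
    s = _synthetic_one()
    matrix = TransitionMatrix(p_sd_to_pd=0.1, p_sd_to_dead=0.0, p_pd_to_dead=0.0)
    settings = ModelSettings(horizon_cycles=50, stop_dead_fraction=1.0)
    with pytest.warns(UserWarning, match="horizon"):
        trace = run_cohort(s, matrix, build_state_costs(s), settings)
    assert trace.truncated_at_horizon
    assert len(trace.df) == 50


def test_half_cycle_correction_averages_occupancy():
    s = _synthetic_one()
    matrix = TransitionMatrix(p_sd_to_pd=1.0, p_sd_to_dead=0.0, p_pd_to_dead=1.0)
    settings = ModelSettings(
        horizon_cycles=10, stop_dead_fraction=1 - 1e-12,
        half_cycle_correction=True, discount=DiscountSpec(annual_rate=0.0),
    )
    trace = run_cohort(s, matrix, build_state_costs(s), settings)
    # half a cycle in SD, a full (half+half) cycle in PD, half in dead
    expected = (0.5 * s.utilities.stable + 1.0 * s.utilities.progressive) / 12.0
    assert trace.total_qaly == pytest.approx(expected, abs=1e-12)


def test_trace_csv_round_trip(tmp_path, analysis1):
    import pandas as pd

    s = analysis1.strategy("KRAS-Bev")
    trace = run_cohort(s, build_transition_matrix(s.survival), build_state_costs(s), analysis1.settings)
    p = tmp_path / "trace.csv"
    trace.to_csv(p)
    df = pd.read_csv(p, comment="#")
    assert len(df) == len(trace.df)
    header = p.read_text().splitlines()
    assert any("p_sd_to_pd" in line for line in header if line.startswith("#"))
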
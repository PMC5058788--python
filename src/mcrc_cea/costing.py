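"""Per-cycle, per-state cost assembly.

Stable-disease (on first-line treatment) monthly cost = biologic drug +
chemotherapy backbone + administration/monitoring + societal (travel and
absenteeism per clinic visit) + adverse-event management.  The first cycle
additionally carries the cetuximab loading-dose increment.  Progressive-
disease monthly cost = weighted subsequent-therapy cost + the same
administration/monitoring and societal fees at a post-progression visit
cadence.

Administrations on 7- or 14-day schedules are converted to the 1-month
cycle with a calendar-average month of 365.25/12 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import AEProfile, DosingSpec, StrategyDefinition

DAYS_PER_MONTH = 365.25 / 12.0

_SUPPORTED_SCHEDULES = (7, 14)


def drug_cost_per_admin(dosing: DosingSpec, unit_price: float, loading: bool = False) -> float:
    """Cost of one administration: body-size-scaled dose (mg) x price (USD/mg)."""
    if unit_price <= 0:
        raise ValueError(f"unit_price must be positive, got {unit_price}")
    if loading:
        if dosing.loading_dose_per_bsa_mg_m2 is None:
            raise ValueError("dosing spec has no loading dose")
        dose_mg = dosing.loading_dose_per_bsa_mg_m2 * dosing.bsa_m2
    elif dosing.dose_per_bsa_mg_m2 is not None:
        dose_mg = dosing.dose_per_bsa_mg_m2 * dosing.bsa_m2
    else:
        dose_mg = dosing.dose_per_kg_mg_kg * dosing.body_weight_kg
    return dose_mg * unit_price


def admin_schedule_to_monthly(cost_per_admin: float, schedule_days: int) -> float:
    """Convert a per-administration cost on a 7- or 14-day schedule to USD
    per monthly cycle (month = 365.25/12 days)."""
    if schedule_days not in _SUPPORTED_SCHEDULES:
        raise ValueError(f"unsupported schedule_days {schedule_days}; expected one of {_SUPPORTED_SCHEDULES}")
    return cost_per_admin * DAYS_PER_MONTH / schedule_days


def ae_monthly_cost(profile: AEProfile, duration_months: float | None = None) -> float:
    """Expected adverse-event management cost per month: the incidence-weighted
    sum of unit costs spread uniformly over ``duration_months`` (defaults to
    the profile's own spread duration).  An empty profile costs 0."""
    if duration_months is None:
        duration_months = profile.spread_duration_months
    if duration_months <= 0:
        raise ValueError(f"duration_months must be positive, got {duration_months}")
    total = sum(ev.incidence * ev.unit_cost_usd for ev in profile.events)
    return total / duration_months


@dataclass
class StateCostProfile:
    """Itemized per-cycle costs per health state; components always sum to
    the per-cycle totals."""

    cost_sd_first_cycle: float
    cost_sd_per_cycle: float
    cost_pd_per_cycle: float
    components: dict[str, dict[str, float]] = field(default_factory=dict)
    societal_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sd = sum(self.components.get("sd", {}).values())
        pd_ = sum(self.components.get("pd", {}).values())
        first = sd + self.components.get("sd_first_cycle_extra", {}).get("loading_increment", 0.0)
        if abs(sd - self.cost_sd_per_cycle) > 1e-6 or abs(pd_ - self.cost_pd_per_cycle) > 1e-6:
            raise ValueError("itemized components do not sum to per-cycle totals")
        if abs(first - self.cost_sd_first_cycle) > 1e-6:
            raise ValueError("first-cycle components do not sum to the first-cycle total")
        if self.cost_sd_first_cycle + 1e-9 < self.cost_sd_per_cycle:
            raise ValueError("first-cycle cost below steady-state cost despite loading dose")


def build_state_costs(strategy: StrategyDefinition) -> StateCostProfile:
    """Assemble the strategy's per-cycle cost profile from its dosing,
    schedule, AE and societal inputs."""
    costs = strategy.costs

    biologic_monthly = 0.0
    loading_increment = 0.0
    visit_schedules = [costs.backbone_schedule_days]
    for entry in strategy.dosing:
        per_admin = drug_cost_per_admin(entry.spec, entry.unit_price_usd_per_mg)
        biologic_monthly += admin_schedule_to_monthly(per_admin, entry.spec.schedule_days)
        if entry.spec.loading_dose_per_bsa_mg_m2 is not None:
            loading_per_admin = drug_cost_per_admin(entry.spec, entry.unit_price_usd_per_mg, loading=True)
            loading_increment += loading_per_admin - per_admin  # one extra-priced administration
        visit_schedules.append(entry.spec.schedule_days)

    backbone_monthly = admin_schedule_to_monthly(costs.backbone_cost_per_admin, costs.backbone_schedule_days)

    # clinic visits follow the most frequent component of the regimen
    sd_visits_per_month = DAYS_PER_MONTH / min(visit_schedules)
    societal_sd = sd_visits_per_month * costs.societal.cost_per_visit()
    societal_pd = costs.pd_visits_per_month * costs.societal.cost_per_visit()

    ae_sd = ae_monthly_cost(strategy.ae)

    sd_components = {
        "biologic_drug": biologic_monthly,
        "backbone_drug": backbone_monthly,
        "admin_monitoring": costs.admin_monitoring_cost_per_cycle,
        "societal": societal_sd,
        "adverse_events": ae_sd,
    }
    pd_components = {
        "progression_therapy": costs.progression_cost_per_month,
        "admin_monitoring": costs.admin_monitoring_cost_per_cycle,
        "societal": societal_pd,
    }
    sd_total = sum(sd_components.values())
    return StateCostProfile(
        cost_sd_first_cycle=sd_total + loading_increment,
        cost_sd_per_cycle=sd_total,
        cost_pd_per_cycle=sum(pd_components.values()),
        components={
            "sd": sd_components,
            "pd": pd_components,
            "sd_first_cycle_extra": {"loading_increment": loading_increment},
        },
        societal_rates={
            "travel_cost_per_visit": costs.societal.travel_cost_per_visit,
            "absenteeism_cost_per_day": costs.societal.absenteeism_cost_per_day,
            "absent_days_per_visit": costs.societal.absent_days_per_visit,
            "sd_visits_per_month": sd_visits_per_month,
            "pd_visits_per_month": costs.pd_visits_per_month,
        },
    )
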
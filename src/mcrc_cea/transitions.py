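"""Median time-to-event → monthly transition probabilities.

Under an exponential (memoryless) time-to-event assumption with monthly
cycles, a median of m months implies a constant per-cycle event probability

    P = 1 - (1/2)^(1/m) = 1 - exp(-R),   R = ln(2)/m,

so that the survivor fraction (1-P)^t reaches one half exactly at t = m.
The three-state structure (stable disease -> progressive disease -> dead,
dead absorbing) uses the PFS median for the progression hazard and the
post-progression median OS - PFS for the death hazard from progressive
disease; overall survival then decomposes as PFS + post-progression time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from .parameters import SurvivalSummary, TransitionOverrides

Structure = Literal["progression_required", "direct_death"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Monthly transition probabilities among {stable, progressive, dead};
    the dead row is implicitly absorbing ([0, 0, 1])."""

    p_sd_to_pd: float
    p_sd_to_dead: float
    p_pd_to_dead: float

    def __post_init__(self) -> None:
        for name in ("p_sd_to_pd", "p_sd_to_dead", "p_pd_to_dead"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_sd_to_pd + self.p_sd_to_dead > 1.0 + 1e-12:
            raise ValueError("p_sd_to_pd + p_sd_to_dead must not exceed 1")

    def as_array(self):
        import numpy as np

        p12, p13, p23 = self.p_sd_to_pd, self.p_sd_to_dead, self.p_pd_to_dead
        return np.array(
            [
                [1.0 - p12 - p13, p12, p13],
                [0.0, 1.0 - p23, p23],
                [0.0, 0.0, 1.0],
            ]
        )


def median_to_monthly_prob(median_months: float) -> float:
    """Per-cycle event probability implied by a median of ``median_months``.

    Strictly decreasing in the median; P(1) = 0.5 (half the cohort transits
    in a single one-month cycle).
    """
    if median_months <= 0:
        raise ValueError(f"median must be positive, got {median_months}")
    return 1.0 - math.exp(-math.log(2.0) / median_months)


def build_transition_matrix(
    survival: SurvivalSummary,
    structure: Structure = "progression_required",
    overrides: Optional[TransitionOverrides] = None,
) -> TransitionMatrix:
    """Assemble the monthly transition matrix from median PFS/OS.

    progression_required (default): death only via progressive disease;
    p(sd->pd) from the PFS median, p(pd->dead) from the post-progression
    median OS - PFS.  This keeps the two hazards identifiable from the two
    published medians.

    direct_death: a competing death risk from stable disease at the hazard
    implied by the OS median; the PFS-implied total exit probability from
    stable disease is split between progression and death.
    """
    pfs = survival.median_pfs_months
    os_ = survival.median_os_months
    if structure == "progression_required":
        p_sd_pd = median_to_monthly_prob(pfs)
        p_sd_dead = 0.0
        p_pd_dead = median_to_monthly_prob(os_ - pfs)
    elif structure == "direct_death":
        p_sd_dead = median_to_monthly_prob(os_)
        p_sd_pd = median_to_monthly_prob(pfs) - p_sd_dead
        p_pd_dead = median_to_monthly_prob(os_ - pfs)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    if overrides is not None:
        if overrides.p_sd_to_pd is not None:
            p_sd_pd = overrides.p_sd_to_pd
        if overrides.p_sd_to_dead is not None:
            p_sd_dead = overrides.p_sd_to_dead
        if overrides.p_pd_to_dead is not None:
            p_pd_dead = overrides.p_pd_to_dead
    return TransitionMatrix(p_sd_to_pd=p_sd_pd, p_sd_to_dead=p_sd_dead, p_pd_to_dead=p_pd_dead)
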
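"""Cost-effectiveness arithmetic: cost/QALY ratios, pairwise ICERs, strong
and extended dominance, the efficiency frontier, and the willingness-to-pay
decision rule.

Conventions: computations run at full floating precision; reported figures
are rounded half-up to 2 decimals (cents), matching standard presentation.
A negative ICER is returned as-is and must be read together with the
dominance classification (cheaper-and-better vs costlier-and-worse).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


def round_report(x: float, decimals: int = 2) -> float:
    """Round half-up (not banker's rounding) for report-facing figures."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CEResult:
    name: str
    total_cost: float
    total_qaly: float
    cost_per_qaly: float
    dominance: str = "nondominated"  # or "dominated"
    extended_dominated: bool = False
    icer_vs_comparator: Optional[float] = None  # vs previous frontier step
    comparator: Optional[str] = None


def cost_per_qaly(total_cost: float, total_qaly: float, decimals: Optional[int] = 2) -> float:
    """Average cost-effectiveness ratio (USD per QALY), reported to cents."""
    if total_qaly <= 0:
        raise ValueError(f"total_qaly must be positive, got {total_qaly}")
    ratio = total_cost / total_qaly
    return round_report(ratio, decimals) if decimals is not None else ratio


def icer(
    intervention: tuple[float, float] | CEResult,
    comparator: tuple[float, float] | CEResult,
    decimals: Optional[int] = 2,
) -> Optional[float]:
    """Incremental cost-effectiveness ratio ΔCost/ΔQALY of the intervention
    versus the comparator.

    Returns None when ΔQALY is exactly 0 (undefined; no infinity
    arithmetic).  A negative value means one strategy dominates the other:
    interpret alongside the sign of ΔQALY.
    """
    ic, iq = (intervention.total_cost, intervention.total_qaly) if isinstance(intervention, CEResult) else intervention
    cc, cq = (comparator.total_cost, comparator.total_qaly) if isinstance(comparator, CEResult) else comparator
    dq = iq - cq
    if dq == 0:
        return None
    value = (ic - cc) / dq
    return round_report(value, decimals) if decimals is not None else value


def _strongly_dominated(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True if a is dominated by b: b costs no more, yields no fewer QALYs,
    with at least one strict inequality."""
    return (
        b[0] <= a[0]
        and b[1] >= a[1]
        and (b[0] < a[0] or b[1] > a[1])
    )


def classify_dominance(
    results: Sequence[tuple[str, float, float]] | Sequence[CEResult],
) -> tuple[list[CEResult], list[CEResult]]:
    """Label strong dominance and build the efficiency frontier.

    Returns (labelled results in input order, frontier).  The frontier is
    the nondominated set sorted by ascending QALY (ties: lower cost, then
    name), with each step's ICER versus the previous frontier strategy.
    Strategies whose frontier ICER exceeds the next step's are additionally
    flagged extended-dominated (weak dominance) but stay on the frontier,
    since only strong dominance drives the 'dominated' label.
    """
    pts: list[CEResult] = []
    for r in results:
        if isinstance(r, CEResult):
            pts.append(r)
        else:
            name, c, q = r
            pts.append(CEResult(name=name, total_cost=c, total_qaly=q, cost_per_qaly=cost_per_qaly(c, q)))
    for r in pts:
        r.dominance = "nondominated"
        r.extended_dominated = False
        r.icer_vs_comparator = None
        r.comparator = None
    for r in pts:
        for other in pts:
            if other is r:
                continue
            if _strongly_dominated((r.total_cost, r.total_qaly), (other.total_cost, other.total_qaly)):
                r.dominance = "dominated"
                break
    frontier = sorted(
        (r for r in pts if r.dominance == "nondominated"),
        key=lambda r: (r.total_qaly, r.total_cost, r.name),
    )
    for prev, cur in zip(frontier, frontier[1:]):
        cur.icer_vs_comparator = icer(cur, prev)
        cur.comparator = prev.name
    # extended (weak) dominance: a frontier step whose ICER exceeds the next
    steps = [r for r in frontier if r.icer_vs_comparator is not None]
    for s1, s2 in zip(steps, steps[1:]):
        if s1.icer_vs_comparator > s2.icer_vs_comparator:
            s1.extended_dominated = True
    return pts, frontier


def wtp_decision(icer_value: Optional[float], threshold: float) -> str:
    """Willingness-to-pay rule: a defined ICER is 'acceptable' iff it does
    not exceed the threshold (a negative ICER from a dominant intervention
    is acceptable); an undefined ICER defers to dominance."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if icer_value is None:
        return "defer_to_dominance"
    return "acceptable" if icer_value <= threshold else "not_acceptable"
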
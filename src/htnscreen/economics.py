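"""Cost and QALY accrual, ICERs with dominance, threshold comparison.

Costs integrate four components per cycle: screening rounds, annual
antihypertensive treatment (charged to every treated state, including
treated CVD states, since therapy persists), the first year after an acute
CVD event (acute-state occupancy) and stable CVD follow-up.  QALYs weight
state occupancy by health-state utilities; deaths accrue nothing in the
cycle they occur (no half-cycle correction).  Both streams discount at
their own annual rate with cycle 0 undiscounted.  Results are reported per
1,000 cohort entrants, the scale on which ICERs are also quoted (the ratio
itself is scale-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    ACUTE_STATES,
    HEALTHY,
    HTN_DIAG_UNTREATED,
    HTN_TREATED,
    HTN_UNDIAG,
    STABLE_STATES,
    STATE_NAMES,
    TREATED_STATES,
    Trace,
)
from .parameters import EconInputs, Scenario

REPORT_SCALE = 1000.0


@dataclass(frozen=True)
class CEResult:
    """Discounted totals for one scenario, per 1,000 entrants."""

    scenario: Scenario
    total_cost: float          # Int$ per 1,000 entrants
    total_qaly: float          # QALYs per 1,000 entrants
    qaly_per_entrant: float
    discount_cost: float
    discount_qaly: float


@dataclass(frozen=True)
class IcerOutcome:
    """ICER of a strategy against its comparator.

    ``kind`` is ``ratio`` (Int$/QALY in ``value``), ``dominant`` (cheaper
    and more effective), ``dominated`` (costlier and less effective) or
    ``undefined`` (zero QALY difference).
    """

    kind: str
    value: float | None = None
    delta_cost: float = 0.0
    delta_qaly: float = 0.0

    def __str__(self) -> str:
        if self.kind == "ratio":
            return f"{self.value:,.0f}"
        return self.kind


def state_utilities(econ: EconInputs, sex: str,
                    utility_set: dict[str, float] | None = None) -> np.ndarray:
    """Utility weight per model state for one sex.

    ``utility_set`` optionally replaces the base utilities with an
    alternative quadruple keyed healthy/htn/acute/stable (e.g. the
    GBD-derived set); dead states weigh zero.
    """
    if utility_set is None:
        u_healthy = econ.utility_healthy
        u_htn = econ.utility_htn[sex]
        u_acute = econ.utility_acute
        u_stable = econ.utility_stable[sex]
    else:
        u_healthy = utility_set["healthy"]
        u_htn = utility_set["htn"]
        u_acute = utility_set["acute"]
        u_stable = utility_set["stable"]
    u = np.zeros(len(STATE_NAMES))
    u[HEALTHY] = u_healthy
    u[[HTN_UNDIAG, HTN_DIAG_UNTREATED, HTN_TREATED]] = u_htn
    u[list(ACUTE_STATES)] = u_acute
    u[list(STABLE_STATES)] = u_stable
    return u


def accrue(trace: Trace, econ: EconInputs,
           utility_set: dict[str, float] | None = None) -> CEResult:
    """Discounted cost and QALY totals over a Trace.

    Cycle ``t`` accrues on the post-transition occupancy (states row
    ``t + 1``) plus that cycle's screening tally, discounted by
    ``(1 + rate)^-t`` so the first cycle is undiscounted.
    """
    T = trace.n_cycles
    occ = trace.states[1:]
    t_idx = np.arange(T)
    disc_c = (1.0 + econ.discount_cost) ** -t_idx
    disc_q = (1.0 + econ.discount_qaly) ** -t_idx

    treated_occ = occ[:, list(TREATED_STATES)].sum(axis=1)
    acute_occ = occ[:, list(ACUTE_STATES)].sum(axis=1)
    stable_occ = occ[:, list(STABLE_STATES)].sum(axis=1)
    cost_t = (
        trace.screened * econ.cost_screen_round
        + treated_occ * econ.cost_htn_treat_year
        + acute_occ * econ.cost_cvd_acute_year
        + stable_occ * econ.cost_cvd_stable_year
    )
    u = state_utilities(econ, trace.scenario.sex, utility_set)
    qaly_t = occ @ u

    total_cost = float(cost_t @ disc_c)
    total_qaly = float(qaly_t @ disc_q)
    return CEResult(
        scenario=trace.scenario,
        total_cost=total_cost * REPORT_SCALE,
        total_qaly=total_qaly * REPORT_SCALE,
        qaly_per_entrant=total_qaly,
        discount_cost=econ.discount_cost,
        discount_qaly=econ.discount_qaly,
    )


def icer(intervention: CEResult | tuple[float, float],
         comparator: CEResult | tuple[float, float]) -> IcerOutcome:
    """Incremental cost-effectiveness of ``intervention`` vs ``comparator``.

    Accepts CEResults or raw ``(cost, qaly)`` pairs.  Sign logic: ratio
    dC/dE whenever dE != 0 (negative dC with positive dE is dominant,
    positive dC with negative dE dominated); dE == 0 yields an undefined
    ratio.
    """
    c_i, e_i = (
        (intervention.total_cost, intervention.total_qaly)
        if isinstance(intervention, CEResult) else intervention
    )
    c_0, e_0 = (
        (comparator.total_cost, comparator.total_qaly)
        if isinstance(comparator, CEResult) else comparator
    )
    dc, de = c_i - c_0, e_i - e_0
    if de == 0.0:
        return IcerOutcome("undefined", None, dc, de)
    if dc < 0.0 and de > 0.0:
        return IcerOutcome("dominant", None, dc, de)
    if dc > 0.0 and de < 0.0:
        return IcerOutcome("dominated", None, dc, de)
    return IcerOutcome("ratio", dc / de, dc, de)


def wtp_threshold(gdp_per_capita: float, multiplier: float,
                  override: float | None = None) -> float:
    """Willingness-to-pay threshold: multiplier x GDP per capita (PPP),
    unless an explicit override is configured."""
    if override is not None:
        return float(override)
    if gdp_per_capita <= 0:
        raise ValueError(f"GDP per capita must be positive, got {gdp_per_capita}")
    return gdp_per_capita * multiplier


def is_cost_effective(outcome: IcerOutcome, threshold: float) -> bool:
    """Net-monetary-benefit rule: threshold * dQALY - dCost >= 0.

    Equivalent to ICER <= threshold in the normal quadrant (a ratio exactly
    at the threshold counts as cost-effective) and handles the dominance
    quadrants and the undefined case consistently.
    """
    return threshold * outcome.delta_qaly - outcome.delta_cost >= 0.0


def compare_strategies(results: list[CEResult], threshold: float) -> pd.DataFrame:
    """Tabulate every strategy against the no-screening comparator.

    Returns one row per strategy with totals, increments, the ICER or
    dominance label, and the cost-effectiveness flag at ``threshold``.
    Raises if no result has strategy ``none``.
    """
    comparators = [r for r in results if r.scenario.strategy == "none"]
    if not comparators:
        raise ValueError("compare_strategies requires a 'none' (no-screening) result")
    base = comparators[0]
    rows = []
    for r in results:
        out = icer(r, base)
        rows.append({
            "strategy": r.scenario.label(),
            "total_cost": r.total_cost,
            "total_qaly": r.total_qaly,
            "incr_cost": out.delta_cost if r is not base else np.nan,
            "incr_qaly": out.delta_qaly if r is not base else np.nan,
            "icer_or_dominance": str(out) if r is not base else "",
            "cost_effective": is_cost_effective(out, threshold) if r is not base else np.nan,
        })
    return pd.DataFrame(rows)
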
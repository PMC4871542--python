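"""Markov cohort engine: initial decision tree, screening schedule, cycling.

The cohort is a mass distribution over ten health states.  Entry (the
decision tree) splits the population into healthy, an unaware hypertensive
pool detectable only by screening, and a symptom-aware pool of whom a
treatment-uptake fraction is on therapy.  Each one-year cycle then applies,
in order: screening (at scheduled cycles), state transitions, accrual.
Screening diagnoses the entire unaware pool present at that cycle and moves
the uptake share onto treatment.  Treatment status persists through the
acute and stable CVD states, so relative risks keep applying to recurrences.
No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, Scenario
from .risk_engine import transition_probs

# State indices
HEALTHY = 0
HTN_UNDIAG = 1
HTN_DIAG_UNTREATED = 2
HTN_TREATED = 3
ACUTE_UNTREATED = 4
ACUTE_TREATED = 5
STABLE_UNTREATED = 6
STABLE_TREATED = 7
DEAD_CVD = 8
DEAD_NONCVD = 9

N_STATES = 10
STATE_NAMES = (
    "healthy",
    "htn_undiagnosed",
    "htn_diagnosed_untreated",
    "htn_treated",
    "acute_cvd_untreated",
    "acute_cvd_treated",
    "stable_cvd_untreated",
    "stable_cvd_treated",
    "dead_cvd",
    "dead_noncvd",
)
DEAD_STATES = (DEAD_CVD, DEAD_NONCVD)
TREATED_STATES = (HTN_TREATED, ACUTE_TREATED, STABLE_TREATED)
ACUTE_STATES = (ACUTE_UNTREATED, ACUTE_TREATED)
STABLE_STATES = (STABLE_UNTREATED, STABLE_TREATED)

MASS_TOL = 1e-9


class ConservationError(RuntimeError):
    """Cohort mass not conserved within tolerance."""


@dataclass
class Trace:
    """Per-cycle record of one scenario run.

    ``states`` has ``n_cycles + 1`` rows: the entry distribution followed by
    the post-transition distribution of each cycle.  ``screened``,
    ``new_acute`` and ``newly_treated`` are per-cycle tallies (length
    ``n_cycles``).  ``n_truncated`` counts source states whose exit
    probabilities were renormalized during degenerate parameter draws.
    """

    scenario: Scenario
    states: np.ndarray
    ages: np.ndarray
    screened: np.ndarray
    new_acute: np.ndarray
    newly_treated: np.ndarray
    n_truncated: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.screened)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per cycle with state occupancies."""
        rows = []
        for t in range(self.n_cycles):
            row = {"cycle": t, "age": self.ages[t]}
            row.update({name: self.states[t + 1, i] for i, name in enumerate(STATE_NAMES)})
            row["screened"] = self.screened[t]
            row["new_acute"] = self.new_acute[t]
            rows.append(row)
        return pd.DataFrame(rows)


def build_schedule(scenario: Scenario, n_cycles: int | None = None) -> frozenset[int]:
    """Cycle indices at which screening occurs for ``scenario``.

    one_off -> {0}; annual -> every cycle; biannual -> every other cycle;
    biannual_then_annual -> biannual while cohort age < switch_age, annual
    thereafter; none -> empty set.
    """
    if n_cycles is None:
        n_cycles = scenario.n_cycles()
    strat = scenario.strategy
    if strat not in Scenario.STRATEGIES:
        raise ValueError(f"unknown strategy {strat!r}; valid: {Scenario.STRATEGIES}")
    if strat == "none":
        return frozenset()
    if strat == "one_off":
        return frozenset({0})
    if strat == "annual":
        return frozenset(range(n_cycles))
    if strat == "biannual":
        return frozenset(range(0, n_cycles, 2))
    # biannual_then_annual
    if scenario.switch_age is None or scenario.switch_age <= scenario.start_age:
        raise ValueError(
            f"biannual_then_annual requires switch_age > start_age "
            f"(got {scenario.switch_age}, start {scenario.start_age})"
        )
    cycles = set()
    for t in range(n_cycles):
        age = scenario.start_age + t
        if age >= scenario.switch_age:
            cycles.add(t)
        elif t % 2 == 0:
            cycles.add(t)
    return frozenset(cycles)


def initial_distribution(scenario: Scenario, params: ParameterSet) -> np.ndarray:
    """Entry state distribution from the decision tree.

    healthy = 1 - total prevalence; the symptom-aware pool is diagnosed at
    entry, with the effective uptake share treated; the screen-detectable
    pool (plus any residual prevalence) starts undiagnosed; CVD states are
    empty.
    """
    total, detect, aware = params.epi.prevalence.lookup(scenario.start_age, scenario.sex)
    scale = params.epi.prev_scale
    total, detect, aware = total * scale, detect * scale, aware * scale
    if not (0.0 <= total <= 1.0 and 0.0 <= detect <= 1.0 and 0.0 <= aware <= 1.0):
        raise ValueError(
            f"scaled prevalence outside [0, 1] at age {scenario.start_age} "
            f"(total={total:.3f}, scale={scale})"
        )
    if detect + aware > total + 1e-9:
        raise ValueError(
            f"screen-detectable {detect:.3f} + aware {aware:.3f} exceeds "
            f"total prevalence {total:.3f}"
        )
    uptake_eff = scenario.effective_uptake(params.epi.uptake[scenario.sex])
    v = np.zeros(N_STATES)
    v[HEALTHY] = 1.0 - total
    v[HTN_UNDIAG] = detect + max(total - detect - aware, 0.0)
    v[HTN_TREATED] = aware * uptake_eff
    v[HTN_DIAG_UNTREATED] = aware * (1.0 - uptake_eff)
    if np.any(v < -1e-12) or np.any(v > 1.0 + 1e-12):
        raise ValueError(f"initial state masses outside [0, 1]: {v}")
    return v


def apply_screening(v: np.ndarray, uptake_effective: float) -> tuple[np.ndarray, float]:
    """One screening round: diagnose the whole unaware pool.

    Of the newly diagnosed, ``uptake_effective`` start treatment and the
    rest remain diagnosed-untreated.  Healthy people are screened (and
    counted for costing) but do not change state.  Returns the new vector
    and the screened mass.
    """
    if not 0.0 <= uptake_effective <= 1.0:
        raise ValueError(f"uptake {uptake_effective} outside [0, 1]")
    out = v.copy()
    screened = v[HEALTHY] + v[HTN_UNDIAG]
    moved = v[HTN_UNDIAG]
    out[HTN_TREATED] += moved * uptake_effective
    out[HTN_DIAG_UNTREATED] += moved * (1.0 - uptake_effective)
    out[HTN_UNDIAG] = 0.0
    return out, screened


def _allocate(exits: list[float], renormalize: bool,
              label: str) -> tuple[list[float], float, bool]:
    """Stay-probability for a source state given its exit probabilities.

    If the exits sum beyond 1 the stay mass would be negative; with
    ``renormalize`` the stay probability is truncated to zero and the exits
    rescaled to sum to one (degenerate PSA draws), otherwise this is an
    error naming the state.
    """
    s = sum(exits)
    if s <= 1.0 + 1e-12:
        return exits, max(1.0 - s, 0.0), False
    if not renormalize:
        raise ValueError(f"exit probabilities from state {label!r} sum to {s:.4f} > 1")
    return [p / s for p in exits], 0.0, True


def step(v: np.ndarray, age: float, sex: str, params: ParameterSet,
         renormalize: bool = False) -> tuple[np.ndarray, float, float, int]:
    """Advance the cohort one cycle.

    Returns ``(v_next, new_acute_events, symptom_diagnosed, n_truncated)``.
    New acute events count inflows to the acute states plus recurrent events
    of people already acute.  Dead states are absorbing; mass is conserved
    to 1e-9 or a ``ConservationError`` is raised.
    """
    tp_u = transition_probs(age, sex, treated=False, params=params,
                            check=not renormalize)
    tp_t = transition_probs(age, sex, treated=True, params=params,
                            check=not renormalize)
    out = np.zeros(N_STATES)
    n_trunc = 0
    new_acute = 0.0

    # healthy: incident hypertension (entering undiagnosed) or non-CVD death
    exits, stay, tr = _allocate(
        [tp_u.p_incidence, tp_u.p_noncvd_death], renormalize, "healthy")
    n_trunc += tr
    out[HTN_UNDIAG] += v[HEALTHY] * exits[0]
    out[DEAD_NONCVD] += v[HEALTHY] * exits[1]
    out[HEALTHY] += v[HEALTHY] * stay

    # hypertension states: acute CVD, fatal CVD, non-CVD death, or stay
    for src, tp, acute_dst in (
        (HTN_UNDIAG, tp_u, ACUTE_UNTREATED),
        (HTN_DIAG_UNTREATED, tp_u, ACUTE_UNTREATED),
        (HTN_TREATED, tp_t, ACUTE_TREATED),
    ):
        exits, stay, tr = _allocate(
            [tp.p_nonfatal_cvd, tp.p_fatal_cvd, tp.p_noncvd_death],
            renormalize, STATE_NAMES[src])
        n_trunc += tr
        mass = v[src]
        out[acute_dst] += mass * exits[0]
        new_acute += mass * exits[0]
        out[DEAD_CVD] += mass * exits[1]
        out[DEAD_NONCVD] += mass * exits[2]
        out[src] += mass * stay

    # acute CVD: death (acute->fatal + non-CVD), recurrent acute (stay in
    # acute), remainder stabilises
    for src, tp in ((ACUTE_UNTREATED, tp_u), (ACUTE_TREATED, tp_t)):
        stable_dst = STABLE_UNTREATED if src == ACUTE_UNTREATED else STABLE_TREATED
        exits, to_stable, tr = _allocate(
            [tp.p_acute_to_fatal, tp.p_noncvd_death, tp.p_nonfatal_cvd],
            renormalize, STATE_NAMES[src])
        n_trunc += tr
        mass = v[src]
        out[DEAD_CVD] += mass * exits[0]
        out[DEAD_NONCVD] += mass * exits[1]
        out[src] += mass * exits[2]  # recurrent event, stays acute
        new_acute += mass * exits[2]
        out[stable_dst] += mass * to_stable

    # stable CVD: recurrence back to acute, fatal CVD, non-CVD death, stay
    for src, tp in ((STABLE_UNTREATED, tp_u), (STABLE_TREATED, tp_t)):
        acute_dst = ACUTE_UNTREATED if src == STABLE_UNTREATED else ACUTE_TREATED
        exits, stay, tr = _allocate(
            [tp.p_nonfatal_cvd, tp.p_fatal_cvd, tp.p_noncvd_death],
            renormalize, STATE_NAMES[src])
        n_trunc += tr
        mass = v[src]
        out[acute_dst] += mass * exits[0]
        new_acute += mass * exits[0]
        out[DEAD_CVD] += mass * exits[1]
        out[DEAD_NONCVD] += mass * exits[2]
        out[src] += mass * stay

    # dead states are absorbing
    out[DEAD_CVD] += v[DEAD_CVD]
    out[DEAD_NONCVD] += v[DEAD_NONCVD]

    # optional background (symptomatic) diagnosis of surviving unaware cases
    sdp = params.epi.symptomatic_diagnosis_prob
    diagnosed = 0.0
    if sdp > 0.0:
        diagnosed = out[HTN_UNDIAG] * sdp
        uptake = params.epi.uptake[sex]
        out[HTN_UNDIAG] -= diagnosed
        out[HTN_TREATED] += diagnosed * uptake
        out[HTN_DIAG_UNTREATED] += diagnosed * (1.0 - uptake)

    if abs(out.sum() - v.sum()) > MASS_TOL:
        raise ConservationError(
            f"mass changed by {out.sum() - v.sum():.3e} in one cycle (age {age})"
        )
    return out, new_acute, diagnosed, n_trunc


def run_cohort(scenario: Scenario, params: ParameterSet,
               renormalize: bool = False) -> Trace:
    """Run the full cohort model for one scenario and return its Trace.

    The horizon is 10 cycles (ten_year) or until the cohort reaches the end
    of the life table (lifetime).  Screening is applied at scheduled cycles
    before the transition of that cycle.
    """
    n_cycles = scenario.n_cycles(max_age=params.life_table.max_age)
    schedule = build_schedule(scenario, n_cycles)
    uptake_eff = scenario.effective_uptake(params.epi.uptake[scenario.sex])

    states = np.zeros((n_cycles + 1, N_STATES))
    ages = np.array([scenario.start_age + t for t in range(n_cycles + 1)], dtype=float)
    screened = np.zeros(n_cycles)
    new_acute = np.zeros(n_cycles)
    newly_treated = np.zeros(n_cycles)
    n_trunc = 0

    v = initial_distribution(scenario, params)
    states[0] = v
    for t in range(n_cycles):
        if t in schedule:
            before_treated = v[HTN_TREATED]
            v, screened[t] = apply_screening(v, uptake_eff)
            newly_treated[t] = v[HTN_TREATED] - before_treated
        v, acute_t, _, tr = step(v, ages[t], scenario.sex, params,
                                 renormalize=renormalize)
        n_trunc += tr
        new_acute[t] = acute_t
        states[t + 1] = v
        if abs(v.sum() - 1.0) > MASS_TOL:
            raise ConservationError(
                f"total mass {v.sum():.12f} deviates from 1 at cycle {t}"
            )
    return Trace(
        scenario=scenario,
        states=states,
        ages=ages,
        screened=screened,
        new_acute=new_acute,
        newly_treated=newly_treated,
        n_truncated=n_trunc,
    )
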
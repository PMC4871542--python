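"""Decision tree, screening schedule and Markov cohort engine."""

import copy

import numpy as np
import pytest

import htnscreen as h
from htnscreen.cohort import (
    ACUTE_UNTREATED,
    DEAD_CVD,
    DEAD_NONCVD,
    DEAD_STATES,
    HEALTHY,
    HTN_DIAG_UNTREATED,
    HTN_TREATED,
    HTN_UNDIAG,
    N_STATES,
)
from htnscreen.risk_engine import transition_probs


def scen(**kw):
    base = dict(sex="male", start_age=55, horizon="ten_year", strategy="none")
    base.update(kw)
    return h.Scenario(**base)


class TestSchedule:
    @pytest.mark.parametrize(
        "kw,expected",
        [
            (dict(strategy="one_off"), {0}),
            (dict(strategy="none"), set()),
            (dict(strategy="annual"), set(range(10))),
            (dict(strategy="biannual", start_age=45), {0, 2, 4, 6, 8}),
        ],
    )
    def test_ten_year_schedules(self, kw, expected):
        assert set(h.build_schedule(scen(**kw))) == expected

    def test_biannual_then_annual_switches_at_age(self):
        s = scen(strategy="biannual_then_annual", start_age=45,
                 horizon="lifetime", switch_age=55)
        sched = sorted(h.build_schedule(s, n_cycles=15))
        assert sched == [0, 2, 4, 6, 8, 10, 11, 12, 13, 14]

    def test_switch_age_must_exceed_start_age(self):
        s = scen(strategy="biannual_then_annual", start_age=55, switch_age=55)
        with pytest.raises(ValueError, match="switch_age"):
            h.build_schedule(s)


class TestInitialDistribution:
    def test_hand_computed_split(self, params):
        # total 0.20 = aware 0.08 + screen-detectable 0.12; uptake 48%
        p2 = copy.deepcopy(params)
        prev = p2.epi.prevalence
        prev.total["male"][:] = 0.20
        prev.screen_detect["male"][:] = 0.12
        prev.aware["male"][:] = 0.08
        v = h.initial_distribution(scen(), p2)
        assert v[HEALTHY] == pytest.approx(0.80)
        assert v[HTN_UNDIAG] == pytest.approx(0.12)
        assert v[HTN_TREATED] == pytest.approx(0.08 * 0.48)
        assert v[HTN_DIAG_UNTREATED] == pytest.approx(0.08 * 0.52)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_prevalence_all_healthy(self, params):
        p2 = copy.deepcopy(params)
        for sex in h.SEXES:
            for tbl in (p2.epi.prevalence.total, p2.epi.prevalence.screen_detect,
                        p2.epi.prevalence.aware):
                tbl[sex][:] = 0.0
        v = h.initial_distribution(scen(), p2)
        assert v[HEALTHY] == 1.0 and v.sum() == 1.0

    def test_coverage_multiplier_scales_entry_uptake(self, params):
        s = scen(sex="female", strategy="annual", coverage_multiplier=1.2)
        v = h.initial_distribution(s, params)
        aware = v[HTN_TREATED] + v[HTN_DIAG_UNTREATED]
        assert v[HTN_TREATED] / aware == pytest.approx(0.62 * 1.2)  # 0.744

    def test_absolute_coverage_mode(self, params):
        s = scen(sex="male", strategy="annual", coverage_multiplier=1.2,
                 coverage_mode="absolute")
        v = h.initial_distribution(s, params)
        aware = v[HTN_TREATED] + v[HTN_DIAG_UNTREATED]
        assert v[HTN_TREATED] / aware == pytest.approx(0.48 + 0.2)


class TestScreening:
    def test_hand_computed_round(self):
        v = np.zeros(N_STATES)
        v[HEALTHY], v[HTN_UNDIAG] = 0.9, 0.10
        out, screened = h.apply_screening(v, uptake_effective=0.48)
        assert screened == pytest.approx(1.0)
        assert out[HTN_TREATED] == pytest.approx(0.048)
        assert out[HTN_DIAG_UNTREATED] == pytest.approx(0.052)
        assert out[HTN_UNDIAG] == 0.0

    def test_zero_uptake_all_diagnosed_untreated(self):
        v = np.zeros(N_STATES)
        v[HTN_UNDIAG] = 0.3
        out, _ = h.apply_screening(v, 0.0)
        assert out[HTN_DIAG_UNTREATED] == pytest.approx(0.3)
        assert out[HTN_TREATED] == 0.0

    def test_no_undiagnosed_leaves_state_unchanged(self):
        v = np.zeros(N_STATES)
        v[HEALTHY] = 1.0
        out, screened = h.apply_screening(v, 0.5)
        np.testing.assert_array_equal(out, v)
        assert screened == 1.0


class TestStep:
    def test_dead_states_absorbing(self, params):
        v = np.zeros(N_STATES)
        v[DEAD_CVD], v[DEAD_NONCVD] = 0.4, 0.6
        out, acute, _, _ = h.step(v, 60, "male", params)
        np.testing.assert_array_equal(out, v)
        assert acute == 0.0

    def test_one_cycle_from_pure_untreated_hypertension(self, params):
        """Occupancy after one cycle matches an independent hand product."""
        tp = transition_probs(55, "male", treated=False, params=params)
        v = np.zeros(N_STATES)
        v[HTN_DIAG_UNTREATED] = 1.0
        out, acute, _, _ = h.step(v, 55, "male", params)
        stay = 1 - tp.p_nonfatal_cvd - tp.p_fatal_cvd - tp.p_noncvd_death
        assert out[ACUTE_UNTREATED] == pytest.approx(tp.p_nonfatal_cvd, rel=1e-12)
        assert out[DEAD_CVD] == pytest.approx(tp.p_fatal_cvd, rel=1e-12)
        assert out[DEAD_NONCVD] == pytest.approx(tp.p_noncvd_death, rel=1e-12)
        assert out[HTN_DIAG_UNTREATED] == pytest.approx(stay, rel=1e-12)
        assert acute == pytest.approx(tp.p_nonfatal_cvd, rel=1e-12)

    def test_treatment_reduces_cumulative_acute_events(self, params):
        p_rr1 = copy.deepcopy(params)
        p_rr1.epi.rr_acute = 1.0
        p_rr1.epi.rr_death = 1.0
        s = scen(strategy="annual")
        events_rr1 = h.run_cohort(s, p_rr1).new_acute.sum()
        events_rr072 = h.run_cohort(s, params).new_acute.sum()
        assert events_rr072 <= events_rr1


class TestRunCohort:
    def test_ten_year_trace_has_ten_transitions(self, params):
        tr = h.run_cohort(scen(strategy="one_off"), params)
        assert tr.n_cycles == 10
        assert tr.states.shape == (11, N_STATES)

    def test_lifetime_runs_to_end_of_life_table(self, params):
        tr = h.run_cohort(scen(strategy="annual", horizon="lifetime"), params)
        assert tr.n_cycles == 100 - 55

    def test_mass_conserved_every_cycle(self, params):
        for s in h.standard_scenarios("female", 45, "ten_year"):
            tr = h.run_cohort(s, params)
            np.testing.assert_allclose(tr.states.sum(axis=1), 1.0, atol=1e-9)

    def test_dead_nondecreasing_healthy_nonincreasing(self, params):
        tr = h.run_cohort(scen(strategy="biannual", horizon="lifetime"), params)
        dead = tr.states[:, list(DEAD_STATES)].sum(axis=1)
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(np.diff(tr.states[:, HEALTHY]) <= 1e-12)

    def test_screening_increases_treatment_and_reduces_events(self, params):
        tr_none = h.run_cohort(scen(strategy="none"), params)
        tr_scr = h.run_cohort(scen(strategy="annual"), params)
        assert np.all(tr_scr.states[:, HTN_TREATED] >= tr_none.states[:, HTN_TREATED] - 1e-12)
        assert tr_scr.new_acute.sum() <= tr_none.new_acute.sum()

    def test_no_prevalence_makes_screening_moot(self, params):
        p2 = copy.deepcopy(params)
        for sex in h.SEXES:
            for tbl in (p2.epi.prevalence.total, p2.epi.prevalence.screen_detect,
                        p2.epi.prevalence.aware):
                tbl[sex][:] = 0.0
        p2.epi.incidence_prob = {s: 0.0 for s in h.SEXES}
        tr_none = h.run_cohort(scen(strategy="none"), p2)
        tr_one = h.run_cohort(scen(strategy="one_off"), p2)
        np.testing.assert_allclose(tr_one.states, tr_none.states, atol=1e-15)
        assert tr_one.screened[0] > 0 and tr_none.screened.sum() == 0

    def test_trace_csv_export_shape(self, params):
        df = h.run_cohort(scen(strategy="biannual"), params).to_frame()
        assert len(df) == 10
        assert {"cycle", "age", "screened", "new_acute", *h.STATE_NAMES} <= set(df.columns)
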
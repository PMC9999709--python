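"""Cohort engine: tunnel mechanics, conservation, discounting and costing
rules, and the closed-form annuity check."""

import copy

import numpy as np
import pytest
from hypothesis import given, strategies as st

from irapen_cea import (accumulate_outcomes, build_cycle_transitions,
                        paper_base_case, run_cohort)
from irapen_cea.markov_engine import (CHD_POST, CHD_Y1, DEAD, EVENT_FREE,
                                      STATES, run_arm)
from irapen_cea.parameters import ParameterError


def quiet_params(chd=0.0, stroke=0.0, qx=1e-12, chd_fatal=0.0,
                 stroke_fatal=0.0, post_chd=0.0, post_stroke=0.0,
                 rate=0.0, label="very_high", diabetic=False):
    """Base case with fully controlled transition inputs."""
    p = copy.deepcopy(paper_base_case(label, diabetic))
    p.incidence_by_age = None
    p.annual_incidence_chd = chd
    p.annual_incidence_stroke = stroke
    p.mortality.background_life_table = {
        a: qx for a in range(40, 81)}
    p.mortality.chd_case_fatality_year1 = chd_fatal
    p.mortality.stroke_case_fatality_year1 = stroke_fatal
    p.mortality.post_chd_annual_fatality = post_chd
    p.mortality.post_stroke_annual_fatality = post_stroke
    p.economics.discount_rate_costs = rate
    p.economics.discount_rate_effects = rate
    return p.validate()


class TestCycleTransitions:
    def test_null_intervention_matches_status_quo(self, base_very_high):
        a = build_cycle_transitions(50, base_very_high, 1.0, 1.0)
        b = build_cycle_transitions(50, base_very_high, 1.0, 1.0)
        assert a == b

    def test_rr_scales_event_probability(self):
        p = quiet_params(chd=0.02)
        t = build_cycle_transitions(45, p, 0.75728, 1.0)
        assert t.p_chd_event == pytest.approx(0.0151456)

    def test_infeasible_probability_sum_names_age(self):
        p = quiet_params(chd=0.4, stroke=0.4)
        with pytest.raises(ParameterError, match="age 52"):
            build_cycle_transitions(52, p, 1.4, 1.4)


class TestRunCohort:
    def test_absorbing_event_free_when_nothing_happens(self):
        p = quiet_params()
        trace = run_cohort(p, "status_quo")
        assert np.allclose(trace.occupancy[:, EVENT_FREE], 1.0, atol=1e-7)

    def test_tunnel_mechanics_with_certain_event(self):
        # everyone has a CHD event in cycle 1, none fatal: one cycle in the
        # first-year state, then the chronic state for good
        p = quiet_params(chd=1.0 - 1e-6)
        trace = run_cohort(p, "status_quo")
        assert trace.occupancy[1, CHD_Y1] == pytest.approx(1.0, abs=1e-5)
        assert trace.occupancy[2, CHD_POST] == pytest.approx(1.0, abs=1e-5)
        assert trace.occupancy[2, CHD_Y1] == pytest.approx(0.0, abs=1e-5)

    def test_cycle_zero_all_event_free(self, base_very_high):
        trace = run_cohort(base_very_high, "irapen")
        assert trace.occupancy[0, EVENT_FREE] == 1.0
        assert trace.occupancy[0, 1:].sum() == 0.0

    @given(st.floats(min_value=0.0, max_value=0.1),
           st.floats(min_value=0.0, max_value=0.05),
           st.floats(min_value=1e-6, max_value=0.05),
           st.floats(min_value=0.0, max_value=0.5),
           st.floats(min_value=0.0, max_value=0.3))
    def test_mass_conservation_and_dead_monotone(self, chd, stroke, qx,
                                                 fatal, post):
        p = quiet_params(chd=chd, stroke=stroke, qx=qx, chd_fatal=fatal,
                         stroke_fatal=fatal, post_chd=post, post_stroke=post)
        for arm in ("status_quo", "irapen"):
            trace = run_cohort(p, arm)
            sums = trace.occupancy.sum(axis=1)
            assert np.all(np.abs(sums - 1.0) < 1e-12)
            dead = trace.occupancy[:, DEAD]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_death_cause_accounting_covers_flow_into_dead(self, base_very_high):
        trace = run_cohort(base_very_high, "status_quo")
        inflow = np.diff(trace.occupancy[:, DEAD])
        accounted = trace.death_causes[1:].sum(axis=1)
        assert np.allclose(inflow, accounted, atol=1e-12)


class TestAccumulateOutcomes:
    def test_annuity_closed_form(self):
        # no events, no deaths, r = 3.5%: cost = C * a(40), QALY = LY = a(40)
        p = quiet_params(rate=0.035, label="very_high", diabetic=False)
        C = p.costs.program_annual_cost_per_cohort["very_high"]
        annuity = sum(1.035 ** -t for t in range(1, 41))
        cost, qaly, ly = accumulate_outcomes(run_cohort(p, "irapen"), p)
        assert cost == pytest.approx(C * annuity, rel=1e-6)
        assert qaly == pytest.approx(annuity, rel=1e-9)
        assert ly == pytest.approx(annuity, rel=1e-9)

    def test_undiscounted_horizon(self):
        p = quiet_params(rate=0.0)
        C = p.costs.program_annual_cost_per_cohort["very_high"]
        cost, qaly, ly = accumulate_outcomes(run_cohort(p, "irapen"), p)
        assert cost == pytest.approx(40 * C, rel=1e-6)
        assert qaly == pytest.approx(40, rel=1e-9)
        assert ly == pytest.approx(40, rel=1e-9)

    def test_status_quo_costs_nothing_without_events(self):
        p = quiet_params(rate=0.035)
        cost, _, _ = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        assert cost == 0.0

    def test_prehospital_chd_deaths_are_costless(self):
        # all CHD events fatal, all pre-hospital: status quo accrues nothing
        p = quiet_params(chd=0.05, chd_fatal=1.0)
        p.costs.prehospital_chd_death_fraction = 1.0
        cost, _, _ = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        assert cost == 0.0
        # hospital deaths incur the first-year CHD cost
        p.costs.prehospital_chd_death_fraction = 0.0
        cost2, _, _ = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        assert cost2 > 0

    def test_fatal_stroke_costs_forty_percent_of_first_year(self):
        p = quiet_params(stroke=0.05, stroke_fatal=1.0, rate=0.0)
        cost, _, _ = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        trace = run_cohort(p, "status_quo")
        entrants = trace.death_causes[:, 2].sum()
        assert cost == pytest.approx(
            entrants * 0.40 * p.costs.stroke_cost_year1, rel=1e-9)

    def test_fatal_entrants_accrue_no_qaly_or_ly(self):
        p = quiet_params(chd=1.0 - 1e-6, chd_fatal=1.0, rate=0.0)
        _, qaly, ly = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        assert qaly == pytest.approx(0.0, abs=1e-4)
        assert ly == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("arm", ["status_quo", "irapen"])
    def test_ly_bounds_qaly_and_discounting_shrinks(self, arm, all_base_cases):
        for p in all_base_cases.values():
            trace = run_cohort(p, arm)
            cost_d, qaly_d, ly_d = accumulate_outcomes(trace, p)
            assert qaly_d <= ly_d + 1e-12
            undiscounted = copy.deepcopy(p)
            undiscounted.economics.discount_rate_costs = 0.0
            undiscounted.economics.discount_rate_effects = 0.0
            cost_u, qaly_u, ly_u = accumulate_outcomes(trace, undiscounted)
            assert cost_d <= cost_u + 1e-12
            assert qaly_d <= qaly_u + 1e-12 and ly_d <= ly_u + 1e-12

    def test_arm_mismatch_rejected(self, base_very_high):
        trace = run_cohort(base_very_high, "irapen")
        with pytest.raises(ParameterError):
            accumulate_outcomes(trace, base_very_high, arm="status_quo")


class TestEffectAndExport:
    def test_null_intervention_identity(self):
        # RR = 1 everywhere and free program: both arms identical exactly
        p = quiet_params(chd=0.02, stroke=0.01, qx=0.003, chd_fatal=0.25,
                         stroke_fatal=0.25, post_chd=0.04, post_stroke=0.08,
                         rate=0.035)
        for t in p.treatments:
            t.rr_chd = t.rr_stroke = 1.0
            t.rr_chd_ci = t.rr_stroke_ci = (1.0, 1.0)
        p.lifestyle_counseling.rr_chd = p.lifestyle_counseling.rr_stroke = 1.0
        p.lifestyle_counseling.rr_chd_ci = (1.0, 1.0)
        p.lifestyle_counseling.rr_stroke_ci = (1.0, 1.0)
        p.costs.program_annual_cost_per_cohort = {
            k: 0.0 for k in p.costs.program_annual_cost_per_cohort}
        ref = accumulate_outcomes(run_cohort(p, "status_quo"), p)
        comp = accumulate_outcomes(run_cohort(p, "irapen"), p)
        assert ref == comp

    def test_stronger_treatment_weakly_increases_incremental_qaly(self):
        p = quiet_params(chd=0.02, stroke=0.01, qx=0.003, chd_fatal=0.25,
                         stroke_fatal=0.25, post_chd=0.04, post_stroke=0.08,
                         rate=0.035)
        _, q_base, _ = accumulate_outcomes(run_cohort(p, "irapen"), p)
        stronger = copy.deepcopy(p)
        stronger.treatment("statin").rr_chd = 0.70
        stronger.treatment("statin").rr_chd_ci = (0.6, 0.8)
        _, q_strong, _ = accumulate_outcomes(run_cohort(stronger, "irapen"),
                                             stronger)
        assert q_strong >= q_base

    def test_trace_export_is_deterministic(self, tmp_path, base_very_high):
        paths = []
        for i in (1, 2):
            out = tmp_path / f"trace{i}.csv"
            run_cohort(base_very_high, "irapen").to_csv(out)
            paths.append(out.read_bytes())
        assert paths[0] == paths[1]

    def test_trace_frame_has_all_states(self, base_very_high):
        df = run_cohort(base_very_high, "status_quo").to_frame()
        assert set(STATES) <= set(df.columns)
        assert len(df) == base_very_high.economics.horizon_cycles + 1

    def test_run_arm_wraps_trace_and_outcomes(self, base_very_high):
        res = run_arm(base_very_high, "irapen")
        cost, qaly, ly = accumulate_outcomes(res.trace, base_very_high)
        assert (res.cost, res.qaly, res.ly) == (cost, qaly, ly)
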
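"""Four-state Markov cohort engine with first-year tunnel sub-states.

States (with the post-event tunnel split): event-free, CHD year 1, CHD
subsequent, stroke year 1, stroke subsequent, dead. The cohort enters 100%
event-free at age 40 and runs 40 annual cycles with no half-cycle correction:
all transitions and rewards fall at cycle end, and cycle 0 accrues nothing.

Costing rules: the status-quo arm costs nothing while event-free and the
intervention arm pays the cohort's annual program cost; fatal CHD events are
costless for the pre-hospital fraction (0.60) and incur the first-year CHD
cost otherwise; fatal strokes incur 40% of the first-year stroke cost (half
occur within 28 days); death itself is costless. Fatal entrants contribute no
QALY or LY in their event cycle; everyone alive at cycle end contributes one
(discounted) life year.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervention
from .parameters import ModelParameters, ParameterError, _check

STATES = ("event_free", "chd_year1", "chd_post",
          "stroke_year1", "stroke_post", "dead")
EVENT_FREE, CHD_Y1, CHD_POST, STROKE_Y1, STROKE_POST, DEAD = range(6)
DEATH_CAUSES = ("fatal_chd_prehospital", "fatal_chd_hospital",
                "fatal_stroke_early", "other_death")
ARMS = ("status_quo", "irapen")

_CONSERVATION_TOL = 1e-12


@dataclass
class CycleTransitions:
    """One cycle's transition probabilities at a given attained age."""

    age: int
    p_chd_event: float          # event-free -> CHD event (fatal or not)
    p_stroke_event: float
    p_other_death: float        # event-free -> dead, non-CVD cause
    chd_fatality: float         # fraction of CHD events fatal in year 1
    chd_prehospital: float      # fraction of fatal CHD events pre-hospital
    stroke_fatality: float
    p_death_post_chd: float     # from either CHD state: fatality + background
    p_death_post_stroke: float

    def validate(self) -> None:
        leaving = self.p_chd_event + self.p_stroke_event + self.p_other_death
        if leaving > 1.0:
            raise ParameterError(
                f"outgoing probabilities from event-free sum to {leaving:.4f}"
                f" > 1 at age {self.age}")
        for name in ("p_chd_event", "p_stroke_event", "p_other_death",
                     "chd_fatality", "chd_prehospital", "stroke_fatality",
                     "p_death_post_chd", "p_death_post_stroke"):
            v = getattr(self, name)
            _check(0 <= v <= 1, f"{name} = {v} outside [0, 1] at age {self.age}")


@dataclass
class CohortTrace:
    """Per-cycle state occupancy, cause-of-death accounting and undiscounted
    reward contributions for one arm."""

    arm: str
    occupancy: np.ndarray            # (horizon+1, 6)
    death_causes: np.ndarray         # (horizon+1, 4), per-cycle flows into dead
    cost: np.ndarray                 # (horizon+1,), undiscounted, cycle 0 = 0
    qaly: np.ndarray
    ly: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        for j, cause in enumerate(DEATH_CAUSES):
            df[cause] = self.death_causes[:, j]
        df["cost"] = self.cost
        df["qaly"] = self.qaly
        df["ly"] = self.ly
        df["arm"] = self.arm
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_cycle_transitions(age: int, params: ModelParameters,
                            rr_chd: float, rr_stroke: float
                            ) -> CycleTransitions:
    """Assemble one cycle's transition set: intervention RRs scale the baseline
    event probabilities; post-event states face cause-specific fatality and
    background mortality combined independently."""
    _check(rr_chd >= 0 and rr_stroke >= 0, "relative risks must be >= 0")
    base_chd, base_stroke = params.incidence_at(age)
    qx = params.mortality.qx(age)
    m = params.mortality
    t = CycleTransitions(
        age=int(age),
        p_chd_event=base_chd * rr_chd,
        p_stroke_event=base_stroke * rr_stroke,
        p_other_death=qx,
        chd_fatality=m.chd_case_fatality_year1,
        chd_prehospital=params.costs.prehospital_chd_death_fraction,
        stroke_fatality=m.stroke_case_fatality_year1,
        p_death_post_chd=1 - (1 - m.post_chd_annual_fatality) * (1 - qx),
        p_death_post_stroke=1 - (1 - m.post_stroke_annual_fatality) * (1 - qx))
    t.validate()
    return t


def run_cohort(params: ModelParameters, arm: str) -> CohortTrace:
    """Advance the cohort through the horizon and record occupancy, death
    causes and per-cycle undiscounted cost/QALY/LY for one arm."""
    _check(arm in ARMS, f"unknown arm {arm!r}")
    rr_chd, rr_stroke = intervention.arm_relative_risks(params, arm)
    H = params.economics.horizon_cycles
    age0 = int(params.profile.age_entry)
    c, u = params.costs, params.utilities

    program_cost = (c.program_annual_cost_per_cohort[params.profile.cohort_label]
                    if arm == "irapen" else c.status_quo_eventfree_cost)
    state_cost = np.array([program_cost, c.chd_cost_year1, c.chd_cost_subsequent,
                           c.stroke_cost_year1, c.stroke_cost_subsequent,
                           c.death_cost])
    state_utility = np.array([u.u_healthy, u.u_chd_year1, u.u_chd_subsequent,
                              u.u_stroke_year1, u.u_stroke_subsequent, u.u_dead])

    occ = np.zeros((H + 1, 6))
    causes = np.zeros((H + 1, 4))
    cost = np.zeros(H + 1)
    qaly = np.zeros(H + 1)
    ly = np.zeros(H + 1)
    occ[0, EVENT_FREE] = 1.0

    for cycle in range(1, H + 1):
        age = age0 + cycle - 1
        t = build_cycle_transitions(age, params, rr_chd, rr_stroke)
        prev = occ[cycle - 1]
        nxt = np.zeros(6)

        ef = prev[EVENT_FREE]
        chd_entrants = ef * t.p_chd_event
        stroke_entrants = ef * t.p_stroke_event
        fatal_chd = chd_entrants * t.chd_fatality
        fatal_stroke = stroke_entrants * t.stroke_fatality
        nxt[EVENT_FREE] = ef * (1 - t.p_chd_event - t.p_stroke_event
                                - t.p_other_death)
        nxt[CHD_Y1] = chd_entrants - fatal_chd
        nxt[STROKE_Y1] = stroke_entrants - fatal_stroke

        # tunnel: last cycle's first-year survivors move on or die
        nxt[CHD_POST] = (prev[CHD_Y1] + prev[CHD_POST]) * (1 - t.p_death_post_chd)
        nxt[STROKE_POST] = ((prev[STROKE_Y1] + prev[STROKE_POST])
                            * (1 - t.p_death_post_stroke))

        other_death = (ef * t.p_other_death
                       + (prev[CHD_Y1] + prev[CHD_POST]) * t.p_death_post_chd
                       + (prev[STROKE_Y1] + prev[STROKE_POST])
                       * t.p_death_post_stroke)
        nxt[DEAD] = prev[DEAD] + fatal_chd + fatal_stroke + other_death
        causes[cycle] = (fatal_chd * t.chd_prehospital,
                         fatal_chd * (1 - t.chd_prehospital),
                         fatal_stroke, other_death)

        total = nxt.sum()
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"occupancy lost mass at cycle {cycle}: {total}")
        occ[cycle] = nxt

        fatal_event_cost = (
            fatal_chd * (1 - t.chd_prehospital)
            * c.fatal_chd_hospital_cost_fraction * c.chd_cost_year1
            + fatal_stroke * c.fatal_stroke_cost_fraction * c.stroke_cost_year1)
        cost[cycle] = float(nxt @ state_cost) + fatal_event_cost
        qaly[cycle] = float(nxt @ state_utility)
        ly[cycle] = float(nxt[:DEAD].sum())

    return CohortTrace(arm=arm, occupancy=occ, death_causes=causes,
                       cost=cost, qaly=qaly, ly=ly)


def accumulate_outcomes(trace: CohortTrace, params: ModelParameters,
                        arm: str | None = None
                        ) -> tuple[float, float, float]:
    """Discounted (cost, QALY, LY) totals of a cohort trace."""
    if arm is not None:
        _check(arm == trace.arm, f"trace is for arm {trace.arm!r}, not {arm!r}")
    H = trace.horizon
    t = np.arange(H + 1)
    df_cost = (1 + params.economics.discount_rate_costs) ** -t.astype(float)
    df_eff = (1 + params.economics.discount_rate_effects) ** -t.astype(float)
    return (float(trace.cost @ df_cost),
            float(trace.qaly @ df_eff),
            float(trace.ly @ df_eff))


@dataclass
class ArmOutcomes:
    arm: str
    cost: float
    qaly: float
    ly: float
    trace: CohortTrace | None = field(default=None, repr=False)


def run_arm(params: ModelParameters, arm: str,
            keep_trace: bool = True) -> ArmOutcomes:
    trace = run_cohort(params, arm)
    cost, q, l = accumulate_outcomes(trace, params)
    return ArmOutcomes(arm=arm, cost=cost, qaly=q, ly=l,
                       trace=trace if keep_trace else None)
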
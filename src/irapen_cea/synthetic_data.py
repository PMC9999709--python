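"""Synthetic stand-ins for the model inputs that are not published.

The source analysis drew its background life table, annual event incidences
and post-event fatality rates from national data files that are not printed
anywhere; this module generates statistically plausible versions of them — a
Gompertz background life table, band-consistent 10-year risks split into
CHD/stroke annual probabilities, and flat post-event fatality rates — so the
whole pipeline is testable without any external data. It also provides the
individual-level microsimulation used as an independent oracle for the cohort
engine, and a self-recovery check that re-estimates the generator's own rates
from simulated event histories.

Generated quantities are flagged ``synthetic`` in provenance and are never
asserted against published absolute results.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import intervention, risk_engine
from .markov_engine import (CHD_POST, CHD_Y1, DEAD, EVENT_FREE, STROKE_POST,
                            STROKE_Y1, build_cycle_transitions)
from .parameters import ModelParameters, _check, paper_base_case

#: Gompertz defaults: adult mortality shape giving a remaining life expectancy
#: at age 40 of ~35-37 years, consistent with national life expectancy >75.
DEFAULT_GOMPERTZ_A = 5e-5
DEFAULT_GOMPERTZ_B = 0.095
DEFAULT_AGE_RANGE = (40, 80)

#: flat annual fatality among event survivors (synthetic defaults)
DEFAULT_POST_CHD_FATALITY = 0.04
DEFAULT_POST_STROKE_FATALITY = 0.08

#: first-year case fatality used when simulating event histories
DEFAULT_CHD_CASE_FATALITY = 0.25
DEFAULT_STROKE_CASE_FATALITY = 0.25

#: sampling windows for band-consistent 10-year risks (the very-high band is
#: open above; 0.45 keeps profiles in the realistic chart range)
BAND_WINDOWS = {"low": (0.02, 0.10), "moderate": (0.10, 0.20),
                "high": (0.20, 0.30), "very_high": (0.30, 0.45)}


def make_life_table(a: float = DEFAULT_GOMPERTZ_A,
                    b: float = DEFAULT_GOMPERTZ_B,
                    age_range: tuple[int, int] = DEFAULT_AGE_RANGE
                    ) -> dict[int, float]:
    """Gompertz annual death probabilities qx(age), capped at 0.99.

    qx = 1 - exp(-a * e^(b*age) * (e^b - 1) / b), strictly increasing in age.
    """
    _check(a > 0 and b > 0, "Gompertz parameters must be positive")
    lo, hi = age_range
    return {age: min(1.0 - math.exp(-a * math.exp(b * age)
                                    * (math.exp(b) - 1.0) / b), 0.99)
            for age in range(int(lo), int(hi) + 1)}


def default_life_table() -> dict[int, float]:
    return make_life_table()


@dataclass
class SyntheticScenario:
    """One generated input set: the true rates behind a ModelParameters."""

    seed: int
    band: str
    diabetic: bool
    gompertz_a: float
    gompertz_b: float
    ten_year_risk: float
    chd_stroke_split_ratio: float
    annual_incidence_chd: float
    annual_incidence_stroke: float
    post_chd_fatality: float
    post_stroke_fatality: float


def make_scenario(seed: int, band: str, diabetic: bool = False
                  ) -> tuple[SyntheticScenario, ModelParameters]:
    """Draw a band-consistent scenario and assemble full model parameters.

    The 10-year CVD risk is uniform inside the band's window, annualised under
    constant hazard and split 3:1 into CHD:stroke; published treatment
    effects, costs and utilities are attached unchanged; the life table and
    post-event fatalities are the synthetic defaults. Incidence is held
    constant over the horizon (the generated risk defines the cohort, not a
    profile to re-evaluate each cycle).
    """
    _check(band in BAND_WINDOWS, f"unknown band {band!r}")
    rng = np.random.default_rng([int(seed) % (2 ** 31), 0xC0DE])
    lo, hi = BAND_WINDOWS[band]
    p10 = float(rng.uniform(lo, hi))
    split = 3.0
    annual = risk_engine.annual_probability(p10)
    p_chd = annual * split / (1 + split)
    p_stroke = annual / (1 + split)
    scenario = SyntheticScenario(
        seed=seed, band=band, diabetic=diabetic,
        gompertz_a=DEFAULT_GOMPERTZ_A, gompertz_b=DEFAULT_GOMPERTZ_B,
        ten_year_risk=p10, chd_stroke_split_ratio=split,
        annual_incidence_chd=p_chd, annual_incidence_stroke=p_stroke,
        post_chd_fatality=DEFAULT_POST_CHD_FATALITY,
        post_stroke_fatality=DEFAULT_POST_STROKE_FATALITY)

    params = paper_base_case(band, diabetic)
    params.incidence_by_age = None          # constant incidence for scenarios
    params.annual_incidence_chd = p_chd
    params.annual_incidence_stroke = p_stroke
    params.mortality.background_life_table = make_life_table(
        scenario.gompertz_a, scenario.gompertz_b)
    params.mortality.post_chd_annual_fatality = scenario.post_chd_fatality
    params.mortality.post_stroke_annual_fatality = scenario.post_stroke_fatality
    params.provenance["annual_incidence"] = "synthetic"
    params.validate()
    assert risk_engine.classify_who_ish(p10) == band
    return scenario, params


# --------------------------------------------------------------------------
# individual-level microsimulation (independent oracle for the cohort engine)
# --------------------------------------------------------------------------

@dataclass
class MicrosimResult:
    n: int
    cost_mean: float
    cost_se: float
    qaly_mean: float
    qaly_se: float
    ly_mean: float
    ly_se: float


def microsimulate(params: ModelParameters, arm: str, n: int,
                  seed: int = 0) -> MicrosimResult:
    """Simulate ``n`` individuals through the same transition and reward rules
    as the cohort engine and return Monte-Carlo means with standard errors.

    This is a path-level re-implementation (states sampled per person-year),
    independent of the cohort engine's expectation arithmetic.
    """
    _check(n >= 1, "n must be >= 1")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    H = params.economics.horizon_cycles
    age0 = int(params.profile.age_entry)
    c, u = params.costs, params.utilities
    rr_chd, rr_stroke = intervention.arm_relative_risks(params, arm)
    program_cost = (c.program_annual_cost_per_cohort[params.profile.cohort_label]
                    if arm == "irapen" else c.status_quo_eventfree_cost)

    state = np.full(n, EVENT_FREE, dtype=np.int8)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    state_cost = np.array([program_cost, c.chd_cost_year1, c.chd_cost_subsequent,
                           c.stroke_cost_year1, c.stroke_cost_subsequent, 0.0])
    state_u = np.array([u.u_healthy, u.u_chd_year1, u.u_chd_subsequent,
                        u.u_stroke_year1, u.u_stroke_subsequent, 0.0])

    for cycle in range(1, H + 1):
        t = build_cycle_transitions(age0 + cycle - 1, params, rr_chd, rr_stroke)
        df_c = (1 + params.economics.discount_rate_costs) ** -cycle
        df_e = (1 + params.economics.discount_rate_effects) ** -cycle
        draw = rng.random(n)
        new = state.copy()

        ef = state == EVENT_FREE
        p1, p2 = t.p_chd_event, t.p_stroke_event
        p3 = p1 + p2 + t.p_other_death
        chd_ev = ef & (draw < p1)
        stroke_ev = ef & (draw >= p1) & (draw < p1 + p2)
        other = ef & (draw >= p1 + p2) & (draw < p3)
        fatal_draw = rng.random(n)
        chd_fatal = chd_ev & (fatal_draw < t.chd_fatality)
        stroke_fatal = stroke_ev & (fatal_draw < t.stroke_fatality)
        prehosp = rng.random(n) < t.chd_prehospital

        new[chd_ev] = CHD_Y1
        new[stroke_ev] = STROKE_Y1
        new[chd_fatal | stroke_fatal | other] = DEAD
        cost[chd_fatal & ~prehosp] += (df_c * c.fatal_chd_hospital_cost_fraction
                                       * c.chd_cost_year1)
        cost[stroke_fatal] += df_c * c.fatal_stroke_cost_fraction \
            * c.stroke_cost_year1

        in_chd = (state == CHD_Y1) | (state == CHD_POST)
        in_stroke = (state == STROKE_Y1) | (state == STROKE_POST)
        new[in_chd] = np.where(draw[in_chd] < t.p_death_post_chd,
                               DEAD, CHD_POST)
        new[in_stroke] = np.where(draw[in_stroke] < t.p_death_post_stroke,
                                  DEAD, STROKE_POST)

        alive = new != DEAD
        cost[alive] += df_c * state_cost[new[alive]]
        qaly[alive] += df_e * state_u[new[alive]]
        ly[alive] += df_e
        state = new

    sq = math.sqrt(n)
    return MicrosimResult(n=n,
                          cost_mean=float(cost.mean()),
                          cost_se=float(cost.std(ddof=1) / sq),
                          qaly_mean=float(qaly.mean()),
                          qaly_se=float(qaly.std(ddof=1) / sq),
                          ly_mean=float(ly.mean()),
                          ly_se=float(ly.std(ddof=1) / sq))


# --------------------------------------------------------------------------
# self-recovery of the generator's own rates
# --------------------------------------------------------------------------

def parameter_recovery_check(scenario: SyntheticScenario, n_sim: int,
                             seed: int = 0) -> dict:
    """Simulate first-event histories from the scenario's true rates and
    re-estimate the annual incidences and first-year case fatalities.

    Returns the estimates, their 3-binomial-SE windows around the truth, and
    whether every estimate falls inside its window.
    """
    _check(n_sim >= 1000, "n_sim must be >= 1000")
    rng = np.random.default_rng([int(seed) % (2 ** 31), scenario.seed])
    p_chd, p_stroke = (scenario.annual_incidence_chd,
                       scenario.annual_incidence_stroke)
    draw = rng.random(n_sim)
    chd = draw < p_chd
    stroke = (draw >= p_chd) & (draw < p_chd + p_stroke)
    fatal_chd = rng.random(n_sim) < DEFAULT_CHD_CASE_FATALITY
    fatal_stroke = rng.random(n_sim) < DEFAULT_STROKE_CASE_FATALITY

    report: dict[str, dict] = {}
    ok = True
    checks = [
        ("annual_incidence_chd", p_chd, chd.mean(), n_sim),
        ("annual_incidence_stroke", p_stroke, stroke.mean(), n_sim),
    ]
    if chd.sum() > 0:
        checks.append(("chd_case_fatality_year1", DEFAULT_CHD_CASE_FATALITY,
                       fatal_chd[chd].mean(), int(chd.sum())))
    if stroke.sum() > 0:
        checks.append(("stroke_case_fatality_year1",
                       DEFAULT_STROKE_CASE_FATALITY,
                       fatal_stroke[stroke].mean(), int(stroke.sum())))
    for name, truth, est, denom in checks:
        se = math.sqrt(max(truth * (1 - truth), 1e-300) / denom)
        within = abs(est - truth) <= 3 * se
        ok = ok and within
        report[name] = {"truth": truth, "estimate": float(est),
                        "n": denom, "binomial_se": se,
                        "relative_error": (float(est / truth - 1)
                                           if truth > 0 else 0.0),
                        "within_3_se": bool(within)}
    report["all_within_3_se"] = ok
    return report
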
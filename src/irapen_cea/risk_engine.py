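"""Cardiovascular risk computation and WHO/ISH band classification.

The 10-year CVD risk of an index profile is computed from Framingham-type
survival equations (packaged coefficient file; alternative published sets can
be swapped in via config), converted to an annual first-event probability
under a constant-hazard assumption, and split into CHD and stroke components.
The 10-year risk — never the annualised one — is what the WHO/ISH bands
classify: <10% low, 10-19% moderate, 20-29% high, >=30% very high.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import yaml

from .parameters import RiskProfile, _check, _data_text

#: ages for which the packaged Framingham equations are calibrated
EQUATION_AGE_RANGE = (30.0, 74.0)

RISK_BANDS = (("low", 0.0, 0.10), ("moderate", 0.10, 0.20),
              ("high", 0.20, 0.30), ("very_high", 0.30, 1.0 + 1e-12))


@dataclass
class RiskEquationCoefficients:
    """One sex's risk-equation coefficients plus the calibration constants."""

    outcome: str                # chd | stroke | cvd_combined
    sex: str
    coefficients: Mapping[str, float]
    baseline_survival: float
    mean_lp: float
    functional_form: str = "cox_survival"

    def validate(self) -> None:
        _check(0 < self.baseline_survival <= 1,
               "baseline_survival must be in (0, 1]")
        _check(len(self.coefficients) > 0, "coefficient map is empty")
        _check(self.functional_form in ("cox_survival", "logistic"),
               f"unknown functional form {self.functional_form!r}")


@dataclass
class RiskEquationSet:
    """Per-sex coefficient sets plus the CHD:stroke split of combined CVD risk."""

    by_sex: dict[str, RiskEquationCoefficients]
    chd_stroke_split_ratio: float = 3.0
    version: str = "unversioned"

    def for_sex(self, sex: str) -> RiskEquationCoefficients:
        return self.by_sex[sex]

    def chd_share(self) -> float:
        r = self.chd_stroke_split_ratio
        return r / (1.0 + r)


def load_equations(source: str | None = None) -> RiskEquationSet:
    """Load a coefficient file; default is the packaged 2008 general-CVD set."""
    text = _data_text("framingham_general_cvd_2008.yaml") if source is None \
        else open(source).read()
    raw = yaml.safe_load(text)
    by_sex = {}
    for sex, c in raw["coefficients"].items():
        c = dict(c)
        s0 = c.pop("baseline_survival")
        mean_lp = c.pop("mean_lp")
        eq = RiskEquationCoefficients(
            outcome=raw.get("outcome", "cvd_combined"), sex=sex,
            coefficients=c, baseline_survival=s0, mean_lp=mean_lp,
            functional_form=raw.get("functional_form", "cox_survival"))
        eq.validate()
        by_sex[sex] = eq
    return RiskEquationSet(by_sex=by_sex,
                           chd_stroke_split_ratio=float(
                               raw.get("chd_stroke_split_ratio", 3.0)),
                           version=str(raw.get("version", "unversioned")))


_DEFAULT_EQUATIONS: RiskEquationSet | None = None


def default_equations() -> RiskEquationSet:
    global _DEFAULT_EQUATIONS
    if _DEFAULT_EQUATIONS is None:
        _DEFAULT_EQUATIONS = load_equations()
    return _DEFAULT_EQUATIONS


def ten_year_risk(profile: RiskProfile,
                  coeffs: RiskEquationCoefficients,
                  age: float | None = None) -> float:
    """10-year CVD risk of a profile under one sex-specific equation.

    ``age`` overrides the profile's entry age (used when recomputing risk each
    model cycle). Ages outside the equations' calibration range are clamped
    with a warning.
    """
    a = profile.age_entry if age is None else age
    lo, hi = EQUATION_AGE_RANGE
    if not (lo <= a <= hi):
        warnings.warn(f"age {a} outside equation validity range {lo}-{hi}; "
                      "clamped", stacklevel=2)
        a = min(max(a, lo), hi)
    c = coeffs.coefficients
    terms = {
        "ln_age": math.log(a),
        "ln_total_cholesterol": math.log(profile.total_cholesterol),
        "ln_hdl": math.log(profile.hdl),
        "ln_sbp_untreated": math.log(profile.sbp),
        "ln_sbp_treated": 0.0,  # profiles enter untreated
        "smoker": 1.0 if profile.smoker else 0.0,
        "diabetic": 1.0 if profile.diabetic else 0.0,
    }
    lp = 0.0
    for name, beta in c.items():
        if name not in terms:
            raise KeyError(f"no profile field for coefficient {name!r}")
        lp += beta * terms[name]
    if coeffs.functional_form == "logistic":
        risk = 1.0 / (1.0 + math.exp(-(lp - coeffs.mean_lp)))
    else:
        risk = 1.0 - coeffs.baseline_survival ** math.exp(lp - coeffs.mean_lp)
    return min(max(risk, 1e-12), 1 - 1e-12)


def annual_probability(p10: float) -> float:
    """Annual event probability from a 10-year one (constant hazard)."""
    _check(0 <= p10 < 1, "10-year risk must be in [0, 1)")
    return 1.0 - (1.0 - p10) ** 0.1


def classify_who_ish(p10: float) -> str:
    """WHO/ISH risk band of a 10-year CVD risk (half-open bands [a, b))."""
    _check(0 <= p10 <= 1, "10-year risk must be in [0, 1]")
    for label, lo, hi in RISK_BANDS:
        if lo <= p10 < hi:
            return label
    return "very_high"


def net_background_mortality(age: int, life_table: Mapping[int, float],
                             cvd_death_rates: Mapping[int, float] | float = 0.0
                             ) -> float:
    """All-cause annual death probability net of CHD/stroke deaths at an age."""
    _check(int(age) in life_table,
           f"age {age} not covered by the life table")
    qx = life_table[int(age)]
    cvd = (cvd_death_rates if isinstance(cvd_death_rates, (int, float))
           else cvd_death_rates.get(int(age), 0.0))
    _check(cvd <= qx,
           f"CVD death rate {cvd} exceeds all-cause rate {qx} at age {age}")
    return max(qx - cvd, 0.0)


def split_annual_incidence(p10_cvd: float,
                           equations: RiskEquationSet | None = None
                           ) -> tuple[float, float]:
    """(CHD, stroke) annual probabilities from a combined 10-year CVD risk."""
    eq = equations or default_equations()
    annual = annual_probability(p10_cvd)
    share = eq.chd_share()
    return annual * share, annual * (1.0 - share)


def incidence_schedule(profile: RiskProfile, ages: list[int],
                       equations: RiskEquationSet | None = None
                       ) -> dict[int, tuple[float, float]]:
    """Age-indexed (CHD, stroke) annual probabilities, risk recomputed per age."""
    eq = equations or default_equations()
    coeffs = eq.for_sex(profile.sex)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamping past 74 is expected here
        for age in ages:
            p10 = ten_year_risk(profile, coeffs, age=age)
            out[int(age)] = split_annual_incidence(p10, eq)
    return out
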
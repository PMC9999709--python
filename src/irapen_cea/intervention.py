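"""Treatment packages and effective relative risks.

Each risk band gets a fixed medication package (plus lifestyle counseling for
every treated cohort; plus oral antidiabetics for diabetic cohorts). Component
relative risks are combined with an overlap correction that damps the joint
risk reduction when multiple interventions act at once:

    RR_combined = 1 - (1 - RR1 x RR2 x ... x RRn) x 0.8

applied only when more than one component is present. Partial adherence
attenuates the combined risk reduction linearly:
RR_effective = 1 - adherence x (1 - RR_combined).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .parameters import (COHORT_LABELS, ModelParameters, TreatmentEffect,
                         _check)

OVERLAP_FACTOR = 0.8

#: antihypertensive escalation: one agent (moderate), two (high), three (very high)
_PACKAGE_COMPONENTS = {
    "low": [],
    "moderate": ["statin", "ace_inhibitor"],
    "high": ["statin", "ace_inhibitor", "thiazide"],
    "very_high": ["statin", "ace_inhibitor", "thiazide", "beta_blocker"],
}
_DIABETES_COMPONENTS = {
    "low": ["metformin"],
    "moderate": ["metformin"],
    "high": ["metformin", "sulfonylurea"],
    "very_high": ["metformin", "sulfonylurea"],
}


@dataclass
class TreatmentPackage:
    """The set of intervention components one cohort receives."""

    cohort_label: str
    diabetic: bool
    components: list[str] = field(default_factory=list)
    overlap_factor: float = OVERLAP_FACTOR

    def validate(self) -> None:
        _check(self.cohort_label in COHORT_LABELS,
               f"unknown cohort label {self.cohort_label!r}")
        _check(0 < self.overlap_factor <= 1, "overlap_factor must be in (0, 1]")
        if self.cohort_label != "low" or self.diabetic:
            _check(len(self.components) > 0,
                   "only the non-diabetic low-risk cohort may be untreated")


def combine_relative_risks(rrs: list[float],
                           overlap_factor: float = OVERLAP_FACTOR) -> float:
    """Combined RR of several components under the overlap correction.

    A single component (or none) is returned unchanged — the correction only
    applies when multiple interventions are involved.
    """
    _check(0 < overlap_factor <= 1, "overlap_factor must be in (0, 1]")
    for rr in rrs:
        _check(rr > 0, f"relative risks must be positive, got {rr}")
    if not rrs:
        return 1.0
    if len(rrs) == 1:
        return rrs[0]
    return 1.0 - (1.0 - math.prod(rrs)) * overlap_factor


def apply_adherence(rr: float, adherence: float) -> float:
    """Linearly attenuate a risk reduction by the adherent fraction."""
    _check(rr > 0, "relative risk must be positive")
    _check(0 <= adherence <= 1, "adherence must be in [0, 1]")
    return 1.0 - adherence * (1.0 - rr)


def build_package(cohort_label: str, diabetic: bool) -> TreatmentPackage:
    """The medication/counseling package a cohort receives.

    The non-diabetic low-risk cohort is screened without intervention (empty
    package); every treated package includes lifestyle counseling.
    """
    _check(cohort_label in COHORT_LABELS,
           f"unknown cohort label {cohort_label!r}")
    components = list(_PACKAGE_COMPONENTS[cohort_label])
    if diabetic:
        components += _DIABETES_COMPONENTS[cohort_label]
    if components:
        components.append("lifestyle")
    pkg = TreatmentPackage(cohort_label=cohort_label, diabetic=diabetic,
                           components=components)
    pkg.validate()
    return pkg


def effective_rr(package: TreatmentPackage, outcome: str, adherence: float,
                 params: ModelParameters | None = None,
                 effects: dict[str, TreatmentEffect] | None = None) -> float:
    """Per-outcome effective RR of a package: combine, then apply adherence.

    Component RRs are looked up in ``params`` (or an explicit ``effects`` map);
    an empty package has no effect (RR = 1).
    """
    if not package.components:
        return 1.0

    def rr_of(name: str) -> float:
        if effects is not None:
            return effects[name].rr(outcome)
        _check(params is not None,
               "effective_rr needs params or an effects map")
        return params.treatment(name).rr(outcome)

    combined = combine_relative_risks([rr_of(c) for c in package.components],
                                      package.overlap_factor)
    return apply_adherence(combined, adherence)


def arm_relative_risks(params: ModelParameters,
                       arm: str) -> tuple[float, float]:
    """(RR_chd, RR_stroke) for one model arm; the status quo is untreated."""
    _check(arm in ("status_quo", "irapen"), f"unknown arm {arm!r}")
    if arm == "status_quo":
        return 1.0, 1.0
    pkg = build_package(params.profile.cohort_label, params.profile.diabetic)
    adh = params.economics.adherence
    return (effective_rr(pkg, "chd", adh, params=params),
            effective_rr(pkg, "stroke", adh, params=params))
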
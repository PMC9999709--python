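"""Incremental cost-effectiveness analysis of the intervention vs status quo.

Produces the incremental cost/QALY/LY, the ICER (reported to whole dollars,
kept at full precision internally), a dominance status, and the net monetary
benefit at the willingness-to-pay threshold (1 x GDP per capita, $4,091).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import markov_engine
from .markov_engine import ArmOutcomes
from .parameters import ModelParameters, _check

#: |delta QALY| below this is treated as zero effect (undefined ICER)
ZERO_EFFECT_TOL = 1e-9

STATUS_ICER = "icer"
STATUS_COST_SAVING = "dominant_cost_saving"
STATUS_DOMINATED = "dominated"
STATUS_UNDEFINED = "undefined_zero_effect"


@dataclass
class CEResult:
    """Pairwise incremental result (intervention vs status quo)."""

    reference: ArmOutcomes
    comparator: ArmOutcomes
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None               # full precision; None when undefined
    status: str
    threshold: float
    nmb: float
    warnings: list[str] = field(default_factory=list)

    @property
    def icer_reported(self) -> int | str:
        """ICER rounded to whole dollars, as the published tables report it."""
        return "Undefined" if self.icer is None else int(round(self.icer))

    def to_dict(self) -> dict:
        return {
            "status_quo": {"cost": self.reference.cost,
                           "qaly": self.reference.qaly,
                           "ly": self.reference.ly},
            "irapen": {"cost": self.comparator.cost,
                       "qaly": self.comparator.qaly, "ly": self.comparator.ly},
            "incremental": {"cost": self.delta_cost, "qaly": self.delta_qaly,
                            "ly": self.delta_ly},
            "icer": self.icer, "icer_reported": self.icer_reported,
            "status": self.status, "threshold": self.threshold,
            "nmb": self.nmb, "warnings": list(self.warnings),
        }

    def to_frame(self) -> pd.DataFrame:
        """Row layout mirroring the published result tables."""
        rows = [
            ("Status quo", self.reference.cost, self.reference.qaly,
             self.reference.ly, ""),
            ("IraPEN", self.comparator.cost, self.comparator.qaly,
             self.comparator.ly, str(self.icer_reported)),
            ("Incremental", self.delta_cost, self.delta_qaly, self.delta_ly, ""),
        ]
        return pd.DataFrame(rows, columns=["arm", "cost", "qaly", "ly", "icer"])

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def incremental(ref: ArmOutcomes, comp: ArmOutcomes,
                threshold: float) -> CEResult:
    """Incremental analysis of a comparator arm against a reference arm."""
    for o in (ref, comp):
        _check(all(map(lambda v: v == v and abs(v) != float("inf"),
                       (o.cost, o.qaly, o.ly))), "arm outcomes must be finite")
    dc = comp.cost - ref.cost
    dq = comp.qaly - ref.qaly
    dl = comp.ly - ref.ly
    warns: list[str] = []
    if abs(dq) < ZERO_EFFECT_TOL:
        icer, status = None, STATUS_UNDEFINED
    else:
        icer = dc / dq
        if dq > 0:
            status = STATUS_COST_SAVING if dc < 0 else STATUS_ICER
        elif dc > 0:
            status = STATUS_DOMINATED
        else:  # southwest quadrant: cheaper but less effective
            status = STATUS_ICER
            warns.append("dominated-direction: comparator is cheaper but less "
                         "effective; interpret the ICER with care")
            warnings.warn(warns[-1], stacklevel=2)
    nmb = threshold * dq - dc
    return CEResult(reference=ref, comparator=comp, delta_cost=dc,
                    delta_qaly=dq, delta_ly=dl, icer=icer, status=status,
                    threshold=threshold, nmb=nmb, warnings=warns)


def classify_against_threshold(icer_or_status: float | str | None,
                               threshold: float) -> str:
    """Verdict against a willingness-to-pay threshold."""
    _check(threshold > 0, "threshold must be positive")
    if icer_or_status in (None, STATUS_UNDEFINED, "Undefined"):
        return "undefined"
    if icer_or_status == STATUS_COST_SAVING:
        return "cost_saving"
    if icer_or_status == STATUS_DOMINATED:
        return "not_cost_effective"
    icer = float(icer_or_status)
    if icer < 0:
        return "cost_saving"
    return "cost_effective" if icer <= threshold else "not_cost_effective"


def evaluate(params: ModelParameters, keep_traces: bool = False) -> CEResult:
    """Run both model arms on one parameter set and compare them."""
    ref = markov_engine.run_arm(params, "status_quo", keep_trace=keep_traces)
    comp = markov_engine.run_arm(params, "irapen", keep_trace=keep_traces)
    return incremental(ref, comp, params.economics.wtp_threshold)
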
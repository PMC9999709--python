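"""One-way deterministic sensitivity analysis (tornado ordering).

Each uncertain scalar is pushed to its low and high bound — the 95% CI for
relative risks, mean +/- 1.96 SE (truncated at zero) for costs and utilities,
and 50%-100% for adherence — with everything else at base, and the resulting
ICER pair's spread orders the tornado. Spreads use full-precision ICERs;
runs whose ICER is undefined are carried as flagged entries and excluded
from the ordering.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import cea
from .parameters import ModelParameters, _check, get_by_path, set_by_path

Z95 = 1.959964


@dataclass
class DsaSpec:
    """One parameter's perturbation range."""

    path: str
    low: float
    high: float
    provenance: str = "manual"     # ci95 | adherence_range | manual

    def validate(self, params: ModelParameters) -> None:
        base = get_by_path(params, self.path)
        _check(self.low <= base <= self.high,
               f"{self.path}: base {base} outside [{self.low}, {self.high}]")


@dataclass
class TornadoEntry:
    path: str
    base_icer: float | None
    icer_at_low: float | None
    icer_at_high: float | None

    @property
    def spread(self) -> float | None:
        if self.icer_at_low is None or self.icer_at_high is None:
            return None
        return abs(self.icer_at_high - self.icer_at_low)


def default_specs(params: ModelParameters) -> list[DsaSpec]:
    """The default one-way set: every component RR (CI bounds), every state
    cost and utility (+/- 1.96 SE), the cohort program cost (SE = 0.1 x mean),
    and adherence 50%-100%."""
    specs: list[DsaSpec] = []
    for t in [*params.treatments, params.lifestyle_counseling]:
        for outcome in ("chd", "stroke"):
            lo, hi = t.ci(outcome)
            specs.append(DsaSpec(f"treatments/{t.name}/rr_{outcome}",
                                 lo, hi, "ci95"))
    for item in ("chd_cost_year1", "chd_cost_subsequent",
                 "stroke_cost_year1", "stroke_cost_subsequent"):
        mean = get_by_path(params, f"costs/{item}")
        se = params.costs.se_of(item)
        specs.append(DsaSpec(f"costs/{item}", max(mean - Z95 * se, 0.0),
                             mean + Z95 * se, "ci95"))
    label = params.profile.cohort_label
    mean = params.costs.program_annual_cost_per_cohort[label]
    se = 0.1 * mean
    specs.append(DsaSpec(f"costs/program_annual_cost_per_cohort/{label}",
                         max(mean - Z95 * se, 0.0), mean + Z95 * se, "ci95"))
    for item in ("u_chd_year1", "u_chd_subsequent",
                 "u_stroke_year1", "u_stroke_subsequent"):
        mean = get_by_path(params, f"utilities/{item}")
        se = getattr(params.utilities, item + "_se")
        specs.append(DsaSpec(f"utilities/{item}", max(mean - Z95 * se, 0.0),
                             min(mean + Z95 * se, 1.0), "ci95"))
    specs.append(DsaSpec("economics/adherence", 0.5, 1.0, "adherence_range"))
    return specs


def run_one_way(params: ModelParameters,
                specs: list[DsaSpec]) -> list[TornadoEntry]:
    """Two model runs per spec (low, high), one parameter at a time; entries
    sorted by ICER spread descending, undefined-ICER entries last."""
    base_icer = cea.evaluate(params).icer
    entries: list[TornadoEntry] = []
    for spec in specs:
        spec.validate(params)
        work = copy.deepcopy(params)
        icers = []
        for bound in (spec.low, spec.high):
            set_by_path(work, spec.path, bound)
            work.validate()
            icers.append(cea.evaluate(work).icer)
        set_by_path(work, spec.path, get_by_path(params, spec.path))
        entries.append(TornadoEntry(path=spec.path, base_icer=base_icer,
                                    icer_at_low=icers[0],
                                    icer_at_high=icers[1]))
    defined = [e for e in entries if e.spread is not None]
    flagged = [e for e in entries if e.spread is None]
    defined.sort(key=lambda e: e.spread, reverse=True)
    return defined + flagged


def to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": e.path, "icer_at_low": e.icer_at_low,
          "icer_at_high": e.icer_at_high, "spread": e.spread,
          "base_icer": e.base_icer} for e in entries],
        columns=["parameter", "icer_at_low", "icer_at_high", "spread",
                 "base_icer"])


def save_csv(entries: list[TornadoEntry], path: str | Path) -> None:
    to_frame(entries).to_csv(path, index=False)
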
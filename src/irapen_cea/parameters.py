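"""Domain types and parameter handling for the IraPEN cost-effectiveness model.

Everything the model consumes lives in a single validated :class:`ModelParameters`
object: the index-cohort risk profile, the medication relative risks, program and
disease-state costs, state utilities, mortality inputs and economic settings.
The published base case is packaged as data and can be materialised with
:func:`paper_base_case`; arbitrary parameter sets load from YAML/JSON configs.

Every top-level item carries a provenance tag (``printed`` — transcribed from the
published tables; ``derived`` — arithmetic on printed values or a documented
package assumption; ``synthetic`` — generated stand-in for unpublished inputs)
so tests can restrict assertions to printed values.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

logger = logging.getLogger("irapen_cea")

COHORT_LABELS = ("low", "moderate", "high", "very_high")
CURRENCY = "USD"


class ParameterError(ValueError):
    """A parameter file failed to parse or violated a model invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


# --------------------------------------------------------------------------
# packaged data
# --------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("irapen_cea.data").joinpath(name).read_text()


def printed_tables() -> dict:
    """The published parameter tables and base-case results, as packaged."""
    return yaml.safe_load(_data_text("printed_tables.yaml"))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class RiskProfile:
    """One index cohort's risk-factor profile (model entry at age 40).

    Bands are the published intervals; ``sbp`` and ``total_cholesterol`` are the
    representative point values inside those bands used by the risk equations.
    Open-ended bands are encoded with ``None`` on the open side.
    """

    cohort_label: str
    sex: str
    sbp_band: tuple[float | None, float | None]
    sbp: float
    total_cholesterol_band: tuple[float | None, float | None]
    total_cholesterol: float
    hdl: float
    smoker: bool
    diabetic: bool
    age_entry: float = 40.0

    def validate(self) -> None:
        _check(self.cohort_label in COHORT_LABELS,
               f"unknown cohort_label {self.cohort_label!r}")
        _check(self.sex in ("male", "female"), f"unknown sex {self.sex!r}")
        _check(self.age_entry >= 30, "age_entry must be >= 30")
        for name, band, value in (("sbp", self.sbp_band, self.sbp),
                                  ("total_cholesterol",
                                   self.total_cholesterol_band,
                                   self.total_cholesterol)):
            lo, hi = band
            _check(lo is None or hi is None or lo < hi,
                   f"{name}_band is empty: {band}")
            _check((lo is None or value >= lo) and (hi is None or value <= hi),
                   f"{name} representative value {value} outside band {band}")
        _check(self.hdl > 0, "hdl must be positive")


@dataclass
class TreatmentEffect:
    """Relative risk of CHD and stroke for one intervention component."""

    name: str
    rr_chd: float
    rr_chd_ci: tuple[float, float]
    rr_stroke: float
    rr_stroke_ci: tuple[float, float]

    def validate(self) -> None:
        for outcome, rr, ci in (("chd", self.rr_chd, self.rr_chd_ci),
                                ("stroke", self.rr_stroke, self.rr_stroke_ci)):
            lo, hi = ci
            _check(rr > 0 and lo > 0 and hi > 0,
                   f"{self.name}/{outcome}: relative risks must be positive")
            _check(lo <= rr <= hi,
                   f"{self.name}/{outcome}: RR {rr} outside its CI ({lo}, {hi})")

    def rr(self, outcome: str) -> float:
        _check(outcome in ("chd", "stroke"), f"unknown outcome {outcome!r}")
        return self.rr_chd if outcome == "chd" else self.rr_stroke

    def ci(self, outcome: str) -> tuple[float, float]:
        return self.rr_chd_ci if outcome == "chd" else self.rr_stroke_ci


@dataclass
class CostParameters:
    """Program and disease-state costs (USD/year) plus fatal-event cost rules.

    ``program_annual_cost_per_cohort`` maps cohort label to the annual
    screening+monitoring+medication cost of the intervention arm. Status-quo
    individuals cost nothing while event-free, and dying costs nothing; a fatal
    CHD event is costless for the pre-hospital fraction (0.60) while fatal
    strokes incur 40% of the first-year stroke cost.
    """

    program_annual_cost_per_cohort: dict[str, float]
    chd_cost_year1: float = 519.0
    chd_cost_year1_se: float = 51.0
    chd_cost_subsequent: float = 173.0
    chd_cost_subsequent_se: float = 17.0
    stroke_cost_year1: float = 5691.0
    stroke_cost_year1_se: float = 569.0
    stroke_cost_subsequent: float = 1422.0
    stroke_cost_subsequent_se: float = 142.0
    prehospital_chd_death_fraction: float = 0.60
    fatal_stroke_cost_fraction: float = 0.40
    fatal_chd_hospital_cost_fraction: float = 1.0
    status_quo_eventfree_cost: float = 0.0
    death_cost: float = 0.0

    SE_FALLBACK_FACTOR = 0.1  # SE = 0.1 x mean for items without a printed SE

    def validate(self) -> None:
        for label, c in self.program_annual_cost_per_cohort.items():
            _check(label in COHORT_LABELS, f"unknown cohort label {label!r}")
            _check(c >= 0, f"program cost for {label} must be >= 0")
        for name in ("chd_cost_year1", "chd_cost_subsequent",
                     "stroke_cost_year1", "stroke_cost_subsequent",
                     "status_quo_eventfree_cost", "death_cost"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("prehospital_chd_death_fraction",
                     "fatal_stroke_cost_fraction",
                     "fatal_chd_hospital_cost_fraction"):
            v = getattr(self, name)
            _check(0 <= v <= 1, f"{name} must be in [0, 1]")
        _check(self.chd_cost_year1 >= self.chd_cost_subsequent,
               "chd_cost_year1 must be >= chd_cost_subsequent")
        _check(self.stroke_cost_year1 >= self.stroke_cost_subsequent,
               "stroke_cost_year1 must be >= stroke_cost_subsequent")

    def se_of(self, name: str) -> float:
        """SE of a cost item, falling back to 0.1 x mean when none is stored."""
        se = getattr(self, name + "_se", None)
        return se if se is not None else self.SE_FALLBACK_FACTOR * getattr(self, name)


@dataclass
class UtilityParameters:
    """Health-state utility weights: 1 while event-free, 0 when dead, and
    first-year vs chronic weights for CHD/stroke survivors."""

    u_healthy: float = 1.0
    u_dead: float = 0.0
    u_chd_year1: float = 0.67
    u_chd_year1_se: float = 0.024
    u_chd_subsequent: float = 0.82
    u_chd_subsequent_se: float = 0.012
    u_stroke_year1: float = 0.33
    u_stroke_year1_se: float = 0.033
    u_stroke_subsequent: float = 0.52
    u_stroke_subsequent_se: float = 0.027

    def validate(self) -> None:
        for name in ("u_healthy", "u_dead", "u_chd_year1", "u_chd_subsequent",
                     "u_stroke_year1", "u_stroke_subsequent"):
            v = getattr(self, name)
            _check(0 <= v <= 1, f"{name} must be in [0, 1]")
        _check(self.u_dead == 0.0, "u_dead must be exactly 0")
        _check(self.u_healthy == 1.0, "u_healthy must be exactly 1")
        _check(self.u_chd_year1 <= self.u_chd_subsequent,
               "u_chd_year1 must be <= u_chd_subsequent (acute worse than chronic)")
        _check(self.u_stroke_year1 <= self.u_stroke_subsequent,
               "u_stroke_year1 must be <= u_stroke_subsequent")


@dataclass
class MortalityParameters:
    """First-year case fatality, post-event annual fatality, and the background
    life table (annual all-cause death probability net of CHD/stroke)."""

    background_life_table: dict[int, float]
    chd_case_fatality_year1: float = 0.25
    stroke_case_fatality_year1: float = 0.25
    post_chd_annual_fatality: float = 0.04
    post_stroke_annual_fatality: float = 0.08

    def validate(self) -> None:
        for name in ("chd_case_fatality_year1", "stroke_case_fatality_year1",
                     "post_chd_annual_fatality", "post_stroke_annual_fatality"):
            v = getattr(self, name)
            _check(0 <= v <= 1, f"{name} must be in [0, 1]")
        _check(len(self.background_life_table) > 0, "life table is empty")
        for age, qx in self.background_life_table.items():
            _check(0 < qx <= 1,
                   f"life-table qx at age {age} must be in (0, 1], got {qx}")

    def qx(self, age: int) -> float:
        try:
            return self.background_life_table[int(age)]
        except KeyError:
            raise ParameterError(
                f"age {age} not covered by the background life table "
                f"(ages {min(self.background_life_table)}-"
                f"{max(self.background_life_table)})") from None


@dataclass
class EconomicSettings:
    discount_rate_costs: float = 0.035
    discount_rate_effects: float = 0.035
    horizon_cycles: int = 40
    cycle_length: float = 1.0
    half_cycle_correction: bool = False
    wtp_threshold: float = 4091.0
    adherence: float = 1.0

    def validate(self) -> None:
        _check(0 <= self.discount_rate_costs < 1, "discount_rate_costs in [0,1)")
        _check(0 <= self.discount_rate_effects < 1, "discount_rate_effects in [0,1)")
        _check(self.horizon_cycles >= 1, "horizon_cycles must be >= 1")
        _check(self.cycle_length > 0, "cycle_length must be positive")
        _check(not self.half_cycle_correction,
               "half-cycle correction is not part of this model")
        _check(self.wtp_threshold > 0, "wtp_threshold must be positive")
        _check(0 < self.adherence <= 1, "adherence must be in (0, 1]")


@dataclass
class ModelParameters:
    """The full, validated parameter set for one index cohort.

    ``annual_incidence_chd``/``annual_incidence_stroke`` are the entry-age
    annual first-event probabilities; when ``incidence_by_age`` is present the
    engine uses the age-specific values (per-cycle risk recalculation), else the
    entry-age values are held constant over the horizon.
    """

    profile: RiskProfile
    treatments: list[TreatmentEffect]
    lifestyle_counseling: TreatmentEffect
    costs: CostParameters
    utilities: UtilityParameters
    mortality: MortalityParameters
    economics: EconomicSettings
    annual_incidence_chd: float
    annual_incidence_stroke: float
    incidence_by_age: dict[int, tuple[float, float]] | None = None
    provenance: dict[str, str] = field(default_factory=dict)
    currency: str = CURRENCY

    def validate(self) -> "ModelParameters":
        self.profile.validate()
        for t in self.treatments:
            t.validate()
        self.lifestyle_counseling.validate()
        self.costs.validate()
        self.utilities.validate()
        self.mortality.validate()
        self.economics.validate()
        _check(0 <= self.annual_incidence_chd < 1,
               "annual_incidence_chd must be in [0, 1)")
        _check(0 <= self.annual_incidence_stroke < 1,
               "annual_incidence_stroke must be in [0, 1)")
        age0 = int(self.profile.age_entry)
        for cycle in range(1, self.economics.horizon_cycles + 1):
            age = age0 + cycle - 1
            p_chd, p_stroke = self.incidence_at(age)
            total = p_chd + p_stroke + self.mortality.qx(age)
            _check(total < 1,
                   f"event + death probabilities sum to {total:.4f} >= 1 at age {age}")
        return self

    def incidence_at(self, age: int) -> tuple[float, float]:
        """Annual (CHD, stroke) first-event probabilities at an attained age."""
        if self.incidence_by_age is not None:
            table = self.incidence_by_age
            key = int(age)
            if key not in table:  # hold boundary value beyond tabulated range
                key = max(table) if key > max(table) else min(table)
            return table[key]
        return self.annual_incidence_chd, self.annual_incidence_stroke

    def treatment(self, name: str) -> TreatmentEffect:
        if name == "lifestyle":
            return self.lifestyle_counseling
        for t in self.treatments:
            if t.name == name:
                return t
        raise ParameterError(f"no treatment named {name!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples/int keys do not survive YAML round trips; normalise here
        return _jsonify(d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2, sort_keys=True)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        return _params_from_dict(d)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _params_from_dict(d: Mapping[str, Any]) -> ModelParameters:
    def band(b) -> tuple[float | None, float | None]:
        lo, hi = b
        return (None if lo is None else float(lo),
                None if hi is None else float(hi))

    def effect(e) -> TreatmentEffect:
        return TreatmentEffect(name=e["name"],
                               rr_chd=float(e["rr_chd"]),
                               rr_chd_ci=tuple(map(float, e["rr_chd_ci"])),
                               rr_stroke=float(e["rr_stroke"]),
                               rr_stroke_ci=tuple(map(float, e["rr_stroke_ci"])))

    p = d["profile"]
    profile = RiskProfile(
        cohort_label=p["cohort_label"], sex=p["sex"],
        sbp_band=band(p["sbp_band"]), sbp=float(p["sbp"]),
        total_cholesterol_band=band(p["total_cholesterol_band"]),
        total_cholesterol=float(p["total_cholesterol"]),
        hdl=float(p["hdl"]), smoker=bool(p["smoker"]),
        diabetic=bool(p["diabetic"]), age_entry=float(p.get("age_entry", 40.0)))
    mort = dict(d["mortality"])
    mort["background_life_table"] = {
        int(a): float(q) for a, q in mort["background_life_table"].items()}
    inc_by_age = d.get("incidence_by_age")
    if inc_by_age is not None:
        inc_by_age = {int(a): (float(v[0]), float(v[1]))
                      for a, v in inc_by_age.items()}
    return ModelParameters(
        profile=profile,
        treatments=[effect(e) for e in d["treatments"]],
        lifestyle_counseling=effect(d["lifestyle_counseling"]),
        costs=CostParameters(**d["costs"]),
        utilities=UtilityParameters(**d["utilities"]),
        mortality=MortalityParameters(**mort),
        economics=EconomicSettings(**d["economics"]),
        annual_incidence_chd=float(d["annual_incidence_chd"]),
        annual_incidence_stroke=float(d["annual_incidence_stroke"]),
        incidence_by_age=inc_by_age,
        provenance=dict(d.get("provenance", {})),
        currency=d.get("currency", CURRENCY),
    ).validate()


# --------------------------------------------------------------------------
# worked-example arithmetic on the published cost table
# --------------------------------------------------------------------------

def sum_cost_components(components: Iterable[int]) -> int:
    """Exact integer sum of IRR cost line items (one published table column)."""
    total = 0
    for c in components:
        _check(c >= 0, f"negative cost component {c}")
        total += int(c)
    return total


def adjust_cost(base_irr: float, inflation_factor: float,
                exchange_rate: float) -> float:
    """Inflate a 2017 IRR amount and convert to USD.

    ``exchange_rate`` is IRR per USD after inflation.
    """
    _check(inflation_factor > 0, "inflation_factor must be positive")
    _check(exchange_rate > 0, "exchange_rate must be positive")
    return base_irr * inflation_factor / exchange_rate


def implied_conversion() -> tuple[float, float]:
    """(inflation factor, IRR-per-USD rate) implied by the published cost rows."""
    conv = printed_tables()["conversion"]
    factor = conv["inflation_numerator_irr"] / conv["inflation_denominator_irr"]
    rate = conv["inflation_numerator_irr"] / conv["usd_anchor"]
    return factor, rate


# --------------------------------------------------------------------------
# the packaged base case
# --------------------------------------------------------------------------

def paper_base_case(cohort_label: str, diabetic: bool,
                    sex: str | None = None) -> ModelParameters:
    """The published base-case parameter set for one index cohort.

    Inputs the publication does not print — the background life table, annual
    incidences and post-event fatalities — come from the synthetic-data
    defaults and are flagged ``synthetic`` in the provenance map. ``sex``
    overrides the cohort's published sex for heterogeneity runs.
    """
    _check(cohort_label in COHORT_LABELS,
           f"unknown cohort_label {cohort_label!r}")
    tables = printed_tables()
    scenario_key = "with_diabetes" if diabetic else "without_diabetes"
    prof = tables["index_cohorts"][scenario_key][cohort_label]
    profile = RiskProfile(
        cohort_label=cohort_label,
        sex=sex if sex is not None else prof["sex"],
        sbp_band=tuple(prof["sbp_band"]), sbp=float(prof["sbp_representative"]),
        total_cholesterol_band=tuple(prof["tc_band"]),
        total_cholesterol=float(prof["tc_representative"]),
        hdl=float(prof["hdl"]), smoker=bool(prof["smoker"]), diabetic=diabetic)

    treatments = [
        TreatmentEffect(name, float(v["chd"][0]),
                        (float(v["chd"][1]), float(v["chd"][2])),
                        float(v["stroke"][0]),
                        (float(v["stroke"][1]), float(v["stroke"][2])))
        for name, v in tables["relative_risks"].items() if name != "lifestyle"]
    ls = tables["relative_risks"]["lifestyle"]
    lifestyle = TreatmentEffect("lifestyle", float(ls["chd"][0]),
                                (float(ls["chd"][1]), float(ls["chd"][2])),
                                float(ls["stroke"][0]),
                                (float(ls["stroke"][1]), float(ls["stroke"][2])))

    cc = tables["cohort_costs"]
    if diabetic:
        program = {k: float(v) for k, v in cc["usd_total_with_diabetes"].items()}
        program_prov = "printed"
    else:
        # low: screening only (no medication at all); others: published total
        # minus the assumed diabetes-medication cost.
        program = {}
        for label in COHORT_LABELS:
            if label == "low":
                program[label] = float(cc["usd_without_medication"]["low"])
            else:
                program[label] = round(
                    float(cc["usd_total_with_diabetes"][label])
                    - float(cc["diabetes_medication_usd"][label]), 2)
        program_prov = "derived"

    sc = tables["state_costs"]
    fat = tables["case_fatality"]
    costs = CostParameters(
        program_annual_cost_per_cohort=program,
        chd_cost_year1=float(sc["chd_year1"][0]),
        chd_cost_year1_se=float(sc["chd_year1"][1]),
        chd_cost_subsequent=float(sc["chd_subsequent"][0]),
        chd_cost_subsequent_se=float(sc["chd_subsequent"][1]),
        stroke_cost_year1=float(sc["stroke_year1"][0]),
        stroke_cost_year1_se=float(sc["stroke_year1"][1]),
        stroke_cost_subsequent=float(sc["stroke_subsequent"][0]),
        stroke_cost_subsequent_se=float(sc["stroke_subsequent"][1]),
        prehospital_chd_death_fraction=float(fat["chd_prehospital_fraction"]),
        fatal_stroke_cost_fraction=float(fat["fatal_stroke_cost_fraction"]))

    ut = tables["utilities"]
    utilities = UtilityParameters(
        u_chd_year1=float(ut["chd_year1"][0]),
        u_chd_year1_se=float(ut["chd_year1"][1]),
        u_chd_subsequent=float(ut["chd_subsequent"][0]),
        u_chd_subsequent_se=float(ut["chd_subsequent"][1]),
        u_stroke_year1=float(ut["stroke_year1"][0]),
        u_stroke_year1_se=float(ut["stroke_year1"][1]),
        u_stroke_subsequent=float(ut["stroke_subsequent"][0]),
        u_stroke_subsequent_se=float(ut["stroke_subsequent"][1]))

    # unprinted inputs: synthetic life table and post-event fatalities,
    # per-cycle incidences from the packaged risk equations
    from . import risk_engine, synthetic_data

    life_table = synthetic_data.default_life_table()
    mortality = MortalityParameters(
        background_life_table=life_table,
        chd_case_fatality_year1=float(fat["chd_year1"]),
        stroke_case_fatality_year1=float(fat["stroke_year1"]),
        post_chd_annual_fatality=synthetic_data.DEFAULT_POST_CHD_FATALITY,
        post_stroke_annual_fatality=synthetic_data.DEFAULT_POST_STROKE_FATALITY)

    econ = tables["economics"]
    economics = EconomicSettings(
        discount_rate_costs=float(econ["discount_rate"]),
        discount_rate_effects=float(econ["discount_rate"]),
        horizon_cycles=int(econ["horizon_cycles"]),
        wtp_threshold=float(econ["wtp_threshold"]))

    incidence_by_age = risk_engine.incidence_schedule(
        profile, ages=sorted(life_table))
    p_chd0, p_stroke0 = incidence_by_age[int(profile.age_entry)]

    provenance = {
        "profile": "printed", "treatments": "printed",
        "lifestyle_counseling": "printed",
        "costs.program_annual_cost_per_cohort": program_prov,
        "costs.state_costs": "printed", "utilities": "printed",
        "mortality.case_fatality_year1": "printed",
        "mortality.post_event_fatality": "synthetic",
        "mortality.background_life_table": "synthetic",
        "economics": "printed",
        "annual_incidence": "derived",
    }
    return ModelParameters(
        profile=profile, treatments=treatments, lifestyle_counseling=lifestyle,
        costs=costs, utilities=utilities, mortality=mortality,
        economics=economics, annual_incidence_chd=p_chd0,
        annual_incidence_stroke=p_stroke0, incidence_by_age=incidence_by_age,
        provenance=provenance).validate()


# --------------------------------------------------------------------------
# config loading
# --------------------------------------------------------------------------

def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter config (YAML or JSON), filling missing fields from the
    packaged base case for the config's cohort.

    A minimal config is ``{cohort_label: high, diabetic: true}``; any field of
    the full serialized form may be overridden. Parse failures and invariant
    violations raise :class:`ParameterError` naming the problem.
    """
    path = Path(path)
    _check(path.exists(), f"no such parameter file: {path}")
    text = path.read_text()
    try:
        raw = (json.loads(text) if path.suffix == ".json"
               else yaml.safe_load(text))
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ParameterError(f"could not parse {path}: {exc}") from exc
    _check(isinstance(raw, Mapping), f"{path}: top level must be a mapping")

    label = raw.get("cohort_label") or raw.get("profile", {}).get("cohort_label")
    _check(label is not None, f"{path}: cohort_label missing")
    diabetic = raw.get("diabetic")
    if diabetic is None:
        diabetic = raw.get("profile", {}).get("diabetic", False)
    base = paper_base_case(label, bool(diabetic)).to_dict()
    merged = _deep_merge(base, {k: v for k, v in raw.items()
                                if k not in ("cohort_label", "diabetic")})
    try:
        return _params_from_dict(merged)
    except TypeError as exc:  # unknown field name in the config
        raise ParameterError(f"{path}: {exc}") from exc


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_life_table_csv(path: str | Path) -> dict[int, float]:
    """Read a 2-column (age, qx) CSV life table; a header row is optional."""
    table: dict[int, float] = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or (i == 0 and not row[0].strip().lstrip("-").isdigit()):
                continue
            age, qx = int(row[0]), float(row[1])
            _check(0 < qx <= 1, f"qx at age {age} must be in (0, 1], got {qx}")
            table[age] = qx
    _check(len(table) > 0, f"life table {path} is empty")
    return table


# --------------------------------------------------------------------------
# slash-path addressing (shared by the sensitivity analyses)
# --------------------------------------------------------------------------

def _resolve(params: ModelParameters, path: str):
    parts = path.split("/")
    obj: Any = params
    for i, part in enumerate(parts[:-1]):
        if part == "treatments":
            obj = params.treatment(parts[i + 1])
            continue
        if isinstance(obj, TreatmentEffect) and part == obj.name:
            continue
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    return obj, parts[-1]


def get_by_path(params: ModelParameters, path: str) -> float:
    """Read a scalar from the parameter tree, e.g. ``utilities/u_chd_year1``,
    ``treatments/statin/rr_chd`` or ``costs/program_annual_cost_per_cohort/high``."""
    obj, leaf = _resolve(params, path)
    value = obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)
    _check(isinstance(value, (int, float)) and not isinstance(value, bool),
           f"path {path!r} does not address a numeric scalar")
    return float(value)


def set_by_path(params: ModelParameters, path: str, value: float) -> None:
    get_by_path(params, path)  # type-check the target first
    obj, leaf = _resolve(params, path)
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        setattr(obj, leaf, value)
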
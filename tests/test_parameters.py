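"""Parameter types, the packaged base case, config loading and the published
cost-table arithmetic."""

import math
from importlib import resources

import pytest
import yaml

from irapen_cea import (ModelParameters, ParameterError, adjust_cost,
                        paper_base_case, printed_tables, sum_cost_components)
from irapen_cea.parameters import (get_by_path, implied_conversion,
                                   load_life_table_csv, load_parameters,
                                   set_by_path)

COHORTS = ("low", "moderate", "high", "very_high")


def fixture_path(name):
    return resources.files("irapen_cea.data").joinpath(f"fixtures/{name}.yaml")


class TestCostTableArithmetic:
    @pytest.mark.parametrize("cohort,expected", [
        ("low", 165_804), ("moderate", 598_496), ("high", 817_185)])
    def test_component_sums_match_printed_totals(self, cohort, expected):
        comps = printed_tables()["cohort_costs"]["irr_components"][cohort]
        assert sum_cost_components(comps.values()) == expected
        assert (printed_tables()["cohort_costs"]["irr_total_printed"][cohort]
                == expected)

    def test_very_high_column_off_by_one(self):
        # the printed very-high total exceeds its own component sum by 1 IRR
        comps = printed_tables()["cohort_costs"]["irr_components"]["very_high"]
        printed = printed_tables()["cohort_costs"]["irr_total_printed"]
        assert sum_cost_components(comps.values()) == printed["very_high"] - 1

    def test_empty_sum_and_negative_component(self):
        assert sum_cost_components([]) == 0
        with pytest.raises(ParameterError):
            sum_cost_components([100, -1])

    def test_adjust_cost_identity_and_zero(self):
        assert adjust_cost(165_804, 1.0, 165_804) == 1.0
        assert adjust_cost(0, 1.306, 41_965) == 0

    def test_implied_conversion_reproduces_printed_usd_rows(self):
        factor, rate = implied_conversion()
        cc = printed_tables()["cohort_costs"]
        for cohort in COHORTS:
            usd = adjust_cost(cc["irr_total_printed"][cohort], factor, rate)
            # printed rows imply 41,965-42,002 IRR/USD; agree to ~3 cents
            assert usd == pytest.approx(
                cc["usd_without_medication"][cohort], abs=0.03)

    def test_adjust_cost_rejects_nonpositive_rates(self):
        with pytest.raises(ParameterError):
            adjust_cost(100, 0.0, 10.0)
        with pytest.raises(ParameterError):
            adjust_cost(100, 1.0, -1.0)


class TestPaperBaseCase:
    @pytest.mark.parametrize("cohort,cost", [
        ("low", 21.63), ("moderate", 57.46), ("high", 73.68),
        ("very_high", 85.29)])
    def test_diabetic_program_costs_as_printed(self, cohort, cost):
        p = paper_base_case(cohort, diabetic=True)
        assert p.costs.program_annual_cost_per_cohort[cohort] == cost

    def test_printed_state_costs_and_utilities(self, base_very_high):
        p = paper_base_case("high", diabetic=True)
        assert p.costs.stroke_cost_year1 == 5691
        assert base_very_high.costs.chd_cost_year1 == 519
        assert base_very_high.utilities.u_chd_year1 == 0.67
        assert base_very_high.utilities.u_stroke_subsequent == 0.52

    def test_low_without_diabetes_is_screening_only(self, base_low_no_diabetes):
        costs = base_low_no_diabetes.costs.program_annual_cost_per_cohort
        assert costs["low"] == 5.16

    def test_unknown_label_rejected(self):
        with pytest.raises(ParameterError):
            paper_base_case("extreme", diabetic=False)

    def test_unprinted_inputs_flagged_synthetic(self, base_very_high):
        prov = base_very_high.provenance
        assert prov["mortality.background_life_table"] == "synthetic"
        assert prov["mortality.post_event_fatality"] == "synthetic"
        assert prov["utilities"] == "printed"

    def test_sex_override_for_heterogeneity_runs(self):
        p = paper_base_case("very_high", diabetic=False, sex="female")
        assert p.profile.sex == "female"

    @pytest.mark.parametrize("diabetic", [False, True])
    @pytest.mark.parametrize("cohort", COHORTS)
    def test_every_base_case_validates(self, cohort, diabetic, all_base_cases):
        all_base_cases[(cohort, diabetic)].validate()


class TestLoadAndSerialize:
    def test_packaged_fixture_very_high_no_diabetes(self):
        p = load_parameters(fixture_path("very_high_no_diabetes"))
        assert p.profile.smoker is True
        assert p.profile.sex == "male"
        assert p.utilities.u_chd_year1 == 0.67

    @pytest.mark.parametrize("name", [
        f"{c}_{tag}" for c in COHORTS for tag in ("no_diabetes", "diabetes")])
    def test_round_trip_all_packaged_fixtures(self, tmp_path, name):
        p = load_parameters(fixture_path(name))
        out = tmp_path / "params.yaml"
        p.save(out)
        q = ModelParameters.from_dict(yaml.safe_load(out.read_text()))
        assert q.to_dict() == p.to_dict()

    def test_json_round_trip(self, tmp_path, base_very_high):
        out = tmp_path / "params.json"
        base_very_high.save(out)
        import json
        q = ModelParameters.from_dict(json.loads(out.read_text()))
        assert q.to_dict() == base_very_high.to_dict()

    def test_invalid_utility_rejected_by_name(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("cohort_label: high\ndiabetic: true\n"
                       "utilities:\n  u_dead: 0.1\n")
        with pytest.raises(ParameterError, match="u_dead"):
            load_parameters(cfg)

    def test_parse_error_reported(self, tmp_path):
        cfg = tmp_path / "broken.yaml"
        cfg.write_text("cohort_label: [unclosed\n")
        with pytest.raises(ParameterError, match="parse"):
            load_parameters(cfg)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            load_parameters(tmp_path / "nope.yaml")

    def test_life_table_csv(self, tmp_path):
        f = tmp_path / "lt.csv"
        f.write_text("age,qx\n40,0.002\n41,0.0022\n")
        assert load_life_table_csv(f) == {40: 0.002, 41: 0.0022}


class TestPathAddressing:
    def test_get_and_set_scalar_paths(self, base_very_high):
        import copy
        p = copy.deepcopy(base_very_high)
        assert get_by_path(p, "utilities/u_chd_year1") == 0.67
        assert get_by_path(p, "treatments/statin/rr_chd") == 0.86
        set_by_path(p, "costs/program_annual_cost_per_cohort/very_high", 90.0)
        assert p.costs.program_annual_cost_per_cohort["very_high"] == 90.0

    def test_non_scalar_path_rejected(self, base_very_high):
        with pytest.raises(ParameterError):
            get_by_path(base_very_high, "profile/smoker")


def test_incidence_probabilities_feasible_at_every_age(all_base_cases):
    # spec invariant: event + death probabilities sum below 1 at every age
    for p in all_base_cases.values():
        age0 = int(p.profile.age_entry)
        for cycle in range(1, p.economics.horizon_cycles + 1):
            age = age0 + cycle - 1
            chd, stroke = p.incidence_at(age)
            assert chd + stroke + p.mortality.qx(age) < 1
            assert math.isfinite(chd) and math.isfinite(stroke)
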
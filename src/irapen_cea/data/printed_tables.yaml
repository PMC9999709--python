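# Published IraPEN base-case inputs and results, transcribed from the source
# cost-effectiveness study. Values under *_representative are this package's
# point choices inside the published bands (the study prints bands only);
# they are chosen so each index cohort's computed 10-year risk falls in its
# own labelled risk band, and are flagged `derived` in provenance.
currency: USD

index_cohorts:
  without_diabetes:
    low:       {sbp_band: [120, 139], sbp_representative: 130, tc_band: [null, 195], tc_representative: 180, hdl: 40, smoker: false, sex: male}
    moderate:  {sbp_band: [140, 159], sbp_representative: 150, tc_band: [310, null], tc_representative: 350, hdl: 46, smoker: true,  sex: female}
    high:      {sbp_band: [160, 179], sbp_representative: 170, tc_band: [310, null], tc_representative: 350, hdl: 46, smoker: true,  sex: female}
    very_high: {sbp_band: [180, null], sbp_representative: 190, tc_band: [310, null], tc_representative: 350, hdl: 41, smoker: true,  sex: male}
  with_diabetes:
    low:       {sbp_band: [120, 139], sbp_representative: 130, tc_band: [null, 195], tc_representative: 180, hdl: 46, smoker: false, sex: female}
    moderate:  {sbp_band: [140, 159], sbp_representative: 150, tc_band: [310, null], tc_representative: 350, hdl: 46, smoker: false, sex: female}
    high:      {sbp_band: [160, 179], sbp_representative: 170, tc_band: [null, 270], tc_representative: 220, hdl: 40, smoker: true,  sex: male}
    very_high: {sbp_band: [180, null], sbp_representative: 190, tc_band: [null, 270], tc_representative: 220, hdl: 41, smoker: true,  sex: male}

# Relative risks (95% CI) per medication subclass, per outcome.
relative_risks:
  ace_inhibitor:   {chd: [0.81, 0.70, 0.94], stroke: [0.65, 0.52, 0.82]}
  thiazide:        {chd: [0.84, 0.75, 0.95], stroke: [0.63, 0.57, 0.71]}
  beta_blocker:    {chd: [0.90, 0.78, 1.03], stroke: [0.83, 0.72, 0.97]}
  statin:          {chd: [0.86, 0.82, 0.90], stroke: [0.90, 0.85, 0.95]}
  metformin:       {chd: [0.67, 0.51, 0.89], stroke: [0.80, 0.50, 1.27]}
  sulfonylurea:    {chd: [0.85, 0.74, 0.97], stroke: [0.91, 0.73, 1.13]}
  lifestyle:       {chd: [0.86, 0.81, 0.91], stroke: [0.86, 0.81, 0.91]}

# Annual program cost per index cohort (with diabetes), 2017 IRR line items and
# the published USD conversions.
cohort_costs:
  irr_components:
    low:       {behvarz_visit: 108173, nutrition_consultation: 38400, fixed_costs: 19231}
    moderate:  {behvarz_visit: 324519, physician_visit: 216346, nutrition_consultation: 38400, fixed_costs: 19231}
    high:      {behvarz_visit: 432692, physician_visit: 288462, nutrition_consultation: 38400, psychiatrist_consultation: 38400, fixed_costs: 19231}
    very_high: {behvarz_visit: 432692, physician_visit: 432692, nutrition_consultation: 38400, psychiatrist_consultation: 38400, fixed_costs: 19231}
  irr_total_printed:        {low: 165804, moderate: 598496, high: 817185, very_high: 961416}
  irr_total_inflated:       {low: 216540, moderate: 781636, high: 1067243, very_high: 1255609}
  usd_without_medication:   {low: 5.16, moderate: 18.61, high: 25.41, very_high: 29.90}
  usd_medication:           {low: 16.00, moderate: 38.85, high: 48.27, very_high: 55.39}
  usd_total_with_diabetes:  {low: 21.63, moderate: 57.46, high: 73.68, very_high: 85.29}
  # Assumed annual diabetes-medication cost removed for non-diabetic cohorts
  # (not printed in the source; package assumption, provenance `derived`).
  diabetes_medication_usd:  {low: 0.0, moderate: 7.00, high: 10.00, very_high: 10.00}

state_costs:   # mean, SE (USD/year)
  chd_year1:         [519, 51]
  chd_subsequent:    [173, 17]
  stroke_year1:      [5691, 569]
  stroke_subsequent: [1422, 142]

utilities:     # mean, SE
  chd_year1:         [0.67, 0.024]
  stroke_year1:      [0.33, 0.033]
  chd_subsequent:    [0.82, 0.012]
  stroke_subsequent: [0.52, 0.027]

case_fatality:
  chd_year1: 0.25
  chd_prehospital_fraction: 0.60
  stroke_year1: 0.25
  fatal_stroke_cost_fraction: 0.40

economics:
  discount_rate: 0.035
  horizon_cycles: 40
  wtp_threshold: 4091
  age_entry: 40

# Currency conversion implied by the published cohort-cost rows
# (inflated IRR / USD-without-medication; the study prints neither rate directly).
conversion:
  inflation_numerator_irr: 216540
  inflation_denominator_irr: 165804
  usd_anchor: 5.16

# Published base-case results (per-arm values, incrementals, ICERs as printed).
# `consistent` flags whether the printed incremental equals the printed arm
# difference / whether the printed ICER equals incremental cost over QALY
# rounded to whole dollars (several printed cells disagree by one unit in the
# last digit, presumably rounded upstream of differencing).
base_case_results:
  without_diabetes:
    low:
      status_quo: {cost: 845, qaly: 18.12, ly: 32.27}
      irapen:     {cost: 918, qaly: 18.12, ly: 32.27}
      incremental: {cost: 73, qaly: 0.0, ly: 0.0}
      icer: Undefined
      consistent: {cost: true, qaly: true, ly: true, icer: true}
    moderate:
      status_quo: {cost: 979, qaly: 17.89, ly: 32.37}
      irapen:     {cost: 1375, qaly: 18.38, ly: 33.06}
      incremental: {cost: 396, qaly: 0.49, ly: 0.69}
      icer: 804
      consistent: {cost: true, qaly: true, ly: true, icer: false}
    high:
      status_quo: {cost: 1204, qaly: 17.68, ly: 32.13}
      irapen:     {cost: 1594, qaly: 18.38, ly: 33.09}
      incremental: {cost: 391, qaly: 0.71, ly: 0.96}
      icer: 551
      consistent: {cost: false, qaly: false, ly: true, icer: true}
    very_high:
      status_quo: {cost: 2348, qaly: 15.83, ly: 29.3}
      irapen:     {cost: 2296, qaly: 17.02, ly: 30.75}
      incremental: {cost: -52, qaly: 1.19, ly: 1.45}
      icer: -44
      consistent: {cost: true, qaly: true, ly: true, icer: true}
  with_diabetes:
    low:
      status_quo: {cost: 647, qaly: 18.59, ly: 33.36}
      irapen:     {cost: 866, qaly: 18.9, ly: 33.82}
      incremental: {cost: 219, qaly: 0.31, ly: 0.46}
      icer: 711
      consistent: {cost: true, qaly: true, ly: true, icer: false}
    moderate:
      status_quo: {cost: 1027, qaly: 17.75, ly: 32.17}
      irapen:     {cost: 1560, qaly: 18.59, ly: 33.37}
      incremental: {cost: 533, qaly: 0.85, ly: 1.2}
      icer: 630
      consistent: {cost: true, qaly: false, ly: true, icer: false}
    high:
      status_quo: {cost: 2429, qaly: 15.91, ly: 29.46}
      irapen:     {cost: 2361, qaly: 17.53, ly: 31.5}
      incremental: {cost: -68, qaly: 1.61, ly: 2.04}
      icer: -42
      consistent: {cost: true, qaly: false, ly: true, icer: true}
    very_high:
      status_quo: {cost: 2810, qaly: 15.31, ly: 28.74}
      irapen:     {cost: 2678, qaly: 17.18, ly: 31.03}
      incremental: {cost: -133, qaly: 1.87, ly: 2.29}
      icer: -71
      consistent: {cost: false, qaly: true, ly: true, icer: true}
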
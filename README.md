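# irapen-cea

A decision-analytic model of risk-stratified primary prevention of
cardiovascular disease (CVD), built around Iran's IraPEN program (the national
adaptation of the WHO Package of Essential Noncommunicable disease
interventions). The package compares lifelong preventive treatment against a
no-prevention status quo for index cohorts defined by the WHO/ISH 10-year CVD
risk bands, and reports incremental cost-effectiveness from a healthcare
perspective. It is aimed at health-economic modellers who want a tested,
scriptable re-implementation of this class of analysis rather than a
spreadsheet.

## The model

Four index cohorts enter at age 40, classified by 10-year CVD risk *p₁₀*
computed from Framingham-type survival equations:
low (<10%), moderate (10–19%), high (20–29%), very high (≥30%).
Each cohort runs through a four-state Markov model (event-free, CHD, stroke,
dead; the post-event states carry a first-year tunnel) over 40 annual cycles
with no half-cycle correction. Annual event probabilities follow a
constant-hazard annualisation, *p₁ = 1 − (1 − p₁₀)^{1/10}*, split 3:1 into
CHD:stroke, and are scaled in the intervention arm by an effective relative
risk that combines the medication package with an overlap correction:

    RR_combined = 1 − (1 − RR₁·RR₂·…·RRₙ) × 0.8          (n ≥ 2)
    RR_effective = 1 − adherence × (1 − RR_combined)

A quarter of CHD events are fatal in the first year (60% of those
pre-hospital and costless); a quarter of strokes are fatal, incurring 40% of
the first-year stroke cost. Costs and effects are discounted at 3.5%/year and
compared as ICER = ΔC/ΔE against a willingness-to-pay threshold of $4,091
(1 × GDP per capita). One-way sensitivity analysis produces tornado
orderings; probabilistic sensitivity analysis samples costs (gamma),
utilities (beta) and relative risks (lognormal from their 95% CIs) over 1,000
draws.

The published program costs, treatment effects, state costs and utilities are
packaged as data; the background life table, annual incidences and post-event
fatalities are not published and are generated synthetically (see
`docs/methods.md`), so absolute cost/QALY levels are illustrative while the
in-table arithmetic, model structure and qualitative conclusions are
reproduced exactly.

## Worked example

```sh
irapen-cea run --cohort very_high --no-diabetes --out out/
```

prints

```
cohort=very_high diabetic=False ICER=-37 status=dominant_cost_saving
```

and writes per-cycle traces plus `ce_result.json`, whose incremental block
reads (discounted, 40-year horizon):

```
delta cost  = -71.37 USD
delta QALY  =  1.95
delta LY    =  1.60
ICER        = -37 USD/QALY   (dominant: cheaper and more effective)
```

Treating the very-high-risk cohort saves money and gains almost two
quality-adjusted life years per person relative to no prevention: the program
cost ($85.29/year) is more than offset by avoided CHD/stroke state costs. The
same command with `--cohort low` reports `ICER=Undefined` — that cohort is
screened but not treated, so it accrues cost without any health effect.

The library surface mirrors the pipeline:

```python
from irapen_cea import paper_base_case, evaluate, run_psa

params = paper_base_case("very_high", diabetic=False)
result = evaluate(params)             # CEResult with ICER, status, NMB
psa = run_psa(params, n_draws=1000, seed=1)
print(result.icer_reported, psa.summary["fraction_cost_saving"])
```

## Layout

- `src/irapen_cea/parameters.py` — domain types, validation, config I/O, the
  packaged published base case
- `src/irapen_cea/risk_engine.py` — Framingham-type risk, annualisation,
  WHO/ISH banding, background mortality
- `src/irapen_cea/intervention.py` — treatment packages, RR combination,
  adherence
- `src/irapen_cea/markov_engine.py` — the cohort engine and reward rules
- `src/irapen_cea/cea.py` — incremental analysis, dominance, NMB
- `src/irapen_cea/dsa.py`, `psa.py` — deterministic and probabilistic
  sensitivity analysis
- `src/irapen_cea/synthetic_data.py` — synthetic inputs, microsimulation
  oracle, self-recovery checks
- `src/irapen_cea/cli.py` — the `irapen-cea` command
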
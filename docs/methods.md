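# Methods

## Model structure

Two scenarios (with and without diabetes) share one structure: a cohort of
identical 40-year-olds advances through six computational states — event-free,
CHD first year, CHD subsequent, stroke first year, stroke subsequent, dead —
over 40 annual cycles. The first-year states are tunnel states: entrants stay
exactly one cycle, then move to the chronic state or die. There are no second
or cross-over CVD events (a survivor of one event can only remain in that
event's chronic state or die), no return to event-free, and no half-cycle
correction: all transitions and rewards fall at cycle end, and cycle 0
accrues nothing. Within a cycle, competing exits from event-free (CHD event,
stroke event, non-CVD death) are treated as mutually exclusive; their sum is
validated to stay below 1 at every attained age. Post-event states face the
event-specific annual fatality and background mortality combined
independently, 1 − (1 − p_fatal)(1 − qx).

## Risk input

Each cohort's 10-year CVD risk comes from the sex-specific Framingham
general-CVD Cox equations (2008 lipid-based specification), shipped as a
versioned YAML data file so alternative published coefficient sets can be
swapped in. The combined CVD risk is annualised under constant hazard,
p₁ = 1 − (1 − p₁₀)^{1/10}, and split into CHD and stroke at a configurable
3:1 ratio. Risk is re-evaluated every cycle with age incremented (ages beyond
the equations' 30–74 calibration range are clamped with a warning); a
constant-incidence mode is also supported and is what the synthetic scenarios
use. WHO/ISH classification always operates on the 10-year risk with
half-open bands: [0, 0.10) low, [0.10, 0.20) moderate, [0.20, 0.30) high,
[0.30, 1] very high.

The published cohort definitions give risk-factor *bands*, not point values.
The packaged profiles use representative points inside those bands — mid-band
systolic pressure (130/150/170, and 190 for ">180"), total cholesterol 180
for "<195", 350 for ">310", 220 for "<270" — chosen once, at fixture
construction, so that each of the eight profiles classifies into its own
labelled band under the packaged equations. These representative values are
tagged `derived` in the provenance map.

## Intervention effect

Medication packages escalate with risk: the moderate cohort receives a statin
plus one antihypertensive (ACE inhibitor), high adds a thiazide, very high
adds a beta-blocker; diabetic cohorts add metformin (all) and a sulfonylurea
(high/very high); every treated package includes lifestyle counseling, whose
relative risk enters the combination product like any other component. The
low-risk non-diabetic cohort is screened only. Component relative risks are
multiplied and the joint reduction damped by the 0.8 overlap factor whenever
two or more components act; a single component is used as-is. Partial
adherence scales the combined risk reduction linearly — the simplest monotone
contract that restores the base case at 100% and no effect at 0%.

## Costs, utilities, discounting

The intervention arm pays the cohort's annual program cost while event-free;
the status-quo arm costs nothing until an event. Disease states cost
$519/$173 (CHD first/subsequent year) and $5,691/$1,422 (stroke), with
published standard errors; any cost item without a published SE takes
SE = 0.1 × mean. Fatal CHD entrants are costless for the pre-hospital 60%
and incur the full first-year CHD cost otherwise (the hospital fraction's
cost share is an exposed scalar); fatal strokes incur 40% of the first-year
stroke cost, absorbing the half-within-28-days timing into a single rule
without sub-annual cycles. Death costs nothing. Utilities are 1 event-free,
0 dead, 0.67/0.82 for CHD and 0.33/0.52 for stroke (first year/chronic).
Fatal entrants accrue no QALY or LY in their event cycle; everyone alive at
cycle end accrues one LY. Costs and effects are discounted at 3.5%/year with
factor (1+r)^(−t); the module contract reports discounted cost, QALY and LY
(undiscounted per-cycle contributions remain available on the trace — note
that the source publication's LY column appears undiscounted, so absolute LY
levels are not comparable to the printed tables).

Program costs are modelled in USD. The published cost table's 2017 IRR rows
imply an inflation factor of 216,540/165,804 and an exchange rate of
216,540/5.16 IRR per USD; neither rate is printed directly, and the USD rows
are mutually consistent only to about three cents. The printed very-high
column total (961,416 IRR) exceeds its own component sum by 1 IRR; the
fixture stores the printed value and the tests assert the discrepancy.
Program costs are printed for diabetic cohorts only; non-diabetic cohorts
default to the printed total minus an assumed diabetes-medication cost
($7/year metformin, $3/year glibenclamide), tagged `derived`, with the
non-diabetic low cohort taking the screening-only $5.16 row.

## Sensitivity analyses

One-way DSA pushes each scalar (addressed by slash-path, e.g.
`utilities/u_chd_year1`) to its bounds — 95% CIs for relative risks,
mean ± 1.96 SE truncated at zero for costs and utilities, 50–100% for
adherence — two model runs per parameter, everything else at base. Spreads
are measured on full-precision ICERs to avoid rounding ties; undefined-ICER
runs are carried as flagged entries outside the ordering.

PSA assigns gamma to costs (shape = (m/SE)², rate = m/SE²), beta to utilities
(moment matching), and lognormal to relative risks (median at the point
estimate, σ from the 95% CI width). Parameters are drawn independently;
component RRs are sampled before combination so the overlap-corrected effect
varies coherently within a draw. Each parameter path owns a named substream
(seed plus a hash of the path), so adding a parameter leaves every other
parameter's draws unchanged. Draws violating a type invariant are replaced
from per-path reserves (logged; a >1% rate warns). A sampled RR may fall
outside the catalogued 95% CI; the stored CI is widened to contain it, since
that invariant describes the catalogue entry rather than a draw. Transition
baselines (incidences, fatalities) stay fixed unless explicitly assigned.

## Synthetic inputs

The source analysis took its background life table, annual incidences and
post-event fatalities from national data files that are not printed; this
package generates stand-ins with the structure the analysis assumes:

- **Life table** — Gompertz annual death probabilities,
  qx = 1 − exp(−a·e^{b·age}(e^b − 1)/b), with a = 5·10⁻⁵, b = 0.095, ages
  40–80; remaining life expectancy at 40 ≈ 35–37 years, consistent with a
  national life expectancy above 75. The table is used directly as the
  net-of-CVD background; the explicit all-cause-minus-CVD subtraction is a
  separate, tested operation for users supplying real tables.
- **Incidences** — scenario 10-year risks drawn uniformly inside the target
  band (very high capped at 0.45), annualised and split 3:1.
- **Post-event fatality** — 0.04/year after CHD, 0.08/year after stroke
  (the published range for first-year stroke fatality, 22–34%, bounds the
  configurable first-year rate; the chronic rates are package defaults).

All such values carry `synthetic` provenance. Because these inputs differ
from the unpublished originals, the absolute base-case costs, QALYs and LYs
do **not** reproduce the printed result tables, and no test asserts that
they do. What passing tests *do* show: the printed in-table arithmetic is
reproduced exactly; the engine's expectation arithmetic matches an
independent individual-level microsimulation within Monte-Carlo error; and
the qualitative published findings hold under the packaged inputs (undefined
ICER for untreated low risk, cost-saving very-high cohorts, 100% of PSA
draws cost-effective at the threshold for very-high risk, adherence
dominating the tornado at high risk).

## Numerical choices and problem sizes

State occupancy is conserved to 1e-12 per cycle and enforced at 1e-9.
Zero-effect incrementals use |ΔQALY| < 1e-9 for the undefined-ICER status;
reported ICERs round to whole dollars while full precision is kept
internally. The microsimulation check uses 100,000 simulees per arm on three
scenarios (agreement within 3 Monte-Carlo SEs); generator self-recovery uses
10⁶ simulated histories against 3 binomial SEs; the PSA uses the published
1,000 draws. The whole test suite runs in well under a minute.

## Known limitations

Second and recurrent CVD events are excluded (as in the source analysis),
which plausibly makes the intervention look slightly worse than it is. The
CHD:stroke split is a fixed ratio rather than outcome-specific equations.
Treatment effects are age- and risk-invariant. The horizon stops at age 80
with the life table. Adherence enters only as a linear effect modifier, not
as a cost modifier.
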
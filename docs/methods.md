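# Methods

## Decision problem and model structure

The package evaluates eight first-line treatment strategies for metastatic
colorectal cancer.  Analysis 1 compares biomarker gating policies — testing
for KRAS exon-2 wild-type only vs extended RAS wild-type (KRAS/NRAS exons
2–4) — before adding cetuximab or bevacizumab to physician-choice
chemotherapy (KRAS-Cetux, KRAS-Bev, RAS-Cetux, RAS-Bev).  Analysis 2 fixes
the population at extended-RAS wild-type and compares chemotherapy backbones
(FOLFOX-Cetux, FOLFOX-Bev, FOLFIRI-Cetux, FOLFIRI-Bev).  Efficacy inputs are
the arm-level median PFS/OS of the CALGB 80405 trial; costs reflect a
Chinese tertiary-hospital setting at $1 = ¥6.15.

The cohort model has three mutually exclusive states — stable disease (SD),
progressive disease (PD), death — with monthly cycles.  Everyone starts in
SD.  By default death is reached only through progression
(`progression_required`): this keeps the two hazards identifiable from the
two published medians, with overall survival decomposing as
OS = PFS + post-progression time.  A competing-risk variant (`direct_death`)
is selectable for structural sensitivity: the SD exit probability implied by
the PFS median is split between progression and a direct death hazard
implied by the OS median.

## Transition probabilities

Median time-to-event *m* (months) converts to a constant per-cycle
probability P = 1 − (1/2)^(1/m), the exact discretization of an exponential
hazard R = ln2/m.  SD→PD uses the PFS median; PD→death uses OS − PFS,
asserting memorylessness (the standard convention when only medians are
available; whether the source analyses used OS or OS − PFS for the
post-progression hazard cannot be confirmed, as their transition-probability
table is not available).  Probabilities are carried at full floating
precision.  Note the discrete geometric mean 1/P exceeds the continuous mean
m/ln2 by about half a cycle — a known, bounded discretization effect
(~0.5·ln2/m relative, ≈6% at m = 6 months) that the tests pin down exactly.

## Costs

Per-cycle SD cost = biologic drug + chemotherapy backbone + administration/
monitoring + societal + adverse-event management; the first cycle adds the
cetuximab loading increment (one administration at 400 mg/m² instead of
250 mg/m²).  Per-cycle PD cost = weighted subsequent-therapy cost +
administration/monitoring + societal fees at a 14-day visit cadence.
Components are itemized and always sum to the totals (a tested conservation
property), and all totals are linear in unit costs.

* Dosing arithmetic uses BSA 1.60 m² and body weight 58 kg.  Unit drug
  prices (USD/mg) are *derived* calibration values chosen so the arithmetic
  reproduces the published per-administration costs: cetuximab
  $3,027.55 regular / $4,844.08 loading (ratio exactly 640/400 = 1.600),
  bevacizumab $2,608.99 per 14-day dose.
* 7- and 14-day schedules convert to monthly cycles with a calendar-average
  month of 365.25/12 days (conventional; the sources do not state one).
* Adverse events: grade-3/4 incidences per biologic arm are published; unit
  costs are not.  The calibration file fixes two unit costs (hematologic,
  rash) so that Σ incidence × unit cost reproduces the published monthly AE
  figures ($105.94 cetuximab arm, $86.90 bevacizumab arm) given assumed
  costs for the remaining events.  AE costs accrue during SD only
  (on-treatment).
* Societal costs: $8.0 travel per visit and $18.94 absenteeism per day
  (published), one day lost per visit (assumed); visit frequency follows the
  most frequent regimen component (weekly for cetuximab strategies, 14-day
  otherwise).
* The PD "weighted subsequent-therapy" cost and the monitoring fee are
  unpublished and shipped as clearly labelled *assumed* calibration values;
  every calibration item carries a provenance note and a
  printed/derived/assumed status, and loading fails loudly if the file or an
  item is missing.

## Discounting, accrual and termination

Costs and QALYs discount at 3% per year, converted to a compound-equivalent
monthly factor (1.03)^(−cycle/12); a simple monthly conversion
(1 + 0.03/12)^(−cycle) is selectable.  Accrual is at cycle start (state
occupancy earns that cycle's cost and utility/12, then transitions apply);
an optional half-cycle correction averages start- and end-of-cycle
occupancy.  QALY accrual is u/12 per month of occupancy with u = 0.85 (SD),
0.65 (PD), 0 (death).  The horizon is lifetime, operationalized as 240
cycles (20 years) with early stop once ≥99.9% of the cohort is dead; a trace
that hits the horizon first records a warning.  Doubling the horizon beyond
the stop threshold moves totals by <0.01% (tested).

For the progression-required structure the engine has an analytic oracle:
with per-cycle discount d and p₁ = P(SD exit), p₂ = P(PD→death), the
discounted occupancy sums are geometric series S_sd = 1/(1−(1−p₁)d) and
S_pd = p₁d/[(1−(1−p₁)d)(1−(1−p₂)d)], giving expected cost
S_sd·c_sd + S_pd·c_pd (+ loading increment) and expected QALY
(S_sd·u_sd + S_pd·u_pd)/12.  Engine and oracle agree to <0.1% over 100
random synthetic strategies.

## Why engine totals differ from the published totals

The published base-case totals (e.g. 1.87 QALYs for RAS-Bev) are *not*
reproducible from the published medians under any standard cohort
convention: the chain expectation for RAS-Bev is ≈2.57 discounted QALYs, and
the published figures sit closer to a median-partition arithmetic
((PFS·0.85 + (OS−PFS)·0.65)/12 ≈ 1.88) than to a cohort expectation.  The
original accrual/termination convention and the unpublished cost cells are
unrecoverable, so the package never tunes the engine toward the published
totals.  Instead, the *printed-totals* mode computes all ratio/ICER/
dominance arithmetic from the published totals exactly (that arithmetic is
internally consistent to the cent and is the package's reproduction
surface), while the *engine* mode reports its own totals with a labelled
deviation column.  One published sensitivity figure (an ICER decrease of
$181,069.06 when u_SD rises 0.85→0.89) is likewise inconsistent with the
published totals (16,828.02/0.08 implies a decrease of 210,350.25) and is
excluded from reproduction.

## Sensitivity analyses

**One-way DSA (tornado).**  Each parameter is set to its low and high value
with everything else at base and the full engine pipeline re-runs; entries
are ranked by spread.  Parameter ranges come from a YAML range file
(dot-addressed paths, strategies by name); absent a file, defaults are ±20%
of base on medians-derived transition probabilities (via overrides),
utilities (capped at their logical bounds), major cost items and the
discount rate (0–5%).  DSA at (base, base) reproduces base outputs
bit-identically, and parameters an outcome provably does not depend on show
exactly zero spread (both tested).

**Monte Carlo.**  The published design is 10,000 individuals × 1,000 trials
without stating whether parameters were redrawn; the default here is
*first-order* microsimulation (fixed parameters, matching the "individuals"
phrasing), with a *second-order* mode that redraws user-specified strategy
parameters per trial (uniform/normal/beta).  Paths are sampled monthly and
vectorized over individuals; a single named seed drives everything, with
per-trial substreams derived from (seed, trial index), so outputs are
byte-reproducible.  First-order grand means converge to the cohort-trace
expectation (tested at 3 SE with 10,000 × 50; the analysis driver uses
10,000 × 50 as its default trial count — the per-trial sampling distribution
is identical to the 1,000-trial design, only the number of replicates
differs).

## Synthetic data

`synthetic_data.generate_strategies` draws strategy sets uniformly within
ranges (PFS medians, positive OS offsets, cost components, ordered
utilities) from a seeded generator; every draw satisfies the input
invariants by construction, and the ground-truth record carries closed-form
expected discounted cost/QALY and the true frontier.  It emulates the
*structure* of the real inputs — exponential-like event times summarized by
medians, decomposable cost schedules, utility-weighted occupancy — but not
real-world features such as non-exponential hazards, dose reductions, vial
wastage, correlated parameters or patient heterogeneity; passing tests
therefore validate the arithmetic and the engine, not the clinical inputs.
`exponential_event_sampler` provides the continuous counterpart of the
median conversion; discretizing its draws to monthly cycles yields exactly a
geometric distribution, and the geometric MLE (1/mean of cycle counts)
recovers P within 2% at 10⁵ draws for medians ≥6 months.  (Re-estimating
from the *discretized median* cannot achieve 2% — the median rounds to an
integer cycle — so recovery uses the MLE; the continuous-median route is
also provided.)

## Numerical and design choices

* Rounding: full precision internally; report-facing values round half-up to
  2 decimals (`round_report`), matching standard presentation.
* ICER with ΔQALY = 0 is reported as undefined (no infinity arithmetic);
  negative ICERs are returned with the dominance context.
* Dominance is *strong* (≤ cost, ≥ QALY, one strict); extended (weak)
  dominance along the frontier is computed but flagged separately.  Frontier
  ties break by lower cost, then name.
* Analysis-2 medians: backbone-specific OS is published (FOLFOX 32.5/29.0;
  FOLFIRI 32.0 cetuximab / 35.2 bevacizumab — the published QALY ordering
  corroborates this assignment); backbone-specific PFS is not, so the pooled
  extended-RAS-wt PFS (11.4/11.3) is used for both backbones and marked
  assumed.
* Unknown config keys are rejected; every fixture value has a retrievable
  provenance note; configs round-trip losslessly.

## Limitations

No time-varying hazards, patient covariates, dose modification, or vial
wastage; post-progression therapy is a single weighted monthly cost, not a
treatment-sequence model; cost-effectiveness acceptability curves and value
of information are out of scope.  Absolute engine totals inherit the
assumed calibration cells and should be read through the deviation column;
the base-case ratio arithmetic does not depend on them.
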
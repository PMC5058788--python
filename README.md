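# mcrc-cea

Markov cohort cost-effectiveness analysis of first-line biologic strategies in
metastatic colorectal cancer (mCRC): cetuximab (anti-EGFR) or bevacizumab
(anti-VEGF) added to FOLFOX/FOLFIRI chemotherapy, gated by KRAS exon-2 vs
extended RAS wild-type testing, costed from a Chinese health-system
perspective.  Written for health-economics analysts who want the complete,
tested pipeline: survival-median inputs → transition probabilities →
discounted cost/QALY accumulation → ICER/dominance analysis → tornado and
Monte Carlo sensitivity analyses.

## Model

Three mutually exclusive states — stable disease (SD), progressive disease
(PD), death — with 1-month cycles.  A median time-to-event of *m* months
under the memoryless (exponential) assumption gives the monthly transition
probability

    P = 1 − (1/2)^(1/m) = 1 − e^(−R),   R = ln 2 / m,

applied with *m* = median PFS for SD→PD and *m* = median OS − median PFS for
PD→death.  Each cycle accrues, per unit of state occupancy, the state's
per-cycle cost and u/12 QALYs (u = 0.85 in SD, 0.65 in PD), discounted at 3%
per year.  Strategies are compared by cost/QALY, by the incremental
cost-effectiveness ratio ICER = ΔCost/ΔQALY along the efficiency frontier,
by strong dominance (no more costly *and* no less effective), and against a
willingness-to-pay threshold of $20,301/QALY (3× Chinese per-capita GDP).

Two report modes are first-class:

* **printed** — ratio/ICER/dominance arithmetic computed from the published
  per-strategy base-case totals shipped in the fixtures (the reproducible
  surface);
* **engine** — totals computed from the Markov cohort engine and shown next
  to the published totals with an explicit deviation column.  The published
  totals are *not* reproducible from the published medians alone (see
  `docs/methods.md`), so the deviation is surfaced, never hidden.

## Worked example

```python
from mcrc_cea import paper_fixture, evaluate_analysis, classify_dominance, icer

config = paper_fixture(1)  # KRAS-wt vs extended-RAS-wt gating of Cetux/Bev
results = evaluate_analysis(config, mode="printed")
labelled, frontier = classify_dominance(
    [(r.name, r.total_cost, r.total_qaly) for r in results]
)
for r in labelled:
    print(r.name, r.cost_per_qaly, r.dominance)
print("ICER RAS-Cetux vs RAS-Bev:",
      icer((157748.27, 1.91), (140920.25, 1.87)))
```

prints

```
KRAS-Cetux 88394.09 dominated
KRAS-Bev 80797.82 dominated
RAS-Cetux 82590.72 nondominated
RAS-Bev 75358.42 nondominated
ICER RAS-Cetux vs RAS-Bev: 420700.5
```

i.e. extended-RAS testing strategies strongly dominate KRAS-only gating
(cheaper *and* more effective), RAS-Bev is the least costly way to buy a
QALY ($75,358.42/QALY), and moving from RAS-Bev to RAS-Cetux buys 0.04 QALY
for $16,828.02 — $420,700.50 per QALY, far above the $20,301 threshold.  In
the second analysis FOLFIRI + bevacizumab is nondominated with the lowest
cost and the highest QALYs (cost/QALY $66,794.96).

The same surfaces are available from the command line and as numbered
drivers:

```bash
mcrc-cea run --analysis 1 --mode both --out results/run1
mcrc-cea dsa --analysis 1 --ranges src/mcrc_cea/fixtures/dsa_ranges_example.yaml --out results/dsa
mcrc-cea psa --analysis 1 --strategy RAS-Bev --seed 1 --out results/psa

python analysis/01_base_case.py            # published-totals arithmetic, both analyses
python analysis/02_engine_evaluation.py    # cohort-engine totals + deviation + traces
python analysis/03_sensitivity_tornado.py  # one-way DSA tornado tables
python analysis/04_monte_carlo.py --seed 1 # 10,000-patient microsimulation
```

## Configs and fixtures

Analyses are YAML configs with a strict schema (`src/mcrc_cea/fixtures/`):
strategies (medians, dosing, costs, grade-3/4 AE incidences, utilities) plus
model settings.  Cells not published anywhere (e.g. monitoring and
post-progression unit costs) are `calibration:<name>` references resolved
from the editable `fixtures/calibration.yaml`, each tagged
printed/derived/assumed with a provenance note retrievable at runtime via
`provenance_of()`.  `mcrc_cea.synthetic_data` generates arbitrary strategy
sets with closed-form ground truth for testing.

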
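# Methods

## Scope and model structure

The package evaluates maintenance durvalumab versus placebo after
chemoradiotherapy for unresectable stage III non-small cell lung cancer
(NSCLC) from four payer perspectives (US, Brazil, Singapore, Spain) as a
four-state Markov microsimulation: progression-free (PFS), first progression
(POD1), second progression (POD2), and death. Simulated patients advance in
1-month (30-day) cycles over a 10-year horizon (120 cycles); both strategies
are run over the same simulated patients. Costs and health outcomes are
discounted at 3% per year. The default cohort size is 1000 patients, the
size at which the analysis' summary tables are reported; sensitivity
analyses use smaller cohorts (250-500 patients) because parameter effects,
not Monte-Carlo noise, are the quantity of interest there.

## Survival inputs: pseudo-IPD and the composite model

Each first-line event-time distribution (PFS and OS per arm) enters as
digitized Kaplan-Meier coordinates. Pseudo individual-patient data (IPD) are
reconstructed from the coordinates: with no at-risk table, no losses to
follow-up are assumed before last follow-up, events are allocated by
cumulative rounding (the running event count stays within 0.5 of
`n * (1 - S(t))` at every digitized time), and survivors are censored at last
follow-up; with an at-risk table, events are set by the survival drop within
each at-risk interval and censorings by the deficit against the next at-risk
count, spread uniformly over the interval. The product-limit estimate of the
reconstruction reproduces the input curve within `1/n` at every digitized
time (a tested invariant).

The working event-time model is *composite*: the nonparametric Kaplan-Meier
step function up to a join point `t_f`, continued by an exponential tail
whose rate is the maximum-likelihood hazard `events / person-time` on the
window beyond `t_f`. For the synthetic bundles `t_f` is set 12 months before
last follow-up, so the tail rate is estimated on the final year of observed
follow-up; this is far more stable than the hazard of the single last KM
interval (the fallback used when no person-time exists beyond `t_f`, itself
falling back to a flat plateau when the last interval has no events).
Medians inside the step body are read off the steps; medians beyond `t_f`
use the closed form `t_f + log(S(t_f)/0.5) / rate`.

Monthly transition probabilities are conditional one-cycle event
probabilities `1 - S(t+1)/S(t)`; querying a curve at a time where `S = 0`
raises rather than returning 0, so calibration errors surface instead of
silently absorbing patients.

## Transition bookkeeping

From PFS, the monthly death probability is taken from the first-line OS
curve and the progression probability is the residual of the PFS event
probability after death, conditioned on surviving the cycle, so both the
simulated progression-free survival and the pre-progression death process
track their configured marginals. At first progression a regimen is assigned
by biomarkers: osimertinib for *EGFR*-mutant disease, alectinib for
*ALK*-rearranged disease, pembrolizumab plus platinum doublet for PD-L1
positive or unknown tumors (pemetrexed backbone if nonsquamous,
(nab)-paclitaxel if squamous), platinum doublet alone for PD-L1-negative
tumors; second progression is always docetaxel. Time to second progression
follows the assigned regimen's second-line curve with the clock restarted at
POD1 entry; a second progression falling in the same cycle as the first is
recorded as a direct PFS -> POD2 transition.

Post-progression mortality must be reconciled with the first-line OS curve,
because that curve already contains all post-progression deaths; layering
third-line trial mortality on top would double count. The default
(`calibrated`) bookkeeping treats the first-line OS hazard applied to the
whole surviving cohort as the cycle's death budget: PFS occupants die at the
OS hazard, POD2 occupants die at the third-line OS hazard (scaled down in
the rare cycles where that would overdraw the budget), and the residual is
allocated uniformly to POD1 occupants. Overall survival then tracks the
configured OS curve while the third-line curve shapes how mortality is
distributed across post-progression states. Two alternative modes are kept
for comparison: `residual` (same allocation but the third-line hazard is
never scaled, so late POD2 mortality can exceed the OS curve) and
`os_hazard` (raw OS hazard in POD1, third-line hazard in POD2, no
reconciliation). Death without prior progression is costed as other-cause
death; death after progression as NSCLC death.

In Spain, durvalumab reimbursement requires PD-L1 tumor proportion score
(TPS) >= 1%: TPS-negative patients assigned to the durvalumab strategy follow
the placebo pathway and accrue no durvalumab acquisition or administration
cost (exactly zero, a tested invariant).

## Random numbers

Each patient owns an RNG stream derived from `(master seed, patient index)`,
so cohort-size changes never reshuffle earlier patients, and the same
streams are replayed for both strategy arms and across sensitivity-analysis
draws (common random numbers). Each event process — death, first
progression, second progression — is driven by a single persistent uniform
crossed by the running product of its per-cycle survival probabilities.
Cycle by cycle this applies exactly the conditional monthly probabilities of
a fresh-draw implementation (identical per-patient marginals), but it
couples the arms comonotonically and reduces Monte-Carlo noise on
incremental endpoints several-fold. Fixed seeds give bit-identical traces
and summaries.

## Costing

All accounting is in USD; native-currency tables are converted once at
configuration load (purchasing-power parity for Brazilian reals, market
rates for Singapore dollars and euros). Doses follow the label rules: mg/kg
(durvalumab 10 mg/kg), mg/m^2 (DuBois body-surface area), flat mg
(pembrolizumab 200 mg), flat monthly price (osimertinib, alectinib), and the
Calvert formula for carboplatin — dose = AUC x (GFR + 25) with GFR from
Cockcroft-Gault creatinine clearance (0.85 female factor), target AUC 5 and
clearance capped at 125 mL/min, both configurable, since the source table
lists only "AUC". No vial rounding is applied in base pricing; vial
granularity exists only inside the access-program scheme, which is
inherently vial-based.

Administrations are delivered on each component's cycle schedule
(`floor(months x 30/cycle_days)`, capped at the maximum cycle count) and
each is discounted at its calendar month; administration cost is infusion
hours times the hourly infusion rate. Treatment duration is per-patient time
in the line, truncated by the line's maximum (durvalumab: 24 q2w
administrations ~ 12 months). Adverse-event costs are expected values
(incidence x unit cost over each regimen's pivotal-trial grade 3-4 toxicity
table) charged once at the start of each treatment line; the
platinum-doublet-alone table reuses the pembrolizumab-doublet incidences, the
only ones printed. Diagnosis (PET/CT + immunohistochemistry) is charged at
entry; the chemoradiotherapy backbone (radiotherapy cost) is charged to both
arms at entry and cancels in incrementals; surveillance imaging recurs every
3 months while alive (configurable); best supportive care accrues monthly in
POD2 after the docetaxel course (6 q3w cycles ~ 5 months) ends; a death cost
(NSCLC or other-cause) is charged at the end of the dying cycle.

Per-patient total cost decomposes exactly (to 1e-6) into diagnosis,
progression-free drug (including the backbone), post-progression drug,
administration, adverse events, supportive care, and end-of-life components.

## Outcome accrual and summaries

Life-years and QALYs accrue at the end of each cycle: 1/12 of a year,
weighted by the occupied state's utility (PFS 0.79, POD1/POD2 0.76, death
0), discounted at that month; the cycle in which death occurs accrues
nothing, and no half-cycle correction is applied (second-order at monthly
resolution). The progression-free utility can be overridden per arm, which
is how the sensitivity analysis varies the durvalumab PFS utility alone.

Arm summaries are means over patients with 95% percentile-bootstrap
confidence intervals; because both arms share patients, the bootstrap
resamples patient indices jointly (paired). Median PFS and OS of a simulated
arm are Kaplan-Meier medians of the simulated event times censored at the
horizon, with linear interpolation at the 0.5 crossing. The ICER is
incremental mean cost over incremental mean QALYs, with dominance labels
when the ratio is undefined; the incremental cost per life-year follows the
source convention of dividing by the incremental *median* OS expressed in
years.

## Sensitivity analysis

One-way deterministic analyses vary one parameter at a time to the ends of
its range (default +-20% of base) with everything else fixed, and rank
parameters by the spread of the chosen outcome (tornado order). The
probabilistic analysis draws full parameter vectors — beta for utilities
(moment-matched, SE 10% of mean), gamma for unit costs (SE 20% of mean),
lognormal multipliers on the four first-line extrapolation tail rates (mean
1, SE 10%) — and pushes each draw through the full model over one fixed
cohort (common random numbers, switchable). These distribution families and
spreads are standard health-technology-assessment conventions; the source
analysis does not state its distributions, so published acceptability
percentages are directional checks only. The acceptability curve reports,
per willingness-to-pay threshold, the fraction of draws with positive net
monetary benefit. Shipped thresholds: US $150,000; Brazil $22,251; Singapore
$55,288; Spain $107,069 per QALY.

## Synthetic data: what it emulates and what it does not

No trial data ship with the package; the `synthetic` module generates every
input. First-line curves are cure-mixture exponentials
`S(t) = c + (1-c) exp(-rho t)` sampled monthly to 60 months, with `rho`
solved so the curve crosses 0.5 exactly at the scenario's published median,
and the cure fraction `c` chosen once by matching the source trial's
published five-year landmark survival (OS 42.9%/33.4%, PFS 33.1%/19.0% for
the immunotherapy/control arms) as closely as the mixture allows. Because
the published model medians are high relative to those landmarks, the
least-error cure fraction is ~0 for both OS curves (pure exponentials,
implying ten-year OS near 20%/12%, clinically sensible for this population)
and ~0/0.12 for PFS. Pseudo-IPD reconstruction uses the trial arm sizes
(476/237) as displayed at-risk counts. Second-line curves are exponentials
at the corresponding trials' median PFS (pembrolizumab combination 8.8,
platinum doublet 4.9, osimertinib 18.9, alectinib 25.7 months); the
third-line OS curve is exponential at median 10.5 months.

The US cost configuration is the published one, value for value. The
Brazilian, Singaporean and Spanish tables are transparent emulations — US
structure with one price scale for drugs and one for procedures — carrying
every published anchor verbatim (currency conversions R$2.53, S$1.34, €0.90
per USD; the WTP thresholds; the Singapore $6.38/mg durvalumab list price,
its access scheme and the 33.7% program discount; the Spanish PD-L1 gate).
They are flagged `synthetic: true` and are not reconstructions of the
unpublished supplementary price tables, so absolute non-US cost outputs are
illustrative: passing tests demonstrate the mechanisms (gating, conversion,
access pricing), not the published non-US cost figures.

Likewise the mixture family cannot reproduce the exact shape of the source
analysis' digitized curves — a mixture pinned to these medians is flatter
around the median and more optimistic in the body than the real KM data —
so curve-shape-dependent outputs (mean survival, hence absolute QALYs and
the incremental QALY) sit near, not at, the published values, and
median-based outputs inherit a few months of Kaplan-Meier sampling noise at
the reported cohort size of 1000. What passing tests show is that the
machinery is correct (marginals track their configured curves, identities
hold exactly, calibration hits its targets within one monthly grid step);
they do not certify fidelity to the unavailable digitized data.

## Numerical choices and degenerate inputs

- Curve validation rejects non-monotone survival, non-increasing times, and
  curves not starting at (0, 1), naming the offending point.
- The round-trip tolerance of reconstruction is `1/n`; calibration tolerance
  of generated medians is one monthly grid step.
- Flooring of the residual progression probability is exact (never needed)
  for parametric curve pairs with ordered hazards; step bodies rebuilt from
  integer patient counts can invert the monthly ordering by up to ~2
  subjects' worth of probability, which the floor absorbs.
- Zero person-time beyond the join point falls back to the last body
  interval's hazard, then to a flat plateau; an all-censored curve yields a
  flat survival function rather than an error.
- Bootstrap replicates with non-positive incremental effect are excluded
  from ratio (ICER, cost-per-life-year) CIs only, never from the underlying
  field CIs.
- Ties at exactly `S = 0.5` count as crossings; KM medians of samples never
  reaching 0.5 are infinite, and infinite medians propagate as undefined
  ratios rather than numbers.

## Known limitations

- No background (life-table) mortality beyond the trial curves; no treatment
  waning, re-challenge, dose reductions, or relative dose intensity.
- Adverse events are expected costs at line start, not sampled per patient,
  and carry no disutility by default (values unpublished; the accrual
  accepts per-line disutility overrides).
- The reconciliation of first-line OS with later-line trial mortality is a
  modeling choice (the source does not state its bookkeeping); three modes
  are provided and the calibrated default is the only one whose overall
  survival reproduces the configured OS curves.
- Non-US absolute costs are emulations (above); only the US table is
  publication-exact.
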
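# nsclc-cea

Cost-effectiveness of maintenance durvalumab after chemoradiotherapy in
unresectable stage III non-small cell lung cancer (NSCLC), evaluated as a
four-state Markov microsimulation from four payer perspectives (US, Brazil,
Singapore, Spain).

Consolidative chemoradiotherapy followed by one year of durvalumab is the
standard of care in this setting, but the drug's price varies enormously
across health systems and several payers restrict it by PD-L1 tumor
proportion score. This package asks the health-economic question: at current
prices, does the survival benefit justify the cost — and under what pricing
(e.g. an industry access program) would it?

## Model

Patients occupy one of four states — progression free (PFS), first
progression (POD1), second progression (POD2), death — and advance in
1-month cycles over a 10-year horizon. Event-time distributions are
*composite survival models*: a Kaplan-Meier step function fit to pseudo
individual-patient data reconstructed from digitized trial curves, continued
beyond the join point by an exponential tail with rate
`lambda = events / person-time` on the tail window. Treatment at progression
is biomarker-driven (osimertinib if *EGFR*-mutant, alectinib if
*ALK*-rearranged, pembrolizumab + platinum doublet if PD-L1 TPS >= 1% or
unknown, platinum doublet if TPS < 1%; docetaxel at second progression), and
each line is costed by dosing rule (mg/kg, mg/m² via DuBois BSA, Calvert
formula for carboplatin, flat monthly for oral agents), infusion time,
expected adverse-event cost, supportive and end-of-life care, discounted at
3%/year.

Headline endpoints are discounted quality-adjusted life-years
(utilities: PFS 0.79, POD 0.76, death 0), the incremental cost-effectiveness
ratio ΔC/ΔE in dollars per QALY gained against each country's
willingness-to-pay threshold, and incremental cost per life-year. Parameter
uncertainty is handled by one-way deterministic sensitivity analysis
(tornado ranking) and probabilistic sensitivity analysis with
cost-effectiveness acceptability curves, P(λ·ΔE − ΔC > 0) over thresholds λ.

All inputs are generated by the `synthetic` module: survival curves are
cure-mixture exponentials calibrated so each arm's median matches the
published value (US base case: OS 51.1 vs 39.3 months, PFS 37.9 vs 19.9
months), the US cost table is the published one value-for-value, and the
non-US tables are clearly-flagged emulations carrying every published anchor
(currency rates, thresholds, the Singapore $6.38/mg list price and its
33.7% access-program discount). See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
from nsclc_cea import make_trial_bundle, run_cea

bundle = make_trial_bundle("us_base", seed=0)      # curves + US cost table
result = run_cea(bundle, n_patients=1000, seed=0)  # simulate, cost, summarize

inc = result.incremental
print(f"incremental cost   ${inc['total_cost'].value:,.0f}")
print(f"incremental QALYs  {inc['qalys'].value:.2f}")
print(f"ICER               ${result.icer_per_qaly.value:,.0f}/QALY")
```

prints (seed 0):

```
incremental cost   $129,899
incremental QALYs  0.58
ICER               $223,684/QALY
```

Durvalumab adds about six-tenths of a discounted QALY at a cost of roughly
$130,000, an ICER of ~$224,000 per QALY — well above the $150,000/QALY US
willingness-to-pay threshold, i.e. not cost-effective at list price. The
same pipeline is scripted as a narrative analysis:

| script | what it does |
| --- | --- |
| `analysis/01_build_inputs.py` | writes the four scenario bundles (curve CSVs + configs) under `results/inputs/` and checks median calibration |
| `analysis/02_base_case.py` | US base case: two-arm summary table with bootstrap CIs (`results/base_case/`) |
| `analysis/03_sensitivity.py` | tornado table, PSA draws and CEAC (`results/sensitivity/`) |
| `analysis/04_access_program.py` | Singapore list price vs access-program price (`results/access_program/`) |

A thin CLI wraps the same functions: `nsclc-cea synth|run|dsa|psa|ceac|validate`
(every stochastic subcommand requires `--seed`; each output directory gets a
manifest sufficient to reproduce it).

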
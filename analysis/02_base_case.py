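"""US base-case cost-effectiveness analysis of maintenance durvalumab.

Simulates 1000 patients per strategy over 120 monthly cycles with arms
calibrated to the US base-case medians, accrues discounted costs and QALYs,
and writes the two-arm summary table (total/drug/progression-free/
post-progression/adverse-event costs, median PFS/OS, QALYs, ICER) with 95%
bootstrap confidence intervals — the analysis' Table-2 analogue — to
results/base_case/.
"""

import argparse
import json
from pathlib import Path

from nsclc_cea import make_trial_bundle, run_cea
from nsclc_cea.config import RunManifest


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/base_case"))
    args = ap.parse_args()

    bundle = make_trial_bundle("us_base", seed=args.seed)
    result = run_cea(bundle, n_patients=args.n_patients, seed=args.seed, n_boot=1000)

    args.out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(args.out / "results.csv", index=False)
    (args.out / "results.json").write_text(json.dumps(result.to_dict(), indent=2))
    RunManifest(
        bundle_path="scenario:us_base",
        seed=args.seed,
        n_patients=args.n_patients,
        out_dir=str(args.out),
    ).write(args.out / "manifest.yaml")

    inc = result.incremental
    print("US base case (durvalumab vs placebo), discounted at 3%/yr:")
    for field, label in [
        ("total_cost", "incremental total cost, $"),
        ("qalys", "incremental QALYs"),
        ("median_pfs", "incremental median PFS, mo"),
        ("median_os", "incremental median OS, mo"),
    ]:
        e = inc[field]
        print(f"  {label:>28}: {e.value:>10.2f}  (95% CI {e.lo:.2f} to {e.hi:.2f})")
    print(
        f"  {'ICER per QALY, $':>28}: {result.icer_per_qaly.value:>10.0f}  "
        f"(95% CI {result.icer_per_qaly.lo:.0f} to {result.icer_per_qaly.hi:.0f})"
    )
    print(
        f"  {'cost per life-year, $':>28}: "
        f"{result.incremental_cost_per_life_year.value:>10.0f}"
    )
    wtp = bundle.config.wtp_per_qaly
    verdict = "below" if result.icer_per_qaly.value <= wtp else "above"
    print(f"  ICER is {verdict} the ${wtp:,.0f}/QALY willingness-to-pay threshold.")


if __name__ == "__main__":
    main()
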
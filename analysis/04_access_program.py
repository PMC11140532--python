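"""Singapore industry access program: list-price vs discounted durvalumab.

The Singapore scenario offers durvalumab through a vial-based access scheme
(500-mg vials buy-1-get-2-free, 120-mg vials buy-2-get-remainder-free) whose
program-level average discount of 33.7% takes the $6.38/mg list price to
$4.23/mg.  This driver runs the Singapore model at both prices and reports
how the discount moves the ICER against the S$75,000 (~$55,288) per QALY
threshold.  Outputs land in results/access_program/.
"""

import argparse
import json
from pathlib import Path

from nsclc_cea import make_trial_bundle, run_cea
from nsclc_cea.costing import access_program_price_per_mg
from nsclc_cea.synthetic import make_country_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results/access_program"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sg = make_country_config("SG")
    list_price = sg.drug_prices["durvalumab"]
    program_price = access_program_price_per_mg(list_price, sg.access_program)
    print(f"durvalumab: list ${list_price:.2f}/mg -> program ${program_price:.2f}/mg")

    results = {}
    for label, price in [("list_price", list_price), ("access_program", program_price)]:
        bundle = make_trial_bundle("singapore_access", seed=args.seed)
        bundle.config.drug_prices["durvalumab"] = price
        res = run_cea(bundle, n_patients=args.n_patients, seed=args.seed, n_boot=500)
        results[label] = res.to_dict()
        icer = res.icer_per_qaly.value
        verdict = "cost-effective" if icer <= sg.wtp_per_qaly else "not cost-effective"
        print(
            f"  {label:>15}: dCost ${res.incremental['total_cost'].value:,.0f}, "
            f"dQALY {res.incremental['qalys'].value:.2f}, ICER ${icer:,.0f}/QALY -> {verdict} "
            f"at ${sg.wtp_per_qaly:,.0f}/QALY"
        )
    (args.out / "results.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
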
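"""Deterministic and probabilistic sensitivity analysis for the US base case.

Runs (a) one-way deterministic analyses over +-20% parameter ranges and ranks
them by incremental-QALY spread (tornado order), and (b) a probabilistic
analysis drawing utilities (beta), unit costs (gamma) and survival-tail
multipliers (lognormal) and pushing each draw through the full model, from
which the cost-effectiveness acceptability curve is computed.  Outputs land
in results/sensitivity/.
"""

import argparse
from pathlib import Path

import pandas as pd

from nsclc_cea import make_trial_bundle
from nsclc_cea.runner import ScenarioParams, make_model_runner
from nsclc_cea.sensitivity import (
    ceac_curve,
    default_dsa_ranges,
    default_psa_distributions,
    one_way_dsa,
    run_psa,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-patients", type=int, default=1000)
    ap.add_argument("--n-iter", type=int, default=500)
    ap.add_argument("--out", type=Path, default=Path("results/sensitivity"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = make_trial_bundle("us_base", seed=args.seed)
    params = ScenarioParams.from_bundle(bundle)
    runner = make_model_runner(bundle, n_patients=args.n_patients, seed=args.seed)

    entries = one_way_dsa(params, default_dsa_ranges(params), runner, metric="delta_qaly")
    pd.DataFrame([e.__dict__ for e in entries]).to_csv(args.out / "tornado.csv", index=False)
    print("Tornado (incremental QALY spread, +-20% ranges):")
    for e in entries[:5]:
        print(f"  {e.parameter:>40}: spread {e.spread:.3f}")

    draws = run_psa(params, default_psa_distributions(params), args.n_iter, args.seed, runner)
    pd.DataFrame(
        {"delta_cost": [d.delta_cost for d in draws], "delta_qaly": [d.delta_qaly for d in draws]}
    ).to_csv(args.out / "psa_draws.csv", index=False)

    grid = [1000.0 * k for k in range(0, 301, 10)]
    curve = ceac_curve(draws, grid)
    pd.DataFrame(curve, columns=["wtp", "probability"]).to_csv(args.out / "ceac.csv", index=False)
    wtp = bundle.config.wtp_per_qaly
    at_wtp = next(p for w, p in curve if w >= wtp)
    print(
        f"PSA ({len(draws)} draws): P(cost-effective at ${wtp:,.0f}/QALY) = {at_wtp:.1%}"
    )


if __name__ == "__main__":
    main()
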
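#!/usr/bin/env python
"""Depth effect on survival at a sample size where it is estimable: fit the
logistic model on a 200-tag synthetic cohort generated with a known depth
effect (odds of survival x5 per 100 m shallower) and check the fitted odds
ratio and its confidence interval recover it.  Writes glm_recovery.csv."""

import argparse
from pathlib import Path

import pandas as pd

from skatesurv.survival import fit_survival_glm
from skatesurv.synthetic_tags import simulate_survival_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n", type=int, default=200)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = simulate_survival_table(args.n, seed=args.seed)
    res = fit_survival_glm(table)
    out = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.values,
            "se": res.bse.values,
            "p": res.pvalues.values,
        }
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.outdir / "glm_recovery.csv", index=False)

    print(f"{args.n} simulated tags, designed OR 5.0 per 100 m shallower")
    print(
        f"fitted OR per 100 m shallower: {res.or_per_100m_shallower:.2f} "
        f"(95% CI {res.or_ci[0]:.2f}-{res.or_ci[1]:.2f})"
    )
    print(
        "depth Wald p-value: "
        f"{res.pvalues['capture_depth_m']:.2g}; separation flag: "
        f"{res.separation_flag}"
    )


if __name__ == "__main__":
    main()
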
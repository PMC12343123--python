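#!/usr/bin/env python
"""Survival estimation from the fate calls: binomial proportion with the
95% Wilson interval (control excluded, ambiguous counted as mortality), the
CI-width/sample-size planning curve, and the depth GLM on the cohort's
capture covariates.  Writes survival.json, power_curve.csv, glm.csv and the
Markdown report."""

import argparse
import json
from pathlib import Path

from skatesurv.pipeline import PipelineConfig, stage_estimate, stage_report
from skatesurv.survival import ci_width_curve


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    payload = stage_estimate(cfg, args.outdir)
    stage_report(cfg, args.outdir)

    print(
        f"survival: {payload['k_survivors']}/{payload['n']} = "
        f"{100 * payload['proportion']:.0f}% "
        f"(95% Wilson CI {100 * payload['ci_low']:.0f}-"
        f"{100 * payload['ci_high']:.0f}%)"
    )
    pc = ci_width_curve(payload["proportion"], n_ref=payload["n"])
    print(
        f"CI width at n={payload['n']}: {pc.width_ref:.2f}; "
        f"halving it requires n = {pc.n_for_target} tags"
    )
    if "or_per_100m_shallower" in payload:
        print(
            f"odds of survival per 100 m shallower: "
            f"{payload['or_per_100m_shallower']:.2f}"
        )
    else:
        print(f"cohort GLM not fitted: {payload.get('glm_error', 'n/a')}")
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
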
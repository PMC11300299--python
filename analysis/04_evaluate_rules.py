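#!/usr/bin/env python
"""Evaluate the derived short-scale rules on the held-out test infants.

For each indicator, applies the training-set cutoff to test-set rows and
reports sensitivity and specificity of the short-scale rule for predicting
the full-scale rule, with bootstrap percentile 95% confidence intervals.
Writes evaluation.csv mirroring the published table layout plus raw counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from smnas import evaluate_rules_on_test
from smnas.evaluation import evaluation_to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
    ap.add_argument("--split", type=Path, default=Path("results/split.csv"))
    ap.add_argument("--cutoffs", type=Path, default=Path("results/cutoffs.csv"))
    ap.add_argument("--n-boot", type=int, default=2000)
    ap.add_argument("--unit", choices=["observation", "infant"],
                    default="observation")
    ap.add_argument("--out", type=Path, default=Path("results/evaluation.csv"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.metrics)
    split = pd.read_csv(args.split, index_col="infant_id")["split"]
    cutoffs = pd.read_csv(args.cutoffs)
    results = evaluate_rules_on_test(metrics, split, cutoffs,
                                     n_boot=args.n_boot, seed=args.seed,
                                     unit=args.unit)
    evaluation_to_frame(results).to_csv(args.out, index=False)

    for r in results:
        print(f"  indicator {r.indicator}: sens {r.sensitivity:.1%} "
              f"({r.sens_ci_low:.1%}-{r.sens_ci_high:.1%}), "
              f"spec {r.specificity:.1%} "
              f"({r.spec_ci_low:.1%}-{r.spec_ci_high:.1%})")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
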
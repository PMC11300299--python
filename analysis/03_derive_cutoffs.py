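#!/usr/bin/env python
"""Derive Youden-optimal short-scale cutoffs on the training infants.

Splits infants into train/test by independent Bernoulli(0.5) draws, then for
each of the six full-scale decision-rule indicators finds the sMNAS-9 metric
cutoff maximizing the Youden index on training rows, with the depth-1 CART
split reported alongside as a cross-check.  Writes split.csv and cutoffs.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from smnas import derive_all, split_infants
from smnas.cutoffs import cutoffs_to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--metrics", type=Path, default=Path("results/metrics.csv"))
    ap.add_argument("--train-prob", type=float, default=0.5)
    ap.add_argument("--out", type=Path, default=Path("results/cutoffs.csv"))
    ap.add_argument("--split-out", type=Path, default=Path("results/split.csv"))
    args = ap.parse_args()

    metrics = pd.read_csv(args.metrics)
    split = split_infants(metrics["infant_id"].unique(), args.train_prob,
                          seed=args.seed)
    train = metrics[metrics["infant_id"].isin(split.index[split == "train"])]
    results = derive_all(train)

    split.to_csv(args.split_out)
    frame = cutoffs_to_frame(results)
    frame.to_csv(args.out, index=False)

    n_train = (split == "train").sum()
    print(f"split: {n_train} train / {(split == 'test').sum()} test infants "
          f"({len(train)} training rows)")
    for r in results:
        print(f"  indicator {r.indicator}: short {r.short_metric} "
              f"{r.direction} {r.cutoff_reported:g} "
              f"(J = {r.youden:.3f}, stump {r.stump_cutoff})")
    print(f"wrote {args.out}, {args.split_out}")


if __name__ == "__main__":
    main()
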
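#!/usr/bin/env python
"""Replicate the whole study across seeded cohorts and tabulate rates.

Runs the complete 60 MHz workflow (simulate, process, bin, OPLS-DA,
quantify, day-5 Welch test) on many independently seeded cohorts and
reports how often each qualitative study finding reproduces: full
score-space separation of the treated group from day 3, the S-line sign
pattern (1.9 ppm up, 0.90-0.98 ppm down), sub-5% acetate recovery by GL
fitting, its advantage over region integration, and day-5 significance.
"""

import argparse
from pathlib import Path

from benchnmr.workflow import replicate_study


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-runs", type=int, default=50)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = replicate_study(args.n_runs, base_seed=args.seed)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "05_replicates.csv", index=False)

    n = len(df)
    print(f"{n} seeded cohorts (base seed {args.seed}):")
    print(f"  OPLS-DA separates treated days 3-5 with zero overlap: "
          f"{df.separated_day3on.sum()}/{n}")
    print(f"  S-line sign pattern (1.9 ppm +, 0.90-0.98 ppm -):      "
          f"{df.sline_signs_ok.sum()}/{n}")
    print(f"  median Q2 (days 2-5 model): {df.q2.median():.3f}")
    print(f"  GL acetate recovery MAPE: {df.mape_gl.mean():.2f}% "
          f"(region integration: {df.mape_region.mean():.2f}%)")
    print(f"  GL error < region error: {(df.mae_gl < df.mae_region).sum()}/{n}")
    print(f"  day-5 Welch p < 0.05 (one-sided): "
          f"{(df.welch_day5_p < 0.05).sum()}/{n}")


if __name__ == "__main__":
    main()
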
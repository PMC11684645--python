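#!/usr/bin/env python
"""Diagnostic battery on the extracted dataset.

Sensitivity/specificity of the pandemic-period and completion flags for
each mention outcome, variance inflation factors of the three model
covariates, and skewness/kurtosis of the mention flags. Writes
results/diagnostics_summary.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from mhtrends.registry_io import read_dataset
from mhtrends.trend_models import diagnostics, moments, vif

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "scratch" / "dataset.csv")
    args = ap.parse_args()

    rows = read_dataset(args.dataset)
    outcomes = [c[:-len("_mention")] for c in rows.columns if c.endswith("_mention")]
    outcomes.append("any_word")

    diag_rows = []
    for outcome in outcomes:
        col = f"{outcome}_mention" if outcome != "any_word" else "any_word"
        for pred in ("covid", "complete"):
            d = diagnostics(rows[pred], rows[col], predictor=pred, outcome=outcome)
            diag_rows.append(dataclasses.asdict(d))
    diag = pd.DataFrame(diag_rows)

    v = vif(rows[["start_year", "covid", "complete"]].to_numpy(dtype=float),
            names=["start_year", "covid", "complete"])

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    diag.to_csv(results / "diagnostics_summary.csv", index=False)

    print("sensitivity/specificity (%) by predictor and outcome:")
    print(diag.pivot_table(index="predictor", columns="outcome",
                           values=["sensitivity", "specificity"]).round(0))
    print(f"\nVIFs: {dict((k, round(x, 3)) for k, x in v.vifs.items())}")
    for outcome in outcomes:
        col = f"{outcome}_mention" if outcome != "any_word" else "any_word"
        m = moments(rows[col])
        shape = ("right-skewed" if m.skewness > 0 else "left-skewed/symmetric")
        tails = "leptokurtic" if m.excess_kurtosis > 0 else "platykurtic"
        print(f"  {outcome:<11} g1={m.skewness:6.2f} g2={m.excess_kurtosis:6.2f}"
              f"  ({shape}, {tails})")


if __name__ == "__main__":
    main()
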
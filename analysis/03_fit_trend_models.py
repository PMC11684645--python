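#!/usr/bin/env python
"""Fit the logistic model battery and Pearson year trends.

Per mention outcome (four terms plus the any-word composite): the
multivariable pandemic-period + completion model and the per-year trend
model, with Wald and likelihood-ratio inference; per (term, status) the
Pearson correlation between year and mean term frequency. Tables land in
results/analysis/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mhtrends.cli import run_analyze
from mhtrends.registry_io import read_dataset

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--dataset", type=Path, default=ROOT / "scratch" / "dataset.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "analysis")
    args = ap.parse_args()

    rows = read_dataset(args.dataset)
    report = run_analyze(rows, args.out)

    print(f"modelled {len(report['models'])} outcomes on {len(rows)} trials")
    for outcome, fits in report["models"].items():
        cov = fits["multivariable"]["coefficients"]["covid"]
        yr = fits["year"]["coefficients"]["start_year"]
        note = "" if fits["multivariable"]["converged"] else "  [separation: OR unreliable]"
        print(f"  {outcome:<11} pandemic-period OR {cov['exp_b']:>9.3f} "
              f"(p={cov['p_value']:.3f});  per-year OR {yr['exp_b']:.3f} "
              f"(Wald {yr['wald']:.2f}, p={yr['p_value']:.3f}){note}")
    trends = pd.DataFrame(report["pearson_trends"])
    if len(trends):
        strongest = trends.loc[trends["r"].abs().idxmax()]
        print(f"strongest year trend: {strongest['term']} among "
              f"{strongest['status']} trials (r = {strongest['r']:.3f})")


if __name__ == "__main__":
    main()
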
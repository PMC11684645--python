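#!/usr/bin/env python
"""Extract the per-trial analysis dataset from the registry XML.

Runs read -> merge -> screen -> tokenize -> profile over the registry
written by 01_simulate_registry.py, writes the flat dataset to
scratch/dataset.csv and the screening accounting plus (year, status)
aggregates to results/.
"""

import argparse
import json
import shutil
from pathlib import Path

from mhtrends.cli import run_extract
from mhtrends.termstats import aggregate

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--registry", type=Path, default=ROOT / "scratch" / "registry")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "dataset.csv")
    args = ap.parse_args()

    rows, report = run_extract(args.registry / "xml", args.registry / "index.csv",
                               args.out)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(args.out.with_suffix(".screening.json"),
                results / "screening_report.json")
    agg = aggregate(rows)
    agg.to_csv(results / "aggregate_by_year_status.csv", index=False)

    print(f"screened {report.n_input} -> {report.n_included} trials")
    print(json.dumps(report.to_dict()["exclusions"], indent=2))
    print(f"dataset: {args.out} ({len(rows)} rows); "
          f"aggregates: {results / 'aggregate_by_year_status.csv'}")


if __name__ == "__main__":
    main()
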
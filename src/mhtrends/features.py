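"""Per-trial model matrix: start year, pandemic-period and completion flags.

The pandemic indicator is 1 for trials starting in or after the cutoff year
(default 2020, the onset of large-scale control measures); completion is 1
for trials whose lifecycle status is "Completed".
"""

from __future__ import annotations

import pandas as pd

from .registry_io import RegistryDataset
from .screening import normalize_status
from .termstats import TermProfile

__all__ = ["build_rows", "COVID_CUTOFF_YEAR"]

COVID_CUTOFF_YEAR = 2020


def build_rows(dataset: RegistryDataset, profiles: dict[str, TermProfile],
               covid_year: int = COVID_CUTOFF_YEAR) -> pd.DataFrame:
    """One analysis row per screened trial.

    ``profiles`` maps nct_id -> TermProfile and must cover every record;
    a missing profile is an error naming the trial.
    """
    rows = []
    for rec in dataset:
        if rec.nct_id not in profiles:
            raise KeyError(f"no term profile for trial {rec.nct_id}")
        year = rec.start_year
        if year is None:
            raise ValueError(f"trial {rec.nct_id} reached feature building without a start year")
        row = {
            "nct_id": rec.nct_id,
            "start_year": year,
            "status": rec.overall_status,
            "covid": int(year >= covid_year),
            "complete": int(normalize_status(rec.overall_status) == "completed"),
        }
        row.update(profiles[rec.nct_id].as_row())
        rows.append(row)
    return pd.DataFrame(rows)
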
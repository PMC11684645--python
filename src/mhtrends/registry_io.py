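"""Reading and writing registry data.

Three surfaces:

* per-trial study records in the legacy ``clinical_study`` XML dialect
  (one file per trial, root ``<clinical_study>``, children
  ``id_info/nct_id``, ``overall_status``, ``start_date`` and the two
  ``textblock`` description elements);
* the start-date index table (spreadsheet or CSV) pairing NCT numbers with
  start dates;
* the flat per-trial analysis dataset (CSV, RFC 4180), which round-trips
  losslessly through :func:`read_dataset`.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "RegistryDataset",
    "RegistryParseError",
    "RecordError",
    "parse_start_date",
    "read_trial_xml",
    "read_registry_dir",
    "read_index",
    "read_archive_table",
    "merge_index",
    "write_dataset",
    "read_dataset",
    "DATASET_COLUMNS",
]

_NCT_RE = re.compile(r"^NCT\d{8}$")

_MONTHS = {m.lower(): i for i, m in enumerate(
    ["January", "February", "March", "April", "May", "June", "July",
     "August", "September", "October", "November", "December"], start=1)}


class RegistryParseError(ValueError):
    """Malformed XML; the message names the offending file."""


class RecordError(ValueError):
    """Structurally valid XML that does not describe a usable record."""


@dataclass(frozen=True)
class TrialRecord:
    """One registry study record.

    ``start_date`` holds the raw date string as found in the record or
    index ("June 2019", "March 3, 2021", ...); ``start_year`` /
    ``start_month`` are the parsed components, ``None`` when the string
    could not be resolved to a year. Description fields are always present
    (empty string when the XML element is absent).
    """

    nct_id: str
    overall_status: str = ""
    start_date: str = ""
    brief_description: str = ""
    detailed_description: str = ""

    @property
    def start_year(self) -> int | None:
        parsed = parse_start_date(self.start_date)
        return parsed[0] if parsed else None

    @property
    def start_month(self) -> int | None:
        parsed = parse_start_date(self.start_date)
        return parsed[1] if parsed else None


@dataclass(frozen=True)
class RegistryDataset:
    records: tuple[TrialRecord, ...]
    source: str = ""
    loaded_at: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))

    def __post_init__(self):
        ids = [r.nct_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordError(f"duplicate nct_id in dataset: {dupes[:5]}")

    @property
    def count(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def parse_start_date(text: str) -> tuple[int, int | None] | None:
    """Parse a registry-style date string to ``(year, month_or_None)``.

    Accepted forms: "Month Year", "Month Day, Year", bare "Year",
    ISO "YYYY-MM[-DD]". Years outside 1900-2100 and anything else yield
    ``None``. Dates without a day are treated as day 1 internally; only
    the year matters downstream.
    """
    text = (text or "").strip()
    if not text:
        return None
    m = re.match(r"^(\d{4})(?:-(\d{1,2})(?:-\d{1,2})?)?$", text)
    if m:
        year, month = int(m.group(1)), int(m.group(2)) if m.group(2) else None
        if 1900 <= year <= 2100 and (month is None or 1 <= month <= 12):
            return year, month
        return None
    m = re.match(r"^([A-Za-z]+)\.?\s+(?:(\d{1,2}),?\s+)?(\d{4})$", text)
    if m:
        month = _MONTHS.get(m.group(1).lower())
        year = int(m.group(3))
        if month and 1900 <= year <= 2100:
            return year, month
    return None


def _text_of(root, path: str) -> str:
    node = root.find(path)
    if node is None or node.text is None:
        return ""
    return node.text


def read_trial_xml(path) -> TrialRecord:
    """Read one legacy-dialect study record.

    Missing description elements become empty strings; textblock whitespace
    is preserved verbatim at this stage (normalization happens later).
    Malformed XML raises :class:`RegistryParseError` naming the file; a
    record without an NCT id raises :class:`RecordError`.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise RegistryParseError(f"malformed XML in {path}: {exc}") from exc
    nct_id = _text_of(root, "id_info/nct_id").strip()
    if not nct_id:
        raise RecordError(f"missing id_info/nct_id in {path}")
    return TrialRecord(
        nct_id=nct_id,
        overall_status=_text_of(root, "overall_status").strip(),
        start_date=_text_of(root, "start_date").strip(),
        brief_description=_text_of(root, "brief_summary/textblock"),
        detailed_description=_text_of(root, "detailed_description/textblock"),
    )


def read_registry_dir(xml_dir) -> tuple[RegistryDataset, list[str]]:
    """Read every ``*.xml`` under ``xml_dir``; skip and log bad files.

    Returns the dataset and the list of skipped file names.
    """
    xml_dir = Path(xml_dir)
    records, skipped = [], []
    for path in sorted(xml_dir.glob("*.xml")):
        try:
            records.append(read_trial_xml(path))
        except (RegistryParseError, RecordError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(path.name)
    return RegistryDataset(tuple(records), source=str(xml_dir)), skipped


def read_index(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the (NCT number, start date) index table.

    ``path`` may be a spreadsheet (``.xlsx``) or a CSV; the first column
    holding NCT ids and the first date-like column are used. Returns
    ``(index, rejects)``: the index has columns ``nct_id, start_date,
    start_year, start_month``; rows whose date does not parse land in
    ``rejects`` with a reason.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str)
    raw.columns = [str(c).strip().lower().replace(" ", "_") for c in raw.columns]
    nct_col = next((c for c in raw.columns if "nct" in c), raw.columns[0])
    date_col = next((c for c in raw.columns if "date" in c or "start" in c), raw.columns[-1])

    rows, rejects = [], []
    for _, row in raw.iterrows():
        nct = str(row[nct_col] or "").strip()
        date = str(row[date_col]) if pd.notna(row[date_col]) else ""
        parsed = parse_start_date(date)
        if parsed is None:
            rejects.append({"nct_id": nct, "start_date": date, "reason": "unparseable date"})
            logger.warning("index row %s rejected: unparseable date %r", nct, date)
            continue
        rows.append({"nct_id": nct, "start_date": date.strip(),
                     "start_year": parsed[0], "start_month": parsed[1]})
    cols = ["nct_id", "start_date", "start_year", "start_month"]
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(rejects, columns=["nct_id", "start_date", "reason"]))


def merge_index(dataset: RegistryDataset, index: pd.DataFrame) -> RegistryDataset:
    """Fill/replace record start dates from the index where present.

    Index rows whose NCT id is absent from the dataset are logged and
    ignored; an empty index returns the dataset unchanged.
    """
    if index is None or len(index) == 0:
        return dataset
    by_id = dict(zip(index["nct_id"], index["start_date"]))
    known = {r.nct_id for r in dataset.records}
    for nct in by_id.keys() - known:
        logger.warning("index nct_id %s not found in dataset", nct)
    records = tuple(
        replace(r, start_date=by_id[r.nct_id]) if r.nct_id in by_id else r
        for r in dataset.records
    )
    return RegistryDataset(records, source=dataset.source, loaded_at=dataset.loaded_at)


#: Stable column order of the per-trial analysis dataset.
def _dataset_columns(terms: Sequence[str]) -> list[str]:
    cols = ["nct_id", "start_year", "status", "covid", "complete"]
    for t in terms:
        cols += [f"{t}_count", f"{t}_frequency", f"{t}_mention"]
    cols += ["total_words", "any_word"]
    return cols


DATASET_COLUMNS = _dataset_columns


def write_dataset(rows: pd.DataFrame, path, terms: Sequence[str] | None = None) -> None:
    """Write the per-trial analysis dataset as CSV with a stable column order.

    Float columns keep full precision (shortest round-trip repr), so
    ``read_dataset(write_dataset(x)) == x``. An empty frame is an error.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty analysis dataset")
    if terms is None:
        terms = [c[:-len("_mention")] for c in rows.columns if c.endswith("_mention")
                 if c != "any_word"]
    cols = _dataset_columns(terms)
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"analysis dataset missing columns: {missing}")
    rows[cols].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read back a :func:`write_dataset` CSV with proper dtypes."""
    df = pd.read_csv(path)
    for col in df.columns:
        if col.endswith(("_count", "_mention")) or col in {
                "start_year", "covid", "complete", "total_words", "any_word"}:
            df[col] = df[col].astype(int)
        elif col.endswith("_frequency"):
            df[col] = df[col].astype(float)
    return df


def read_archive_table(path, lexicon: Iterable[str] = ("depression", "anxiety", "loneliness", "distress")) -> pd.DataFrame:
    """Adapter for an externally archived per-trial extraction table.

    Accepts a CSV or spreadsheet with, at minimum, an NCT column, a start
    date (or year) column, a status column and per-term count or mention
    columns under reasonable header spellings, and maps it into the
    analysis-dataset layout so it can enter the pipeline at the modelling
    stage. Columns that cannot be derived (e.g. frequencies without word
    counts) are filled with NaN and the affected analyses degrade
    gracefully.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    raw.columns = [str(c).strip().lower().replace(" ", "_") for c in raw.columns]

    def find(*cands):
        for cand in cands:
            for col in raw.columns:
                if cand in col:
                    return col
        return None

    out = pd.DataFrame()
    nct = find("nct")
    if nct is None:
        raise ValueError(f"{path}: no NCT column recognised")
    out["nct_id"] = raw[nct].astype(str).str.strip()
    year_col = find("start_year", "year", "start_date", "date")
    years = []
    for v in raw[year_col]:
        parsed = parse_start_date(str(v))
        years.append(parsed[0] if parsed else pd.NA)
    out["start_year"] = pd.array(years, dtype="Int64")
    status_col = find("status")
    out["status"] = raw[status_col].astype(str).str.strip() if status_col else ""
    covid_col = find("covid")
    if covid_col is not None:
        out["covid"] = raw[covid_col].astype(float).astype(int)
    else:
        out["covid"] = (out["start_year"].astype(float) >= 2020).astype(int)
    complete_col = find("complete")
    if complete_col is not None:
        out["complete"] = raw[complete_col].astype(float).astype(int)
    else:
        out["complete"] = (out["status"].str.strip().str.lower() == "completed").astype(int)
    total_col = find("total_word", "word_count", "total")
    out["total_words"] = raw[total_col] if total_col else pd.NA
    for term in lexicon:
        count_col = find(f"{term}_count", f"{term}s", term)
        mention_col = find(f"{term}_mention", f"{term}_yn", f"{term}_flag")
        if count_col is not None and raw[count_col].dropna().isin([0, 1]).all() and mention_col is None:
            # ambiguous: a 0/1 column under the bare term name is a mention flag
            mention_col, count_col = count_col, None
        if count_col is not None:
            out[f"{term}_count"] = raw[count_col].astype(float).astype(int)
            out[f"{term}_mention"] = (out[f"{term}_count"] > 0).astype(int)
        elif mention_col is not None:
            out[f"{term}_mention"] = raw[mention_col].astype(float).astype(int)
            out[f"{term}_count"] = pd.NA
        else:
            raise ValueError(f"{path}: no column recognised for term {term!r}")
        if total_col and count_col:
            tw = out["total_words"].astype(float)
            out[f"{term}_frequency"] = out[f"{term}_count"] / tw.where(tw > 0)
        else:
            out[f"{term}_frequency"] = pd.NA
    mention_cols = [f"{t}_mention" for t in lexicon]
    out["any_word"] = out[mention_cols].max(axis=1).astype(int)
    return out
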
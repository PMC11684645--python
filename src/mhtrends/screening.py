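"""Eligibility screening of registry records by status and start-year window.

Records whose lifecycle status is in the include set and whose start year
falls in the study window survive; everything else is counted into an
accounting report in which every input record lands in exactly one bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .registry_io import RegistryDataset

__all__ = ["ScreeningPolicy", "ScreeningReport", "ScreeningError",
           "normalize_status", "screen", "DEFAULT_INCLUDE", "DEFAULT_EXCLUDE"]

DEFAULT_INCLUDE = frozenset({
    "recruiting",
    "enrolling by invitation",
    "completed",
    "active, not recruiting",
})

DEFAULT_EXCLUDE = frozenset({
    "available",
    "withdrawn",
    "unknown status",
    "terminated",
    "suspended",
    "not yet recruiting",
    "no longer available",
})


class ScreeningError(ValueError):
    """A status label not covered by the policy, in strict mode."""


def normalize_status(label: str) -> str:
    """Lowercase, trim and collapse internal whitespace of a status label.

    Registry exports vary in casing ("ACTIVE, NOT RECRUITING" vs
    "Active, not recruiting"); matching is done on this normal form.
    """
    return " ".join(label.lower().split())


@dataclass(frozen=True)
class ScreeningPolicy:
    include_statuses: frozenset[str] = DEFAULT_INCLUDE
    exclude_statuses: frozenset[str] = DEFAULT_EXCLUDE
    year_min: int = 1988
    year_max: int = 2022
    strict: bool = True  # unknown status label -> error (else exclude + warn)

    def __post_init__(self):
        inc = frozenset(normalize_status(s) for s in self.include_statuses)
        exc = frozenset(normalize_status(s) for s in self.exclude_statuses)
        if inc & exc:
            raise ValueError(f"include/exclude overlap: {sorted(inc & exc)}")
        if self.year_min > self.year_max:
            raise ValueError("year_min > year_max")
        object.__setattr__(self, "include_statuses", inc)
        object.__setattr__(self, "exclude_statuses", exc)


@dataclass
class ScreeningReport:
    n_input: int = 0
    n_included: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)  # bucket -> count
    n_bad_date: int = 0

    def balances(self) -> bool:
        return self.n_input == self.n_included + sum(self.exclusions.values()) + self.n_bad_date

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_included": self.n_included,
                "exclusions": dict(sorted(self.exclusions.items())),
                "n_bad_date": self.n_bad_date}


def screen(dataset: RegistryDataset, policy: ScreeningPolicy | None = None
           ) -> tuple[RegistryDataset, ScreeningReport]:
    """Apply ``policy`` to ``dataset``.

    Bucket order per record: excluded status first (counted under its
    normalized label), then unresolvable start year (``n_bad_date``), then
    start year outside the window (``out_of_window`` bucket), else included.
    Screening an already-screened dataset is a no-op.
    """
    policy = policy or ScreeningPolicy()
    report = ScreeningReport(n_input=dataset.count)
    kept = []
    for rec in dataset:
        status = normalize_status(rec.overall_status)
        if status in policy.exclude_statuses:
            report.exclusions[status] = report.exclusions.get(status, 0) + 1
            continue
        if status not in policy.include_statuses:
            if policy.strict:
                raise ScreeningError(
                    f"status {rec.overall_status!r} of {rec.nct_id} is in neither "
                    "the include nor the exclude set")
            report.exclusions[status] = report.exclusions.get(status, 0) + 1
            continue
        year = rec.start_year
        if year is None:
            report.n_bad_date += 1
            continue
        if not policy.year_min <= year <= policy.year_max:
            report.exclusions["out_of_window"] = report.exclusions.get("out_of_window", 0) + 1
            continue
        kept.append(rec)
        report.n_included += 1
    out = RegistryDataset(tuple(kept), source=dataset.source, loaded_at=dataset.loaded_at)
    assert report.balances()
    return out, report
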
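"""Per-trial lexicon term counts, frequencies and mention flags.

Matching is exact token equality: "anxiety-like", "anxious" or "depressive"
never count toward "anxiety"/"depression". Frequency is occurrences divided
by the trial's total word count; the binary mention flag is count >= 1, and
``any_word`` is the OR over the lexicon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .textprep import TokenizedSummary, normalize_text, tokenize

__all__ = ["TermLexicon", "TermProfile", "DEFAULT_LEXICON", "profile", "aggregate"]

#: The four canonical mental-health terms.
DEFAULT_TERMS = ("depression", "anxiety", "loneliness", "distress")


@dataclass(frozen=True)
class TermLexicon:
    """Ordered set of lowercase single-word terms.

    Each term must survive the text pipeline unchanged, otherwise it could
    never be matched and the profile would silently read zero.
    """

    terms: tuple[str, ...] = DEFAULT_TERMS

    def __post_init__(self):
        if not self.terms:
            raise ValueError("lexicon must be non-empty")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("lexicon terms must be unique")
        for term in self.terms:
            survived = tokenize(normalize_text(term)).tokens
            if survived != (term,):
                raise ValueError(
                    f"term {term!r} does not survive text preparation "
                    f"(becomes {survived}); use its normalized single-token form")

    def __iter__(self):
        return iter(self.terms)


DEFAULT_LEXICON = TermLexicon()


@dataclass(frozen=True)
class TermProfile:
    counts: dict[str, int]
    frequencies: dict[str, float]
    mentions: dict[str, int]
    total_words: int
    any_word: int
    degenerate: bool = False  # zero-length text; frequencies recorded as 0

    def as_row(self) -> dict:
        row: dict = {}
        for term in self.counts:
            row[f"{term}_count"] = self.counts[term]
            row[f"{term}_frequency"] = self.frequencies[term]
            row[f"{term}_mention"] = self.mentions[term]
        row["total_words"] = self.total_words
        row["any_word"] = self.any_word
        return row


def profile(summary: TokenizedSummary, lexicon: TermLexicon = DEFAULT_LEXICON) -> TermProfile:
    """Count each lexicon term in ``summary`` by exact token equality.

    A zero-word summary yields all-zero counts and mentions with
    frequencies recorded as 0 (not missing) and ``degenerate=True``, so the
    trial still enters mention-based regressions as a non-mention.
    """
    total = summary.total_words
    bag = Counter(summary.tokens)
    counts = {t: bag.get(t, 0) for t in lexicon}
    mentions = {t: int(c >= 1) for t, c in counts.items()}
    if total > 0:
        freqs = {t: c / total for t, c in counts.items()}
        degenerate = False
    else:
        freqs = {t: 0.0 for t in lexicon}
        degenerate = True
    return TermProfile(counts=counts, frequencies=freqs, mentions=mentions,
                       total_words=total, any_word=max(mentions.values()),
                       degenerate=degenerate)


def aggregate(rows: pd.DataFrame, terms=DEFAULT_TERMS) -> pd.DataFrame:
    """Group per-trial profiles by (start_year, status).

    ``rows`` is an analysis-dataset frame (one row per screened trial).
    Returns one row per non-empty (year, status) cell with the trial count,
    each term's mean frequency and mention proportion, and the any-word
    proportion.
    """
    aggs = {"nct_id": ("nct_id", "size")}
    for t in terms:
        aggs[f"{t}_mean_frequency"] = (f"{t}_frequency", "mean")
        aggs[f"{t}_mention_prop"] = (f"{t}_mention", "mean")
    aggs["any_word_prop"] = ("any_word", "mean")
    out = (rows.groupby(["start_year", "status"], as_index=False)
               .agg(**aggs)
               .rename(columns={"nct_id": "n_trials"}))
    return out
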
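"""Text normalization and tokenization for registry description blocks.

The dialect is deliberately rigid and not configurable: every character
other than letters, digits, whitespace, apostrophes and dashes is replaced
by a single space, text is lowercased, tokens are split on whitespace runs,
and a word-final ``'s`` (possessive) is stripped so that e.g. "alzheimer's"
and "alzheimer" count as the same word. Keeping the dialect fixed keeps
term counts comparable across datasets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["TokenizedSummary", "normalize_text", "tokenize", "prepare"]

# Typographic variants folded into a single ASCII form first, so the kept-set
# and the possessive rule each have one spelling to deal with.
_FOLD = str.maketrans({"’": "'", "–": "-", "—": "-"})

# Anything that is not a Unicode letter, digit, whitespace, straight
# apostrophe or hyphen-minus becomes one space. Underscore is excluded from
# \w by hand: it is a symbol, not a word character here.
_DROP = re.compile(r"[^\w\s'\-]|_", flags=re.UNICODE)


@dataclass(frozen=True)
class TokenizedSummary:
    """Ordered lowercase tokens of one trial's combined descriptions."""

    tokens: tuple[str, ...] = field(default=())

    @property
    def total_words(self) -> int:
        return len(self.tokens)


def normalize_text(raw: str) -> str:
    """Lowercase ``raw`` and replace every disallowed symbol with a space.

    Kept characters: Unicode letters, digits, whitespace, apostrophes and
    dashes (typographic apostrophes/en/em dashes are folded to ``'`` / ``-``).
    Each removed character is replaced by exactly one space, so surrounding
    words never fuse. Idempotent.
    """
    return _DROP.sub(" ", raw.translate(_FOLD)).lower()


def tokenize(normalized: str) -> TokenizedSummary:
    """Split normalized text on whitespace and strip word-final ``'s``.

    Empty tokens (including a bare ``'s``) are dropped; a trailing apostrophe
    alone (plural possessive, ``patients'``) is left untouched.
    """
    tokens = []
    for chunk in normalized.split():
        if chunk.endswith("'s"):
            chunk = chunk[:-2]
        if chunk:
            tokens.append(chunk)
    return TokenizedSummary(tuple(tokens))


def prepare(record) -> TokenizedSummary:
    """Tokenize a trial record's brief and detailed descriptions jointly.

    The two blocks are concatenated brief-then-detailed with a single
    separating space (so the last brief word and first detailed word stay
    distinct tokens) and pushed through :func:`normalize_text` and
    :func:`tokenize`. The resulting ``total_words`` is the frequency
    denominator used everywhere downstream.
    """
    combined = f"{record.brief_description} {record.detailed_description}"
    return tokenize(normalize_text(combined))
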
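"""Affect lexicon and the 21-subcategory emotion taxonomy.

The taxonomy maps 21 emotion subcategory codes onto five primary emotions
(HAPPY, SAD, ANGRY, FEAR, DISGUST) and a binary polarity, following the
Chinese Affective Lexicon Ontology scheme.  One code, PC (surprise), is
dual-natured: it rolls up to HAPPY when the lexicon entry is positive and
to FEAR when it is negative.  One code, PF (grief), carries a ``P`` prefix
but is negative and maps to SAD; the prefix convention is not uniform in
the source scheme and is preserved verbatim here.

A lexicon is a flat word list where each entry carries a code and a
polarity; a surface form may appear under several codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "PRIMARY_EMOTIONS",
    "CODES",
    "CODES_FOR_PRIMARY",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "primary_of",
    "default_polarity",
    "classify_token",
]

#: The five primary emotions (EMPTY is a narrative tag, never a lexicon primary).
PRIMARY_EMOTIONS: tuple[str, ...] = ("HAPPY", "ANGRY", "SAD", "FEAR", "DISGUST")

#: All 21 subcategory codes in canonical (taxonomy-table) order.
CODES: tuple[str, ...] = (
    "PA", "PE", "PD", "PH", "PG", "PB", "PK",   # HAPPY
    "NA",                                       # ANGRY
    "NB", "NJ", "NH", "PF",                     # SAD
    "NI", "NC", "NG", "NE",                     # FEAR
    "ND", "NN", "NK",                           # DISGUST
    "NL",                                       # FEAR
    "PC",                                       # FEAR/HAPPY by polarity
)

#: Unambiguous code -> primary mapping (PC excluded; it needs a polarity).
_CODE_PRIMARY: dict[str, str] = {
    **{c: "HAPPY" for c in ("PA", "PE", "PD", "PH", "PG", "PB", "PK")},
    "NA": "ANGRY",
    **{c: "SAD" for c in ("NB", "NJ", "NH", "PF")},
    **{c: "FEAR" for c in ("NI", "NC", "NG", "NE", "NL")},
    **{c: "DISGUST" for c in ("ND", "NN", "NK")},
}

#: Codes eligible as subcategories of each primary, canonical order.
#: PC may annotate either FEAR or HAPPY narratives.
CODES_FOR_PRIMARY: dict[str, tuple[str, ...]] = {
    "HAPPY": ("PA", "PE", "PD", "PH", "PG", "PB", "PK", "PC"),
    "ANGRY": ("NA",),
    "SAD": ("NB", "NJ", "NH", "PF"),
    "FEAR": ("NI", "NC", "NG", "NE", "NL", "PC"),
    "DISGUST": ("ND", "NN", "NK"),
}

POLARITIES: tuple[str, str] = ("positive", "negative")


class LexiconError(ValueError):
    """Raised for malformed lexicon files or invalid codes/polarities."""


def primary_of(code: str, polarity: str | None = None) -> str:
    """Map a subcategory code to its primary emotion.

    PC resolves by polarity: positive -> HAPPY, negative -> FEAR.  All
    other codes ignore ``polarity``.
    """
    code = code.upper()
    if code == "PC":
        if polarity not in POLARITIES:
            raise LexiconError("PC requires an explicit polarity to resolve its primary")
        return "HAPPY" if polarity == "positive" else "FEAR"
    try:
        return _CODE_PRIMARY[code]
    except KeyError:
        raise LexiconError(f"unknown subcategory code {code!r}") from None


def default_polarity(code: str) -> str:
    """Default polarity of a code: positive iff it rolls up to HAPPY.

    PF (grief) is negative despite its prefix.  PC has no default and
    raises; its polarity must come from the lexicon entry.
    """
    code = code.upper()
    if code == "PC":
        raise LexiconError("PC has no default polarity")
    return "positive" if _CODE_PRIMARY[code] == "HAPPY" else "negative"


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    code: str
    polarity: str

    def __post_init__(self) -> None:
        if self.code not in CODES:
            raise LexiconError(f"unknown subcategory code {self.code!r} for word {self.word!r}")
        if self.polarity not in POLARITIES:
            raise LexiconError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r} for word {self.word!r}"
            )

    @property
    def primary(self) -> str:
        return primary_of(self.code, self.polarity)


class Lexicon:
    """An ordered affect word list with an index by surface form.

    Entry order is file order; ``classify_token`` reports a word's codes
    in that order, which downstream counting relies on for deterministic
    first-entry attribution.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = list(entries)
        seen: set[tuple[str, str]] = set()
        self._index: dict[str, list[LexiconEntry]] = {}
        for e in self.entries:
            key = (e.word, e.code)
            if key in seen:
                raise LexiconError(f"duplicate lexicon entry {key}")
            seen.add(key)
            self._index.setdefault(e.word, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def lookup(self, word: str) -> list[LexiconEntry]:
        """All entries for an exact surface form, file order; [] if absent."""
        return self._index.get(word, [])


def classify_token(word: str, lexicon: Lexicon) -> list[tuple[str, str]]:
    """All (code, polarity) pairs the exact surface form maps to.

    Matching is exact string equality: no stemming, no case folding —
    segmented words are matched as-is.
    """
    return [(e.code, e.polarity) for e in lexicon.lookup(word)]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a TSV file with header ``word  code  polarity``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["word", "code", "polarity"]
    if list(df.columns[:3]) != required:
        raise LexiconError(f"lexicon header must start with {required}, got {list(df.columns)}")
    entries = []
    for row in df.itertuples(index=False):
        word = row.word.strip()
        if not word:
            raise LexiconError("empty word in lexicon")
        entries.append(LexiconEntry(word, row.code.strip().upper(), row.polarity.strip().lower()))
    return Lexicon(entries)
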
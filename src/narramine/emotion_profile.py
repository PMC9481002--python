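"""Emotion-word frequency profiles by group.

Counts lexicon words in the stopword-filtered token streams of each
group, as conditional frequency distributions at three levels:

* ``polarity`` — positive vs negative;
* ``primary5`` — the five primary emotions;
* ``sub21``   — the 21 subcategory codes.

A token carrying several lexicon codes counts once per code at the
21-way level, but exactly once at the aggregated levels, attributed via
its first-listed lexicon entry (PC resolved to HAPPY or FEAR by that
entry's polarity).  This keeps the aggregate levels conserved: the five
primary counts and the two polarity counts both sum to the once-per-token
emotional total.  Both absolute counts and counts per 1,000 filtered
tokens are reported, so groups with unequal corpus sizes compare fairly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .corpus_io import Corpus, GROUPS
from .lexicon import CODES, Lexicon, PRIMARY_EMOTIONS, primary_of
from .preprocess import DEFAULT_TERMINATORS, tokenize_narrative

__all__ = ["EmotionFrequencyTable", "emotion_counts", "profile_report", "LEVELS"]

LEVELS: tuple[str, ...] = ("polarity", "primary5", "sub21")

_LEVEL_KEYS = {
    "polarity": ("positive", "negative"),
    "primary5": PRIMARY_EMOTIONS,
    "sub21": CODES,
}


@dataclass
class EmotionFrequencyTable:
    """Counts per (group, condition level) with per-1,000-token relative counts."""

    level: str
    counts: dict[tuple[str, str], int]
    denominators: dict[str, int]

    @property
    def relative(self) -> dict[tuple[str, str], float]:
        return {
            (g, k): 1000.0 * c / self.denominators[g] if self.denominators[g] else 0.0
            for (g, k), c in self.counts.items()
        }

    def group_total(self, group: str) -> int:
        return sum(c for (g, _), c in self.counts.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        rel = self.relative
        rows = [
            {
                "level": k,
                "group": g,
                "count": self.counts[(g, k)],
                "per_1000_tokens": rel[(g, k)],
            }
            for g in GROUPS
            for k in _LEVEL_KEYS[self.level]
        ]
        return pd.DataFrame(rows)


def _filtered_group_tokens(
    corpus: Corpus,
    stoplist,
    tokenizer: str,
    terminators: str,
    by_narrative_emotion: str | None = None,
) -> dict[str, list[str]]:
    streams: dict[str, list[str]] = {g: [] for g in GROUPS}
    for p in corpus:
        for n in p.narratives:
            if by_narrative_emotion is not None and n.tag.primary != by_narrative_emotion:
                continue
            tn = tokenize_narrative(n.text, tokenizer, terminators, stoplist)
            streams[p.group].extend(tn.filtered_tokens)
    return streams


def emotion_counts(
    corpus: Corpus,
    lexicon: Lexicon,
    stoplist,
    level: str = "sub21",
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
    by_narrative_emotion: str | None = None,
) -> EmotionFrequencyTable:
    """Conditional frequency distribution of emotion words by group.

    Counts run over all narratives regardless of their tag (the profile
    conditions only on group); pass ``by_narrative_emotion`` to restrict
    to narratives of one primary emotion.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    streams = _filtered_group_tokens(corpus, stoplist, tokenizer, terminators, by_narrative_emotion)
    counts = {(g, k): 0 for g in GROUPS for k in _LEVEL_KEYS[level]}
    for g, tokens in streams.items():
        for tok in tokens:
            entries = lexicon.lookup(tok)
            if not entries:
                continue
            if level == "sub21":
                for e in entries:
                    counts[(g, e.code)] += 1
            else:
                first = entries[0]
                key = first.polarity if level == "polarity" else primary_of(first.code, first.polarity)
                counts[(g, key)] += 1
    denominators = {g: len(tokens) for g, tokens in streams.items()}
    return EmotionFrequencyTable(level=level, counts=counts, denominators=denominators)


def profile_report(
    corpus: Corpus,
    lexicon: Lexicon,
    stoplist,
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
) -> dict[str, pd.DataFrame]:
    """The three frequency tables (polarity, 5-way, 21-way), patient-count sorted.

    Each table carries absolute counts and per-1,000-token relative counts
    for both groups, one row per condition level, sorted by descending
    patient count.
    """
    report = {}
    for level in LEVELS:
        table = emotion_counts(corpus, lexicon, stoplist, level, tokenizer, terminators)
        df = table.to_frame()
        wide = df.pivot(index="level", columns="group", values=["count", "per_1000_tokens"])
        wide.columns = [f"{stat}_{grp}" for stat, grp in wide.columns]
        for col in wide.columns:
            if col.startswith("count_"):
                wide[col] = wide[col].astype(int)
        wide = wide.reset_index().sort_values(
            ["count_patient", "level"], ascending=[False, True], kind="mergesort"
        )
        report[level] = wide.reset_index(drop=True)
    return report
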
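"""Corpus keyness via the two-cell log-likelihood ratio.

For a word with observed frequency O1 in a focal corpus of N1 tokens and
O2 in a reference corpus of N2 tokens, expected frequencies under the
shared-rate null are E_i = N_i * (O1 + O2) / (N1 + N2) and the statistic
is

    LL = -2 ln lambda = 2 * [ O1 ln(O1/E1) + O2 ln(O2/E2) ]

with the x ln x -> 0 convention for a zero observed cell.  This is the
two-cell form used in corpus linguistics (the sum runs over the two
corpora only, not over all four cells of the 2x2 table); it differs
numerically from the four-cell G statistic and is implemented exactly in
this form.  Under the null it is approximately chi-square with 1 df; the
conventional significance cutoff 15.13 is the 1-df quantile at
p = 1e-4, truncated to two decimals.

A word is keyed "+" (overuse in the focal corpus) when O1/N1 > O2/N2 and
"-" (underuse) when O1/N1 < O2/N2.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Corpus
from .preprocess import DEFAULT_TERMINATORS, tokenize_narrative

__all__ = [
    "ContingencyTable",
    "KeynessResult",
    "ll_statistic",
    "ll_values",
    "critical_value",
    "keyness_table",
    "emotion_keyness",
    "EmotionKeyness",
    "DEFAULT_ALPHA",
    "DEFAULT_THRESHOLD",
]

DEFAULT_ALPHA = 1e-4
#: The corpus-linguistics convention: chi2(1df) quantile at 1-1e-4, truncated.
DEFAULT_THRESHOLD = 15.13


@dataclass(frozen=True)
class ContingencyTable:
    """Two-cell word-frequency table: O1 of N1 tokens vs O2 of N2 tokens."""

    a: int  # target-word frequency in corpus 1
    b: int  # target-word frequency in corpus 2
    n1: int  # corpus 1 token total
    n2: int  # corpus 2 token total

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.b <= self.n2):
            raise ValueError(f"need 0 <= a <= n1 and 0 <= b <= n2, got {self}")
        if self.a + self.b < 1:
            raise ValueError("word occurs in neither corpus (a + b = 0)")

    @property
    def e1(self) -> float:
        return self.n1 * (self.a + self.b) / (self.n1 + self.n2)

    @property
    def e2(self) -> float:
        return self.n2 * (self.a + self.b) / (self.n1 + self.n2)


def ll_statistic(table: ContingencyTable) -> float:
    """The two-cell log-likelihood ratio statistic for one word."""
    ll = 0.0
    if table.a:
        ll += table.a * np.log(table.a / table.e1)
    if table.b:
        ll += table.b * np.log(table.b / table.e2)
    return max(2.0 * ll, 0.0)


def ll_values(a: np.ndarray, b: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Vectorized two-cell LL over parallel frequency arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    tot = a + b
    e1 = n1 * tot / (n1 + n2)
    e2 = n2 * tot / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(a > 0, a * np.log(a / e1), 0.0)
        term2 = np.where(b > 0, b * np.log(b / e2), 0.0)
    return np.maximum(2.0 * (term1 + term2), 0.0)


def critical_value(alpha: float = DEFAULT_ALPHA, mode: str = "truncate") -> float:
    """Chi-square (1 df) quantile at 1 - alpha, truncated or rounded to 2 decimals.

    The default (alpha = 1e-4, truncate) reproduces the conventional
    cutoff 15.13 (exact quantile 15.1367...).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    q = stats.chi2.ppf(1.0 - alpha, df=1)
    if mode == "truncate":
        return np.floor(q * 100.0) / 100.0
    if mode == "round":
        return round(q, 2)
    raise ValueError(f"mode must be 'truncate' or 'round', got {mode!r}")


@dataclass(frozen=True)
class KeynessResult:
    word: str
    ll: float
    freq1: int
    freq2: int
    rel1: float  # relative frequency in corpus 1, percent
    rel2: float
    sign: str  # '+' overuse in corpus 1, '-' underuse, '0' equal rates
    significant: bool


def keyness_table(
    tokens1: Sequence[str],
    tokens2: Sequence[str],
    min_freq: int = 5,
    threshold: float | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Keyness of every word type, ranked by LL.

    ``min_freq`` filters on the pooled frequency a+b (the default 5
    suppresses unstable low-count keys; 1 admits singletons).  Ranking is
    LL descending, ties broken by pooled frequency descending then
    lexicographically.  Relative frequencies are percentages at full
    precision; format at display time.
    """
    if not tokens1 or not tokens2:
        raise ValueError("both token streams must be non-empty")
    if min_freq < 1:
        raise ValueError("min_freq must be >= 1")
    if threshold is None:
        threshold = critical_value(alpha)
    n1, n2 = len(tokens1), len(tokens2)
    c1 = Counter(tokens1)
    c2 = Counter(tokens2)
    vocab = sorted(set(c1) | set(c2))
    a = np.array([c1[w] for w in vocab])
    b = np.array([c2[w] for w in vocab])
    keep = (a + b) >= min_freq
    if not keep.any():
        raise ValueError(f"no word reaches pooled frequency {min_freq}")
    words = np.array(vocab, dtype=object)[keep]
    a, b = a[keep], b[keep]
    ll = ll_values(a, b, n1, n2)
    rate1, rate2 = a / n1, b / n2
    sign = np.where(rate1 > rate2, "+", np.where(rate1 < rate2, "-", "0"))
    df = pd.DataFrame(
        {
            "word": words,
            "ll": ll,
            "freq1": a,
            "rel1": 100.0 * rate1,
            "freq2": b,
            "rel2": 100.0 * rate2,
            "sign": sign,
            "significant": ll >= threshold,
        }
    )
    df["_pooled"] = df["freq1"] + df["freq2"]
    df = df.sort_values(
        ["ll", "_pooled", "word"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_pooled")
    return df.reset_index(drop=True)


def results_from_table(df: pd.DataFrame) -> list[KeynessResult]:
    """The table rows as :class:`KeynessResult` records, rank order."""
    return [
        KeynessResult(
            word=r.word, ll=r.ll, freq1=int(r.freq1), freq2=int(r.freq2),
            rel1=r.rel1, rel2=r.rel2, sign=r.sign, significant=bool(r.significant),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class EmotionKeyness:
    """Keyness restricted to one emotion's narratives, group1 vs group2."""

    emotion: str
    table: pd.DataFrame
    more_common_in_group1: list[str]
    more_common_in_group2: list[str]
    n1: int
    n2: int


def emotion_keyness(
    corpus: Corpus,
    emotion: str,
    min_freq: int = 5,
    threshold: float | None = None,
    alpha: float = DEFAULT_ALPHA,
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
    stoplist: Iterable[str] = (),
    group_order: tuple[str, str] = ("patient", "control"),
) -> EmotionKeyness:
    """Keyness between the two groups' narratives of one primary emotion.

    Token streams retain stopwords by default (function words are often
    the strongest keys); pass a stoplist to exclude them.  Raises when a
    group has no narrative of the emotion.
    """
    stop = set(stoplist)
    streams: dict[str, list[str]] = {g: [] for g in group_order}
    present: dict[str, bool] = {g: False for g in group_order}
    for p in corpus:
        if p.group not in streams:
            continue
        for n in p.narratives:
            if n.tag.primary != emotion:
                continue
            present[p.group] = True
            tn = tokenize_narrative(n.text, tokenizer, terminators, stop)
            streams[p.group].extend(tn.filtered_tokens if stop else tn.tokens)
    for g in group_order:
        if not present[g]:
            raise ValueError(f"group {g!r} has no {emotion} narrative")
    t1, t2 = streams[group_order[0]], streams[group_order[1]]
    df = keyness_table(t1, t2, min_freq=min_freq, threshold=threshold, alpha=alpha)
    sig = df[df["significant"]]
    return EmotionKeyness(
        emotion=emotion,
        table=df,
        more_common_in_group1=sig.loc[sig["sign"] == "+", "word"].tolist(),
        more_common_in_group2=sig.loc[sig["sign"] == "-", "word"].tolist(),
        n1=len(t1),
        n2=len(t2),
    )
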
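"""Narrative-complexity features and two-group Welch comparison.

Per participant, over all non-EMPTY narratives:

* type-token ratio (TTR): distinct word forms / total tokens, a
  lexical-diversity index (one value per participant, so the group
  comparison has one observation per speaker);
* mean word-length in characters per token;
* words per sentence, sentences per narrative, words per narrative;
* the words-per-narrative figure additionally broken down by the five
  primary emotions of the narrative tags.

Group comparison is a two-tailed Welch (unequal-variance) t-test, run on
the raw feature values and on pooled min-max-normalized values.  Min-max
normalization over the pooled sample is an affine map, so the t statistic
and p-value of the normalized rows equal the raw rows exactly; both are
reported because normalized means are easier to read across features.
The sign convention is t = mean(group1) - mean(group2), with group order
an explicit argument defaulting to (patient, control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Corpus, Participant
from .lexicon import PRIMARY_EMOTIONS
from .preprocess import DEFAULT_TERMINATORS, TokenizedNarrative, tokenize_narrative

__all__ = [
    "FeatureVector",
    "WelchResult",
    "FeatureComparison",
    "compute_features",
    "minmax_normalize",
    "welch_t",
    "feature_comparison_table",
    "FEATURE_NAMES",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ttr",
    "mean_word_length",
    "words_per_sentence",
    "sentences_per_narrative",
    "words_per_narrative",
)


@dataclass
class FeatureVector:
    """Per-participant generic features over non-EMPTY narratives."""

    ttr: float
    mean_word_length: float
    words_per_sentence: float
    sentences_per_narrative: float
    words_per_narrative: float
    #: words/narrative restricted to narratives of each primary emotion;
    #: absent when the participant has no narrative of that emotion.
    per_emotion_words_per_narrative: dict[str, float] = field(default_factory=dict)
    #: narrative counts per emotion (used to reconstruct the overall figure).
    per_emotion_narrative_count: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass
class WelchResult:
    """Welch's unequal-variance t-test; t's sign is mean1 - mean2."""

    t: float
    df: float
    p: float
    n1: int
    n2: int
    mean1: float
    mean2: float


def compute_features(
    narratives: list[tuple[str, TokenizedNarrative]],
) -> FeatureVector:
    """Compute a participant's feature vector.

    ``narratives`` pairs each narrative's primary-emotion label (``EMPTY``
    allowed, excluded from every statistic here) with its tokenized form.
    """
    emotional = [(e, tn) for e, tn in narratives if e != "EMPTY"]
    if not emotional:
        raise ValueError("participant has no non-EMPTY narrative")
    tokens: list[str] = []
    total_sentences = 0
    for _, tn in emotional:
        tokens.extend(tn.tokens)
        total_sentences += tn.sentence_count
    n_tok = len(tokens)
    n_narr = len(emotional)
    if n_tok == 0:
        raise ValueError("participant has no tokens")

    per_emotion_wpn: dict[str, float] = {}
    per_emotion_nn: dict[str, int] = {}
    for emo in PRIMARY_EMOTIONS:
        subset = [tn for e, tn in emotional if e == emo]
        if subset:
            per_emotion_nn[emo] = len(subset)
            per_emotion_wpn[emo] = sum(tn.token_count for tn in subset) / len(subset)

    return FeatureVector(
        ttr=len(set(tokens)) / n_tok,
        mean_word_length=sum(len(t) for t in tokens) / n_tok,
        words_per_sentence=n_tok / total_sentences,
        sentences_per_narrative=total_sentences / n_narr,
        words_per_narrative=n_tok / n_narr,
        per_emotion_words_per_narrative=per_emotion_wpn,
        per_emotion_narrative_count=per_emotion_nn,
    )


def minmax_normalize(values) -> np.ndarray:
    """(x - min)/(max - min) over the pooled sample; requires >=2 distinct values."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined: all values identical")
    return (x - lo) / (hi - lo)


def welch_t(group1, group2) -> WelchResult:
    """Welch's two-sample t with Welch–Satterthwaite df and two-tailed p.

    Sample variances use the n-1 denominator.  Requires >=2 values per
    group and nonzero variance in at least one group.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    se1, se2 = v1 / n1, v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se1 + se2)
    df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=t, df=df, p=p, n1=n1, n2=n2, mean1=x.mean(), mean2=y.mean())


@dataclass
class FeatureComparison:
    """Feature table (raw + normalized rows) and per-emotion words/narrative table."""

    features: pd.DataFrame
    per_emotion: pd.DataFrame
    vectors: dict[str, FeatureVector]


def _comparison_row(name: str, variant: str, g1: np.ndarray, g2: np.ndarray) -> dict:
    row = {
        "feature": name,
        "variant": variant,
        "mean1": g1.mean() if len(g1) else float("nan"),
        "mean2": g2.mean() if len(g2) else float("nan"),
        "n1": len(g1),
        "n2": len(g2),
        "t": float("nan"),
        "df": float("nan"),
        "p": float("nan"),
        "computable": False,
    }
    try:
        res = welch_t(g1, g2)
    except ValueError:
        return row
    row.update(t=res.t, df=res.df, p=res.p, computable=True)
    return row


def tokenize_participant(
    participant: Participant,
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
    stoplist=(),
) -> list[tuple[str, TokenizedNarrative]]:
    """Tokenize all of a participant's narratives, labelled by primary emotion."""
    return [
        (n.tag.primary, tokenize_narrative(n.text, tokenizer, terminators, stoplist))
        for n in participant.narratives
    ]


def feature_comparison_table(
    corpus: Corpus,
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
    group_order: tuple[str, str] = ("patient", "control"),
) -> FeatureComparison:
    """Per-participant features and the two-group Welch comparison tables.

    Emits one row per feature for the raw values and one for the pooled
    min-max-normalized values, then a words/narrative row per primary
    emotion restricted to participants having that emotion.  Rows where a
    group has fewer than two usable values are marked not computable.
    """
    g1_name, g2_name = group_order
    vectors: dict[str, FeatureVector] = {}
    groups: dict[str, list[FeatureVector]] = {g1_name: [], g2_name: []}
    for p in corpus:
        fv = compute_features(tokenize_participant(p, tokenizer, terminators))
        vectors[p.id] = fv
        groups[p.group].append(fv)
    if not groups[g1_name] or not groups[g2_name]:
        raise ValueError("both groups must be non-empty")

    rows = []
    for name in FEATURE_NAMES:
        g1 = np.array([getattr(fv, name) for fv in groups[g1_name]])
        g2 = np.array([getattr(fv, name) for fv in groups[g2_name]])
        rows.append(_comparison_row(name, "raw", g1, g2))
        pooled = np.concatenate([g1, g2])
        try:
            norm = minmax_normalize(pooled)
        except ValueError:
            row = _comparison_row(name, "normalized", g1, g2)
            row.update(mean1=float("nan"), mean2=float("nan"), computable=False)
            rows.append(row)
            continue
        rows.append(_comparison_row(name, "normalized", norm[: len(g1)], norm[len(g1):]))
    features = pd.DataFrame(rows)

    emo_rows = []
    for emo in PRIMARY_EMOTIONS:
        g1 = np.array(
            [fv.per_emotion_words_per_narrative[emo]
             for fv in groups[g1_name] if emo in fv.per_emotion_words_per_narrative]
        )
        g2 = np.array(
            [fv.per_emotion_words_per_narrative[emo]
             for fv in groups[g2_name] if emo in fv.per_emotion_words_per_narrative]
        )
        emo_rows.append(_comparison_row(emo, "raw", g1, g2))
    per_emotion = pd.DataFrame(emo_rows)

    return FeatureComparison(features=features, per_emotion=per_emotion, vectors=vectors)
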
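"""Sentence segmentation, tokenization and stopword filtering.

Tokenizers are pluggable.  The default splits on whitespace and strips
punctuation, which suits Latin-script text and pre-segmented Chinese
(words already separated by spaces).  Languages without word delimiters
plug in an external segmenter through :func:`register_tokenizer`; the
adapter's token list is passed through unchanged.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "DEFAULT_TERMINATORS",
    "TokenizedNarrative",
    "segment_sentences",
    "tokenize",
    "register_tokenizer",
    "available_tokenizers",
    "filter_stopwords",
    "load_stoplist",
    "tokenize_narrative",
]

#: Default sentence-final punctuation (configurable; CJK + Latin).
DEFAULT_TERMINATORS = "。！？.!?"

#: Characters stripped from token edges; a token reduced to nothing is dropped.
_PUNCT = string.punctuation + "。！？，、；：“”‘’（）《》〈〉【】…—·～「」『』"


def segment_sentences(text: str, terminators: str = DEFAULT_TERMINATORS) -> list[str]:
    """Split text into sentences at terminator characters.

    A sentence is a maximal run ending at a (run of) terminator(s), with
    the terminators attached; trailing text without a terminator forms a
    final sentence.  Empty segments are dropped.
    """
    if not terminators:
        raise ValueError("terminator set must be non-empty")
    t = re.escape(terminators)
    pieces = re.findall(rf"[^{t}]+[{t}]*|[{t}]+", text)
    return [s for s in (p.strip() for p in pieces) if s]


def _whitespace_tokenize(sentence: str) -> list[str]:
    tokens = []
    for chunk in sentence.split():
        tok = chunk.strip(_PUNCT)
        if tok:
            tokens.append(tok)
    return tokens


def _character_tokenize(sentence: str) -> list[str]:
    """One token per non-space, non-punctuation character (crude CJK fallback)."""
    return [ch for ch in sentence if not ch.isspace() and ch not in _PUNCT]


_TOKENIZERS: dict[str, Callable[[str], list[str]]] = {
    "whitespace": _whitespace_tokenize,
    "character": _character_tokenize,
}


def register_tokenizer(name: str, fn: Callable[[str], list[str]]) -> None:
    """Register an external segmenter adapter under ``name``.

    ``fn`` maps a sentence string to its token list; the list is used
    verbatim (no further splitting or stripping).
    """
    _TOKENIZERS[name] = fn


def available_tokenizers() -> list[str]:
    return sorted(_TOKENIZERS)


def tokenize(sentence: str, tokenizer: str = "whitespace") -> list[str]:
    """Tokenize one sentence with a registered strategy."""
    try:
        fn = _TOKENIZERS[tokenizer]
    except KeyError:
        raise KeyError(
            f"unregistered tokenizer {tokenizer!r}; available: {available_tokenizers()}"
        ) from None
    return fn(sentence)


def filter_stopwords(tokens: Sequence[str], stoplist: Iterable[str]) -> list[str]:
    """Remove tokens whose surface form is in the stoplist, preserving order."""
    stop = stoplist if isinstance(stoplist, (set, frozenset)) else set(stoplist)
    return [t for t in tokens if t not in stop]


def load_stoplist(path: str | Path) -> set[str]:
    """Load a stoplist: one word per line, UTF-8, ``#`` comment lines ignored."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip()
        if w and not w.startswith("#"):
            words.add(w)
    return words


@dataclass
class TokenizedNarrative:
    """A narrative as ordered sentences of tokens, with stopword-filtered view.

    ``sentences`` retains all (non-punctuation) tokens; ``filtered_tokens``
    is the flat token stream after stopword removal.  Narrative-complexity
    features use the unfiltered view, emotion-word counting the filtered one.
    """

    sentences: list[list[str]]
    filtered_tokens: list[str]

    @property
    def tokens(self) -> list[str]:
        return [t for s in self.sentences for t in s]

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def sentence_count(self) -> int:
        return len(self.sentences)

    @property
    def filtered_token_count(self) -> int:
        return len(self.filtered_tokens)

    @property
    def char_count(self) -> int:
        return sum(len(t) for s in self.sentences for t in s)


def tokenize_narrative(
    text: str,
    tokenizer: str = "whitespace",
    terminators: str = DEFAULT_TERMINATORS,
    stoplist: Iterable[str] = (),
) -> TokenizedNarrative:
    """Segment + tokenize a narrative and attach its stopword-filtered stream."""
    stop = stoplist if isinstance(stoplist, (set, frozenset)) else set(stoplist)
    sentences = [tokenize(s, tokenizer) for s in segment_sentences(text, terminators)]
    sentences = [s for s in sentences if s]
    flat = [t for s in sentences for t in s]
    return TokenizedNarrative(sentences=sentences, filtered_tokens=filter_stopwords(flat, stop))
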
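"""Reading and writing emotion-tagged narrative corpora.

On disk a corpus is a directory of UTF-8 text files, one per participant
(filename stem = participant id), plus a tab-delimited metadata table.
Each participant file is a sequence of line-initial emotion tags, each
followed by the narrative's text until the next tag:

    ++SAD(NB)++
    On the way to the isolation hospital, I cried all the way.
    ++EMPTY++
    Then we talked about the weather.

A tag names one primary emotion — HAPPY, SAD, ANGRY, FEAR, DISGUST, or
EMPTY for narratives carrying no emotion — and optionally one or more
subcategory codes drawn from the 21-code affect taxonomy.  Text may
continue on the tag line after an optional colon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lexicon import CODES_FOR_PRIMARY, PRIMARY_EMOTIONS

__all__ = [
    "EmotionTag",
    "Narrative",
    "Participant",
    "Corpus",
    "CorpusFormatError",
    "parse_tag",
    "format_tag",
    "read_corpus",
    "write_corpus",
    "GROUPS",
]

GROUPS: tuple[str, str] = ("patient", "control")

#: Primaries valid in a tag (the five emotions plus EMPTY).
TAG_PRIMARIES: tuple[str, ...] = PRIMARY_EMOTIONS + ("EMPTY",)


class CorpusFormatError(ValueError):
    """Raised for malformed tags, files, or metadata."""


@dataclass(frozen=True)
class EmotionTag:
    """A narrative's emotion annotation: a primary plus subcategory codes."""

    primary: str
    subcategories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.primary not in TAG_PRIMARIES:
            raise CorpusFormatError(f"unknown primary emotion {self.primary!r}")
        object.__setattr__(self, "subcategories", tuple(self.subcategories))
        if self.primary == "EMPTY":
            if self.subcategories:
                raise CorpusFormatError("EMPTY tag cannot carry subcategories")
            return
        allowed = CODES_FOR_PRIMARY[self.primary]
        seen = set()
        for code in self.subcategories:
            if code not in allowed:
                raise CorpusFormatError(
                    f"code {code!r} does not belong to primary {self.primary}"
                )
            if code in seen:
                raise CorpusFormatError(f"duplicate code {code!r} in tag")
            seen.add(code)

    @property
    def is_empty(self) -> bool:
        return self.primary == "EMPTY"


@dataclass
class Narrative:
    """One tagged discourse unit: congruent topic/emotion within an interview."""

    tag: EmotionTag
    text: str
    ordinal: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusFormatError(f"narrative {self.ordinal} has empty text")


@dataclass
class Participant:
    id: str
    group: str
    gender: str | None = None
    marital_status: str | None = None
    age: float | None = None
    days_in_hospital: float | None = None
    narratives: list[Narrative] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CorpusFormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.group == "control" and self.days_in_hospital is not None:
            raise CorpusFormatError(
                f"participant {self.id}: days_in_hospital is only valid for patients"
            )


@dataclass
class Corpus:
    participants: list[Participant]

    def by_group(self, group: str) -> list[Participant]:
        return [p for p in self.participants if p.group == group]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)


_TAG_RE = re.compile(
    r"^\+\+\s*(?P<emotion>[A-Za-z]+)\s*"
    r"(?:\(\s*(?P<codes>[A-Za-z]+(?:\s*/\s*[A-Za-z]+)*)\s*\))?"
    r"\s*\+\+(?P<colon>:)?"
)


def parse_tag(line: str, lineno: int | None = None) -> EmotionTag:
    """Parse a line-initial emotion tag like ``++HAPPY (PH/PD) ++:``.

    The emotion name and codes are case-insensitive; whitespace inside
    the delimiters is ignored.  Raises :class:`CorpusFormatError` naming
    the offending token (and line, when given) on any malformation.
    """
    where = f" at line {lineno}" if lineno is not None else ""
    m = _TAG_RE.match(line.strip())
    if m is None:
        raise CorpusFormatError(f"malformed tag {line.strip()!r}{where}")
    emotion = m.group("emotion").upper()
    if emotion not in TAG_PRIMARIES:
        raise CorpusFormatError(f"unknown emotion {m.group('emotion')!r}{where}")
    codes: tuple[str, ...] = ()
    if m.group("codes"):
        codes = tuple(c.strip().upper() for c in m.group("codes").split("/"))
    try:
        return EmotionTag(emotion, codes)
    except CorpusFormatError as err:
        raise CorpusFormatError(f"{err}{where}") from None


def format_tag(tag: EmotionTag) -> str:
    """Canonical on-disk form: ``++EMOTION(C1/C2)++`` with no interior spaces."""
    if tag.subcategories:
        return f"++{tag.primary}({'/'.join(tag.subcategories)})++"
    return f"++{tag.primary}++"


def _tag_rest(line: str) -> str:
    """Text following the tag on the same line (after the optional colon)."""
    m = _TAG_RE.match(line.strip())
    assert m is not None
    return line.strip()[m.end():].strip()


def _is_tag_line(line: str) -> bool:
    return line.lstrip().startswith("++")


def _parse_participant_file(path: Path) -> list[tuple[EmotionTag, str]]:
    narratives: list[tuple[EmotionTag, str]] = []
    tag: EmotionTag | None = None
    chunks: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal tag, chunks
        if tag is not None:
            text = "\n".join(chunks).strip()
            if not text:
                raise CorpusFormatError(
                    f"{path.name}: tag {format_tag(tag)} before line {lineno} has no narrative text"
                )
            narratives.append((tag, text))
        tag, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if _is_tag_line(line):
                flush(lineno)
                tag = parse_tag(line, lineno=lineno)
                rest = _tag_rest(line)
                if rest:
                    chunks.append(rest)
            else:
                if tag is None and line.strip():
                    raise CorpusFormatError(
                        f"{path.name}: text before first tag at line {lineno}"
                    )
                if tag is not None:
                    chunks.append(line)
    flush(lineno=-1)
    if not narratives:
        raise CorpusFormatError(f"{path.name}: no tags found")
    return narratives


_META_COLUMNS = ["id", "group", "gender", "marital_status", "age", "days_in_hospital"]


def read_corpus(corpus_path: str | Path, metadata_path: str | Path) -> Corpus:
    """Read a tagged corpus directory plus its metadata TSV into a :class:`Corpus`."""
    corpus_dir = Path(corpus_path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    if list(meta.columns) != _META_COLUMNS:
        raise CorpusFormatError(
            f"metadata header must be {_META_COLUMNS}, got {list(meta.columns)}"
        )
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise CorpusFormatError(f"duplicate participant ids in metadata: {dupes}")

    files = {p.stem: p for p in sorted(corpus_dir.glob("*.txt"))}
    meta_ids = list(meta["id"])
    missing_files = sorted(set(meta_ids) - set(files))
    if missing_files:
        raise CorpusFormatError(f"metadata ids with no corpus file: {missing_files}")
    orphan_files = sorted(set(files) - set(meta_ids))
    if orphan_files:
        raise CorpusFormatError(f"corpus files with no metadata row: {orphan_files}")

    participants = []
    for row in meta.itertuples(index=False):
        raw = _parse_participant_file(files[row.id])
        narratives = [
            Narrative(tag=tag, text=text, ordinal=i)
            for i, (tag, text) in enumerate(raw, start=1)
        ]
        participants.append(
            Participant(
                id=row.id,
                group=row.group,
                gender=row.gender or None,
                marital_status=row.marital_status or None,
                age=float(row.age) if row.age else None,
                days_in_hospital=float(row.days_in_hospital) if row.days_in_hospital else None,
                narratives=narratives,
            )
        )
    return Corpus(participants)


def write_corpus(corpus: Corpus, corpus_path: str | Path, metadata_path: str | Path) -> None:
    """Write a corpus in the dialect read by :func:`read_corpus` (round-trip safe)."""
    corpus_dir = Path(corpus_path)
    corpus_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in corpus.participants:
        lines = []
        for n in p.narratives:
            lines.append(format_tag(n.tag))
            lines.append(n.text.strip())
        (corpus_dir / f"{p.id}.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
        rows.append(
            {
                "id": p.id,
                "group": p.group,
                "gender": p.gender or "",
                "marital_status": p.marital_status or "",
                "age": "" if p.age is None else f"{p.age:g}",
                "days_in_hospital": "" if p.days_in_hospital is None else f"{p.days_in_hospital:g}",
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(metadata_path, sep="\t", index=False)
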
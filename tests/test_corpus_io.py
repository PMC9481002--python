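"""Tag grammar, corpus dialect parsing, and write/read round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

from narramine import (
    Corpus,
    CorpusFormatError,
    EmotionTag,
    Narrative,
    Participant,
    format_tag,
    parse_tag,
    read_corpus,
    write_corpus,
)
from narramine.lexicon import CODES_FOR_PRIMARY, PRIMARY_EMOTIONS


@pytest.mark.parametrize(
    "line, primary, codes",
    [
        ("++HAPPY (PH/PD) ++:", "HAPPY", ("PH", "PD")),
        ("++EMPTY++", "EMPTY", ()),
        ("++fear( nc )++", "FEAR", ("NC",)),
        ("++SAD(NB)++", "SAD", ("NB",)),
        ("++ANGRY ( NA ) ++", "ANGRY", ("NA",)),
        ("++DISGUST(ND/NN/NK)++:", "DISGUST", ("ND", "NN", "NK")),
    ],
)
def test_parse_tag_normalizes_case_and_whitespace(line, primary, codes):
    tag = parse_tag(line)
    assert tag.primary == primary
    assert tag.subcategories == codes


@pytest.mark.parametrize(
    "line",
    [
        "++JOYFUL++",          # unknown emotion
        "++HAPPY(XX)++",       # unknown code
        "++HAPPY(NB)++",       # code of a different primary
        "++EMPTY(PA)++",       # EMPTY cannot carry codes
        "++HAPPY(PH/PH)++",    # duplicate code
        "+HAPPY+",             # malformed delimiter
        "HAPPY(PH)",           # no delimiter at all
    ],
)
def test_parse_tag_rejects_malformed_input(line):
    with pytest.raises(CorpusFormatError):
        parse_tag(line)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    primary=st.sampled_from(PRIMARY_EMOTIONS + ("EMPTY",)),
    data=st.data(),
)
def test_canonical_form_round_trips(primary, data):
    """parse_tag(format_tag(t)) == t for every representable tag."""
    if primary == "EMPTY":
        tag = EmotionTag("EMPTY")
    else:
        codes = data.draw(
            st.lists(st.sampled_from(CODES_FOR_PRIMARY[primary]), unique=True, max_size=3)
        )
        tag = EmotionTag(primary, tuple(codes))
    assert parse_tag(format_tag(tag)) == tag
    assert "(" not in format_tag(EmotionTag("EMPTY"))


def _write_read(corpus, tmp_path):
    cdir = tmp_path / "corpus"
    meta = tmp_path / "metadata.tsv"
    write_corpus(corpus, cdir, meta)
    return read_corpus(cdir, meta)


def test_minimal_corpus_reads(tmp_path):
    (tmp_path / "corpus").mkdir()
    (tmp_path / "corpus" / "p1.txt").write_text("++SAD(NB)++\nI cried all the way.\n")
    (tmp_path / "metadata.tsv").write_text(
        "id\tgroup\tgender\tmarital_status\tage\tdays_in_hospital\n"
        "p1\tpatient\tfemale\tmarried\t30\t14\n"
    )
    corpus = read_corpus(tmp_path / "corpus", tmp_path / "metadata.tsv")
    assert len(corpus) == 1
    p = corpus.participants[0]
    assert p.id == "p1" and p.group == "patient" and p.age == 30
    assert len(p.narratives) == 1
    assert p.narratives[0].tag == EmotionTag("SAD", ("NB",))
    assert p.narratives[0].text == "I cried all the way."


def test_text_on_tag_line_after_colon(tmp_path):
    (tmp_path / "corpus").mkdir()
    (tmp_path / "corpus" / "p1.txt").write_text("++SAD(NB)++: I cried. All the way.\n")
    (tmp_path / "metadata.tsv").write_text(
        "id\tgroup\tgender\tmarital_status\tage\tdays_in_hospital\np1\tpatient\t\t\t\t\n"
    )
    corpus = read_corpus(tmp_path / "corpus", tmp_path / "metadata.tsv")
    assert corpus.participants[0].narratives[0].text == "I cried. All the way."


@pytest.mark.parametrize(
    "content, match",
    [
        ("++SAD(NB)++\n++HAPPY(PA)++\ntext\n", "no narrative text"),
        ("stray text\n++SAD(NB)++\ntext\n", "before first tag"),
        ("just prose, never a tag\n", "before first tag"),
    ],
)
def test_malformed_participant_files(tmp_path, content, match):
    (tmp_path / "corpus").mkdir()
    (tmp_path / "corpus" / "p1.txt").write_text(content)
    (tmp_path / "metadata.tsv").write_text(
        "id\tgroup\tgender\tmarital_status\tage\tdays_in_hospital\np1\tpatient\t\t\t\t\n"
    )
    with pytest.raises(CorpusFormatError, match=match):
        read_corpus(tmp_path / "corpus", tmp_path / "metadata.tsv")


def test_metadata_file_mismatch(tmp_path):
    (tmp_path / "corpus").mkdir()
    (tmp_path / "corpus" / "p1.txt").write_text("++SAD(NB)++\ntext.\n")
    (tmp_path / "metadata.tsv").write_text(
        "id\tgroup\tgender\tmarital_status\tage\tdays_in_hospital\n"
        "p1\tpatient\t\t\t\t\np2\tcontrol\t\t\t\t\n"
    )
    with pytest.raises(CorpusFormatError, match="no corpus file"):
        read_corpus(tmp_path / "corpus", tmp_path / "metadata.tsv")


def test_days_in_hospital_patient_only():
    with pytest.raises(CorpusFormatError, match="days_in_hospital"):
        Participant(id="c1", group="control", days_in_hospital=10.0)


def test_round_trip_identity_on_generated_corpus(small_bundle, tmp_path):
    """write_corpus then read_corpus preserves every field of every narrative."""
    original = small_bundle.corpus
    restored = _write_read(original, tmp_path)
    assert len(restored) == len(original)
    for p0, p1 in zip(original, restored):
        assert (p0.id, p0.group, p0.gender, p0.marital_status, p0.age,
                p0.days_in_hospital) == (p1.id, p1.group, p1.gender,
                                         p1.marital_status, p1.age, p1.days_in_hospital)
        assert len(p0.narratives) == len(p1.narratives)
        for n0, n1 in zip(p0.narratives, p1.narratives):
            assert n0.tag == n1.tag
            assert n0.text == n1.text
            assert n0.ordinal == n1.ordinal


def test_round_trip_preserves_per_emotion_narrative_counts(small_bundle, tmp_path):
    restored = _write_read(small_bundle.corpus, tmp_path)
    def tally(corpus):
        out = {}
        for p in corpus:
            for n in p.narratives:
                out[(p.group, n.tag.primary)] = out.get((p.group, n.tag.primary), 0) + 1
        return out
    assert tally(restored) == tally(small_bundle.corpus)
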
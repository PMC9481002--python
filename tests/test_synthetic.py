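"""Generator determinism, truth bookkeeping, and preset calibration."""

import numpy as np
import pytest
from scipy import stats

from narramine import synthetic
from narramine.lexicon import CODES, PRIMARY_EMOTIONS


def _tiny_config(**overrides):
    cfg = synthetic.symmetric_preset(n_participants=2, narrative_rate=2.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def test_same_seed_same_corpus():
    cfg = _tiny_config()
    b1 = synthetic.generate(cfg, seed=11)
    b2 = synthetic.generate(cfg, seed=11)
    texts1 = [(p.id, n.tag, n.text) for p in b1.corpus for n in p.narratives]
    texts2 = [(p.id, n.tag, n.text) for p in b2.corpus for n in p.narratives]
    assert texts1 == texts2
    assert b1.truth == b2.truth


def test_different_seed_different_corpus():
    cfg = _tiny_config()
    b1 = synthetic.generate(cfg, seed=1)
    b2 = synthetic.generate(cfg, seed=2)
    assert [n.text for p in b1.corpus for n in p.narratives] != [
        n.text for p in b2.corpus for n in p.narratives
    ]


def test_zero_rates_give_pure_background():
    cfg = _tiny_config()
    for g in cfg.groups.values():
        g.stopword_rate = 0.0
        g.code_emission = {c: 0.0 for c in CODES}
    b = synthetic.generate(cfg, seed=3)
    lex_words = {e.word for e in b.lexicon}
    tokens = [t for p in b.corpus for n in p.narratives
              for t in n.text.replace(".", " ").split()]
    assert not (set(tokens) & lex_words)
    assert not (set(tokens) & b.stoplist)
    assert all(v == 0 for g in b.truth.code_counts.values() for v in g.values())


def test_truth_channels_sum_to_token_totals(small_bundle):
    t = small_bundle.truth
    for g in ("patient", "control"):
        channels = (
            t.stopword_counts[g]
            + sum(t.code_counts[g].values())
            + sum(t.marker_counts[g].values())
            + t.background_counts[g]
        )
        assert channels == t.token_totals[g]
        assert t.filtered_token_totals[g] == t.token_totals[g] - t.stopword_counts[g]


def test_narrative_tags_match_generating_emotion(small_bundle):
    """Tag counts in the corpus equal the truth's per-emotion narrative counts."""
    tally = {g: {} for g in ("patient", "control")}
    for p in small_bundle.corpus:
        for n in p.narratives:
            tally[p.group][n.tag.primary] = tally[p.group].get(n.tag.primary, 0) + 1
            if not n.tag.is_empty:
                assert len(n.tag.subcategories) == 1
    for g in tally:
        truth = {e: c for e, c in small_bundle.truth.narrative_counts[g].items() if c}
        assert tally[g] == truth


def test_infeasible_config_rejected():
    cfg = _tiny_config()
    next(iter(cfg.groups.values())).stopword_rate = 0.99
    with pytest.raises(ValueError, match="> 1"):
        synthetic.generate(cfg, seed=0)


def test_study_preset_shape():
    cfg = synthetic.study_preset()
    assert cfg.groups["patient"].n_participants == 34
    assert cfg.groups["control"].n_participants == 24
    # means of 1+Poisson match the target sentence/narrative shapes
    assert 1 + cfg.groups["patient"].token_rate["SAD"] == pytest.approx(23.7)
    assert 1 + cfg.groups["control"].token_rate["SAD"] == pytest.approx(19.5)
    assert 1 + cfg.groups["patient"].sentence_rate["SAD"] == pytest.approx(2.41)
    assert 1 + cfg.groups["control"].sentence_rate["SAD"] == pytest.approx(4.11)
    for c in ("NC", "NE", "NN", "PA", "PG", "PB"):
        assert (cfg.groups["patient"].code_emission[c]
                > cfg.groups["control"].code_emission[c])


def test_study_preset_token_totals_land_near_targets():
    """Realized group totals stay within 5% of the 168k/121k calibration."""
    cfg = synthetic.study_preset()
    targets = {"patient": 167795, "control": 121372}
    for g, target in targets.items():
        assert synthetic.expected_token_total(cfg, g) == pytest.approx(target, rel=0.02)
    totals = {g: [] for g in targets}
    for seed in range(10):
        b = synthetic.generate(cfg, seed=seed)
        for g in targets:
            totals[g].append(b.truth.token_totals[g])
    for g, target in targets.items():
        assert np.mean(totals[g]) == pytest.approx(target, rel=0.05)


def test_code_frequency_recovery_within_binomial_ci():
    """Realized per-code counts sit in exact binomial 99% intervals of p_c."""
    b = synthetic.generate(synthetic.symmetric_preset(n_participants=5), seed=13)
    misses = 0
    for g, gp in b.config.groups.items():
        n = b.truth.token_totals[g]
        assert n >= 10000
        for c in CODES:
            k = b.truth.code_counts[g][c]
            lo = stats.binom.ppf(0.005, n, gp.code_emission[c])
            hi = stats.binom.ppf(0.995, n, gp.code_emission[c])
            misses += not (lo <= k <= hi)
    assert misses <= 1  # 42 conservative 99% intervals


def test_save_bundle_round_trips_through_corpus_io(small_bundle, tmp_path):
    from narramine import load_lexicon, load_stoplist, read_corpus

    paths = synthetic.save_bundle(small_bundle, tmp_path)
    corpus = read_corpus(paths["corpus"], paths["metadata"])
    assert len(corpus) == len(small_bundle.corpus)
    lex = load_lexicon(paths["lexicon"])
    assert [ (e.word, e.code, e.polarity) for e in lex ] == [
        (e.word, e.code, e.polarity) for e in small_bundle.lexicon ]
    assert load_stoplist(paths["stoplist"]) == small_bundle.stoplist
    assert paths["truth"].exists()


def test_lexicon_covers_all_codes(small_bundle):
    per_code = {c: 0 for c in CODES}
    for e in small_bundle.lexicon:
        per_code[e.code] += 1
    assert all(v == small_bundle.config.words_per_code for v in per_code.values())
    pc_pols = {e.polarity for e in small_bundle.lexicon if e.code == "PC"}
    assert pc_pols == {"positive", "negative"}
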
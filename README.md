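# narramine

Text mining of emotion-tagged narrative corpora — for psycholinguists and
clinical researchers comparing the emotional discourse of two groups of
speakers (e.g. patients vs healthy controls) from interview transcripts.

Interview narratives are annotated as discourse units with line-initial
tags `++EMOTION(CODE)++`, where the emotion is one of HAPPY, SAD, ANGRY,
FEAR, DISGUST (or EMPTY for unemotional units) and the codes come from a
21-subcategory affect taxonomy that rolls up to the five primaries and a
binary polarity.  From such a corpus the package computes:

* **Narrative-complexity features** per participant — type-token ratio
  (TTR = distinct word forms / total tokens), mean word-length,
  words/sentence, sentences/narrative, words/narrative — compared across
  groups with a two-tailed Welch (unequal-variance) t-test on raw and
  pooled min-max-normalized values.  With sample means m̄ᵢ, variances sᵢ²
  and sizes nᵢ,

      t = (m̄₁ − m̄₂) / √(s₁²/n₁ + s₂²/n₂),
      df = (s₁²/n₁ + s₂²/n₂)² / [(s₁²/n₁)²/(n₁−1) + (s₂²/n₂)²/(n₂−1)].

* **Emotion-word frequency profiles** — conditional frequency
  distributions of affect-lexicon words per group at three levels
  (polarity / 5 primaries / 21 subcategories), on stopword-filtered
  tokens, absolute and per 1,000 tokens.

* **Keyness** — words distinctive of one group via the two-cell
  log-likelihood ratio.  For a word observed O₁ times in N₁ focal tokens
  and O₂ times in N₂ reference tokens, with Eᵢ = Nᵢ(O₁+O₂)/(N₁+N₂),

      LL = −2 ln λ = 2·[O₁ ln(O₁/E₁) + O₂ ln(O₂/E₂)],

  with x ln x → 0 for a zero cell; LL ≥ 15.13 (the chi-square 1-df
  quantile at p = 10⁻⁴, truncated) marks a significant key word, signed
  "+"/"−" for overuse/underuse in the focal corpus.

* **Synthetic corpora** — a seeded generator emitting the full corpus
  dialect with exact ground truth (per-code emission counts, marker-word
  injections, token totals), so every pipeline stage is testable against
  known parameters.

## Worked example

```python
from narramine import emotion_keyness, feature_comparison_table, synthetic

bundle = synthetic.generate(synthetic.study_preset(), seed=1)
comp = feature_comparison_table(bundle.corpus)   # t sign: patient − control
print(comp.features.query("variant == 'raw'")[["feature", "mean1", "mean2", "t", "p"]])

res = emotion_keyness(bundle.corpus, "SAD")
print(res.table.head(3))
```

prints (seed 1):

```
                   feature      mean1      mean2          t             p
0                      ttr   0.173128   0.176292  -0.797484  4.297819e-01
2         mean_word_length   3.291455   3.301839  -2.273128  2.767534e-02
4       words_per_sentence  23.682979  19.497348  63.424789  9.540237e-54
6  sentences_per_narrative   2.381801   4.077442 -30.002140  6.346090e-23
8      words_per_narrative  56.407529  79.496830 -20.215632  1.977523e-19

        word         ll  freq1      rel1  freq2      rel2 sign  significant
0  isolation  57.560998     90  0.275997      8  0.033351    +         True
1       this  17.401743    167  0.512129     69  0.287656    +         True
2       mopi  16.838980     43  0.131865      8  0.033351    +         True
```

The generator's preset gives patients longer sentences (means 23.7 vs
19.5 words) but shorter narratives (2.41 vs 4.11 sentences), and the
Welch comparison recovers both directions decisively; `isolation`, the
marker word injected into patient SAD narratives at a 10× rate ratio,
tops the SAD keyness table far above the 15.13 cutoff.  The scripts in
`examples/` walk through each capability (simulation, features,
frequency profiles, keyness) with commentary.

A thin CLI mirrors the stages:

```bash
narramine simulate --preset study --seed 7 --out run/
narramine features --corpus run/corpus --metadata run/metadata.tsv --out run/tables
narramine keyness  --corpus run/corpus --metadata run/metadata.tsv --emotion SAD --out run/tables
```

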
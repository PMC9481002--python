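# Methods

## The analysis model

The package operates on a corpus of interview narratives from two groups
of speakers.  Each narrative is a contiguous discourse unit annotated
with one primary emotion — HAPPY, SAD, ANGRY, FEAR, DISGUST — plus
optional subcategory codes, or EMPTY when no emotion applies.  The
21-code affect taxonomy partitions into the primaries as HAPPY = {PA,
PE, PD, PH, PG, PB, PK}, ANGRY = {NA}, SAD = {NB, NJ, NH, PF}, FEAR =
{NI, NC, NG, NE, NL}, DISGUST = {ND, NN, NK}, with the dual code PC
(surprise) resolving to HAPPY when an entry is positive and FEAR when
negative.  Polarity defaults to positive exactly for the HAPPY-mapped
codes; PF (grief) keeps its negative polarity despite the P prefix, as
in the source scheme.

Three analyses sit on top:

1. **Generic features.**  Per participant, over the concatenation of all
   non-EMPTY narratives: TTR, mean word-length (characters/token),
   words/sentence, sentences/narrative, words/narrative, and
   words/narrative restricted to each primary emotion.  TTR is one value
   per participant (not per narrative), so the group comparison has one
   observation per speaker and ~n₁+n₂−2 nominal degrees of freedom.
   Features use unfiltered tokens (stopwords retained); tokens are
   whatever the configured tokenizer emits, with punctuation-only tokens
   discarded.
2. **Emotion-word frequencies.**  Counts of lexicon words in
   stopword-filtered token streams, conditioned on group, at polarity /
   primary5 / sub21 levels.  A token with several lexicon codes counts
   once per code at sub21 but exactly once at aggregated levels via its
   first-listed entry — this convention makes the aggregate levels
   conserved (Σ primaries = Σ polarities = once-per-token emotional
   total) and is deterministic given lexicon file order.  Absolute
   counts and per-1,000-token rates are both emitted; the rates are the
   comparable quantity across unequal corpora.
3. **Keyness.**  The two-cell log-likelihood ratio per word type, as
   defined in the README.  The two-cell form (summing over the two
   corpora only, not all four cells of the 2×2 table) is implemented
   deliberately: it is the form used by the corpus-linguistics tools
   this package mirrors, and it differs numerically from the four-cell
   G² (e.g. ~52.5 vs ~53.1 on a 178/226 contingency).  The significance
   cutoff is the chi-square 1-df quantile at 1−α truncated to two
   decimals, reproducing the conventional 15.13 at α = 10⁻⁴ (exact
   quantile 15.1367); truncation vs rounding is selectable.

## Statistical conventions

* **Welch's t** is computed from first-principles sums (n−1 variance
  denominators, Welch–Satterthwaite df, two-tailed Student-t tail).  The
  sign convention is t = mean(group1) − mean(group2) with group order an
  explicit argument, default (patient, control).  Published tables of
  this design disagree internally on sign; fixing one convention and
  documenting it is the only consistent option.
* **Min-max normalization** is pooled across both groups per feature.
  Because it is affine, raw and normalized rows share t, df and p
  exactly; the package asserts this to 1e-9 rather than printing
  near-duplicates blindly.  (A reference table whose raw and normalized
  TTR means reverse order under identical t is arithmetically impossible
  under a pooled affine map and is treated as a typo, not a target.)
* **Keyness defaults**: pooled minimum frequency 5 (singleton keys are
  admissible at min_freq = 1, matching published tables that include
  1-occurrence words); stopwords retained in keyness streams (function
  words are often the strongest keys); relative frequencies are reported
  as percentages at full precision and formatted to 2 decimals only at
  display time; ranking is LL descending with ties broken by pooled
  frequency then lexicographically.
* **Zero cells** contribute zero to the LL sum (x ln x → 0), keeping the
  statistic finite for words absent from one corpus.
* **p-values** are reported without multiple-testing correction,
  matching standard keyness practice; the keyness α is configurable.

## The synthetic-data generator

The generator emulates the study shape the package is designed for: two
cohorts (default 34 patients, 24 controls) of telephone-interview
narratives.  Per participant and emotion, narrative count ~
Poisson(λ_{g,e}); sentences/narrative ~ 1+Poisson(ν_{g,e});
tokens/sentence ~ 1+Poisson(μ_{g,e}).  Each token is independently a
stopword (probability q), an emotion word of code c (probability
p_{g,c}, uniform over that code's lexicon words), an injected marker
word (in narratives of the marker's emotion only), or a background word
from a Zipf(s = 1.1) vocabulary of 1,500 pseudo-words.  Narratives are
tagged with their generating emotion (annotation treated as
oracle-perfect); the subcategory is the modal emitted eligible code, or
the emotion's first canonical code when none was emitted.  EMPTY
narratives are added at 5% of the emotional narrative rate to exercise
their exclusion path: they are excluded from generic features and
per-emotion statistics but count toward whole-corpus token totals and
frequency-profile denominators.

The **study-shape preset** calibrates expectations to the cohort it
emulates: group token totals near 167,795 / 121,372; words/sentence
means 23.7 vs 19.5 (μ = 22.7 / 18.5); sentences/narrative 2.41 vs 4.11
(ν = 1.41 / 3.11); per-group stopword rates 0.154 / 0.123 (the observed
raw-to-filtered corpus shrinkage); per-code emission 0.004, inflated to
0.006 in patients for NC, NE, NN, PA, PG, PB (the reported direction of
patient overuse); and two marker words injected into patient SAD and
FEAR narratives at 0.3% vs 0.03% per token (a 10× ratio at ≥0.3% base
rate).  The narrative rate λ is derived analytically from these targets
rather than tuned.  A **symmetric preset** shares every rate between
groups (8 participants each, ≈26k expected tokens/group) for null
calibration runs.

Pseudo-words are consonant-vowel syllable strings with syllable count ~
1+Poisson(0.5) (so 2, 4, 6… characters, mean ≈ 3).  A per-word
*character* count of 1+Poisson(0.5) cannot yield the thousands of
distinct word forms the vocabulary needs (61% of words would be single
characters), so the length distribution is applied at the syllable
level; mean word-length remains a nondegenerate feature, merely on a
different scale than a logographic script.

What the generator does **not** emulate: discourse coherence, topical
structure, annotator disagreement, within-participant rate
heterogeneity, and grammatical word order — every token is exchangeable
within its narrative.  Passing tests therefore demonstrate that the
pipeline's counting, statistics and bookkeeping are correct under known
emission rates, not that the features discriminate real clinical groups.

## Verification design

Every stage is tested against an independent route: Welch's t against
scipy's unequal-variance t-test; the LL statistic against a
first-principles expansion of the formula summed with compensated
addition (1e-9 agreement on 1,000 random tables); the published
SAD-narrative keyness table recomputed from its printed frequencies
using sub-corpus totals implied by the printed relative frequencies
(n₁ = 28,200, n₂ = 17,360), reproducing all 16 printed LL values within
5%; generator output against its own exact truth bookkeeping (binomial
99% interval coverage of per-code counts); and a 100-seed null
simulation bounding the fraction of spuriously significant key words at
the α = 10⁻⁴ cutoff.  Simulation-based checks use 100 seeds of the
study-shape preset (~290k tokens per realization), sizes chosen so the
full suite runs in a few minutes on one CPU.

## Known limitations

* Exact surface-form lexicon matching: no lemmatization, stemming or
  negation-scope handling (bag-of-words by design — a narrative of
  happiness about overcoming fear will contribute fear-words).
* TTR is length-sensitive; length-corrected indices (MATTR, MTLD) are
  out of scope.
* The default tokenizer is whitespace-based; logographic scripts need an
  external segmenter plugged in via `register_tokenizer`.
* The keyness candidate universe and minimum-frequency policy of
  published tables are rarely stated; both are configurable rather than
  fixed.
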
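"""Narrative-complexity features with Welch two-group comparison.

Computes per-participant type-token ratio, mean word-length, words per
sentence, sentences per narrative and words per narrative, then compares
the groups with a two-tailed Welch t-test on raw and pooled
min-max-normalized values (the t and p of the two variants coincide
because min-max is an affine map).
"""

import pandas as pd

from narramine import feature_comparison_table, synthetic

bundle = synthetic.generate(synthetic.study_preset(), seed=1)
comp = feature_comparison_table(bundle.corpus)  # sign: patient minus control

pd.set_option("display.width", 120)
print(comp.features[["feature", "variant", "mean1", "mean2", "t", "df", "p"]]
      .round(4).to_string(index=False))
print()
print(comp.per_emotion[["feature", "mean1", "mean2", "t", "df", "p"]]
      .round(4).to_string(index=False))

# Positive t on words/sentence: patients pack more words into a sentence
# (preset means 23.7 vs 19.5).  Negative t on sentences/narrative and
# words/narrative: patient narratives are shorter (2.41 vs 4.11 sentences).
# The per-emotion table breaks words/narrative down by narrative tag.
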
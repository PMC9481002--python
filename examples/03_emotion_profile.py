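"""Emotion-word frequency profiles by group.

Counts affect-lexicon words in the stopword-filtered token streams at
three condition levels — polarity, the five primary emotions, and the 21
subcategory codes — reporting absolute counts and counts per 1,000
filtered tokens so the unequal-sized groups compare fairly.
"""

from narramine import profile_report, synthetic

bundle = synthetic.generate(synthetic.study_preset(), seed=1)
report = profile_report(bundle.corpus, bundle.lexicon, bundle.stoplist)

print("-- polarity --")
print(report["polarity"].round(2).to_string(index=False))
print("-- five primary emotions --")
print(report["primary5"].round(2).to_string(index=False))
print("-- top 8 of 21 subcategories (by patient count) --")
print(report["sub21"].head(8).round(2).to_string(index=False))

# The preset inflates patient emission of NC, NE, NN, PA, PG and PB, so
# those codes — and their primaries FEAR, DISGUST and HAPPY — lead the
# patient columns in per-1,000-token terms.
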
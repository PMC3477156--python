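"""Compute the predictor battery for the test pairs of one condition.

Shows the repetition-coding operators on the classic token strings,
then builds the chunk/repetition and gapped-bigram feature matrices
whose per-pair differences feed the choice regressions.
"""

from aglab import (
    CorpusStatistics,
    build_stimulus_set,
    feature_matrix,
    global_repetition_code,
    local_repetition_code,
)

print("adjacent repetition code of AABBCC:", local_repetition_code("AABBCC"))
print("global repetition code of AABBCC:  ", global_repetition_code("AABBCC"))
print("ABABC and BCBCD share the global code:",
      global_repetition_code("ABABC"), "==",
      global_repetition_code("BCBCD"))

design = build_stimulus_set("centre-left", seed=7)
stats = CorpusStatistics.from_corpus(design.training)

fm = feature_matrix(design.pairs, stats, "chunk-rep")
print(f"\nchunk/repetition predictor matrix: {fm.shape[0]} pairs x "
      f"{fm.shape[1]} predictors")
print(fm.describe().loc[["mean", "std"]].round(2).to_string())

fm4 = feature_matrix(design.pairs, stats, "gapped")
print(f"\ngapped-bigram predictor matrix: {fm4.shape[0]} pairs x "
      f"{fm4.shape[1]} predictors")
# Each value is grammatical-minus-ungrammatical: positive chunk
# differences mean the grammatical member is made of more familiar
# word/class n-grams, so a chunk-sensitive learner favours it.
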
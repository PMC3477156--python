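"""Build one condition's full stimulus bundle and inspect its parts.

Constructs the training corpus (168 sentences), the control corpus,
and the 66 length-matched test pairs for the tail-embedding
right-branching grammar, then prints the count structure and one
violation example.
"""

from collections import Counter

from aglab import build_stimulus_set

design = build_stimulus_set("tail-right", seed=7)

by_layer = Counter(s.source.n_layers for s in design.training)
print(f"training sentences: {len(design.training)} "
      f"(by layer: {by_layer[1]}/{by_layer[2]}/{by_layer[3]})")
print(f"old structures: {len(design.old)}, new structures: {len(design.new)}")

u_status = Counter(p.ungrammatical.status for p in design.pairs)
g_status = Counter(p.grammatical.status for p in design.pairs)
print(f"test pairs: {len(design.pairs)} "
      f"({u_status['layer-ungrammatical']} layer violations + "
      f"{u_status['random-ungrammatical']} random; "
      f"{g_status['old-grammatical']} old + "
      f"{g_status['new-grammatical']} new grammatical)")

nonlocal_n = sum(1 for p in design.pairs
                 if p.ungrammatical.locality == "nonlocal")
print(f"nonlocal (long-distance) violation trials: {nonlocal_n}")

pair = next(p for p in design.pairs
            if p.ungrammatical.locality == "nonlocal")
print("\nexample nonlocal pair (equal length by construction):")
print("  grammatical:  ", " ".join(pair.grammatical.words),
      "  <-", " ".join(pair.grammatical.classes))
print("  ungrammatical:", " ".join(pair.ungrammatical.words),
      "  <-", " ".join(pair.ungrammatical.classes),
      f" (layer {pair.ungrammatical.violated_layer} violated)")
# A nonlocal violation rewrites a layer that is split by correctly
# embedded material, so detecting it requires a long-distance
# dependency across the intervening clause.
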
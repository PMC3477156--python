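"""Enumerate the abstract structures of one grammar and parse strings.

Builds the centre-embedding left-branching grammar, lists its 18
word-class structures with embedding-layer annotation, and checks two
sequences for grammaticality.
"""

from aglab import enumerate_structures, make_grammar, parse

grammar = make_grammar("centre-left")
structures = enumerate_structures(grammar)

print(f"{grammar.variant}: {len(structures)} abstract structures\n")
for s in structures:
    layers = "".join(map(str, s.layers))
    print(f"  {s.class_string():<18} layers {layers}  ({s.n_layers}-layer)")

# A grammatical sequence: main clause "N V ... N" wrapped around the
# embedded clause "V N R"; and the same string with its main clause
# scrambled, which no derivation covers.
for string in ("N V V N R N", "V N V N R N"):
    res = parse(grammar, string.split())
    verdict = "grammatical" if res.grammatical else "ungrammatical"
    print(f"\n'{string}' is {verdict}", end="")
    if res.grammatical:
        print(f" with layers {res.layers}", end="")
print()
# The 18 structures per grammar and the 2/10/6 one-/two-/three-layer
# profile are the fixed inventory every stimulus set is built from.
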
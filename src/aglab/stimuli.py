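"""Stimulus construction: lexicon, training corpus, and test pairs.

The study design instantiates abstract word-class structures with a
9-word monosyllabic lexicon (4 nouns, 4 verbs, 1 relative marker),
splits the 18 structures of a grammar into *old* (trained) and *new*
(generalisation) sets, builds a 168-sentence training corpus, and
assembles 66 test pairs, each pairing a grammatical sentence with a
length-matched ungrammatical one.

Two kinds of ungrammatical items are constructed:

* **layer violations** rewrite the tokens of exactly one embedding
  layer by an invalid same-length pattern, leaving every other layer
  untouched.  When the violated layer is intermitted by correctly
  embedded material, detecting the violation requires a long-distance
  (nonlocal) dependency.
* **random-ungrammatical** items permute the class multiset of a
  grammatical template until the result no longer parses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .grammar import (
    AbstractStructure,
    Grammar,
    layer_spans,
    parse,
)

__all__ = [
    "Lexicon",
    "DEFAULT_LEXICON",
    "Sentence",
    "TestPair",
    "StimulusSet",
    "split_old_new",
    "instantiate",
    "build_training_corpus",
    "violate_layer",
    "layer_violation_options",
    "build_layer_violation_set",
    "make_random_ungrammatical",
    "tag_locality",
    "build_test_set",
    "build_control_corpus",
    "build_stimulus_set",
]

# Per-layer instantiation multipliers for the training corpus:
# 1-layer structures x8, 2-layer x16, 3-layer x24 (deeper structures
# are repeated more because they are plausibly harder to learn).
TRAINING_MULTIPLIERS = {1: 8, 2: 16, 3: 24}


@dataclass(frozen=True)
class Lexicon:
    """Class -> word-list mapping; words are disjoint across classes."""

    words: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        all_words = [w for ws in self.words.values() for w in ws]
        if len(all_words) != len(set(all_words)):
            raise ValueError("lexicon word lists must be disjoint")

    def class_of(self, word: str) -> str:
        for cls, ws in self.words.items():
            if word in ws:
                return cls
        raise KeyError(word)

    def __getitem__(self, cls: str) -> tuple[str, ...]:
        try:
            return self.words[cls]
        except KeyError:
            raise KeyError(f"lexicon has no class {cls!r}") from None


#: The nine monosyllabic words of the study, assigned 4/4/1 to N/V/R.
DEFAULT_LEXICON = Lexicon(
    words={
        "N": ("wao", "yai", "piu", "shin"),
        "V": ("bam", "fai", "ti", "ra"),
        "R": ("ki",),
    }
)


@dataclass(frozen=True)
class Sentence:
    """A word sequence with its class sequence and stimulus metadata."""

    words: tuple[str, ...]
    classes: tuple[str, ...]
    status: str  # old-grammatical | new-grammatical |
    # layer-ungrammatical | random-ungrammatical
    source: AbstractStructure | None = None
    violated_layer: int | None = None
    locality: str = "n/a"  # local | nonlocal | n/a

    def __post_init__(self) -> None:
        if len(self.words) != len(self.classes):
            raise ValueError("words and classes must have equal length")
        if self.status == "layer-ungrammatical" and (
            self.violated_layer is None or self.source is None
        ):
            raise ValueError(
                "layer-ungrammatical sentences need violated_layer and source"
            )

    def __len__(self) -> int:
        return len(self.words)

    @property
    def grammatical(self) -> bool:
        return self.status in ("old-grammatical", "new-grammatical")

    def to_record(self) -> dict:
        return {
            "words": " ".join(self.words),
            "classes": " ".join(self.classes),
            "status": self.status,
            "violated_layer": self.violated_layer,
            "locality": self.locality,
            "source": (
                self.source.class_string() if self.source is not None else None
            ),
        }


@dataclass(frozen=True)
class TestPair:
    __test__ = False  # not a pytest class, despite the name

    pair_id: int
    grammatical: Sentence
    ungrammatical: Sentence

    def __post_init__(self) -> None:
        if len(self.grammatical) != len(self.ungrammatical):
            raise ValueError(
                "pair members must match in length: "
                f"{len(self.grammatical)} vs {len(self.ungrammatical)}"
            )


# ---------------------------------------------------------------------------
# Layer-violation substitution tables
# ---------------------------------------------------------------------------
# The table below is printed for the centre-embedding left-branching
# grammar; main-clause (layer 1) contents are the same strings in all
# four grammars, so the layer-1 entries are shared.  Embedded-clause
# (CP) contents mirror between left- and right-branching grammars, so
# the right-branching entries are the token reversals of the
# left-branching ones; the tail-left "N V R" entry applies the same
# two edits (noun -> verb substitution; one-step rotation) as the
# printed "V N R" entry.  Every substitution is asserted ungrammatical
# in context by the parser.

_LAYER1_VIOLATIONS = {
    ("N", "V", "N"): (("V", "N", "N"), ("N", "R", "V")),
    ("N", "V"): (("R", "V"), ("V", "N")),
}

_CP_VIOLATIONS = {
    "centre-left": {
        ("V", "N", "R"): (("V", "V", "R"), ("N", "R", "V")),
        ("V", "R"): (("R", "V"), ("N", "R")),
    },
    "centre-right": {  # mirror of centre-left
        ("R", "N", "V"): (("R", "V", "V"), ("V", "R", "N")),
        ("R", "V"): (("V", "R"), ("R", "N")),
    },
    "tail-left": {
        ("N", "V", "R"): (("V", "V", "R"), ("V", "R", "N")),
        ("V", "R"): (("R", "V"), ("N", "R")),
    },
    "tail-right": {  # mirror of tail-left
        ("R", "V", "N"): (("R", "V", "V"), ("N", "R", "V")),
        ("R", "V"): (("V", "R"), ("R", "N")),
    },
}


def _layer_constituents(
    structure: AbstractStructure, layer: int
) -> list[tuple[int, ...]]:
    """Violable constituents at ``layer``: the main clause for layer 1,
    otherwise one entry per CP at that layer (sibling CPs are separate
    constituents).  Each entry lists the constituent's direct token
    positions."""
    from .grammar import cp_constituents

    if layer > structure.n_layers:
        raise ValueError(
            f"structure has {structure.n_layers} layers; cannot violate "
            f"layer {layer}"
        )
    if layer == 1:
        return [
            tuple(i for i, l in enumerate(structure.layers) if l == 1)
        ]
    return [
        pos for lay, pos in cp_constituents(structure) if lay == layer
    ]


def layer_violation_options(
    structure: AbstractStructure, layer: int, grammar: Grammar
) -> tuple[tuple[str, ...], ...]:
    """All violated class sequences for one layer of a structure.

    One constituent of the layer (the main clause, or a single CP) has
    its direct tokens rewritten in place by a substitution-table
    entry; all other tokens are untouched, so the result has the same
    length and differs only within the violated constituent.  Each
    result is verified ungrammatical by the parser.  Layers realised
    by a single constituent yield exactly the two tabled forms.
    """
    table = (
        _LAYER1_VIOLATIONS if layer == 1 else _CP_VIOLATIONS[grammar.variant]
    )
    out = []
    for positions in _layer_constituents(structure, layer):
        content = tuple(structure.classes[i] for i in positions)
        if content not in table:
            raise KeyError(
                f"no violation entry for constituent content "
                f"{' '.join(content)} ({grammar.variant})"
            )
        for repl in table[content]:
            seq = list(structure.classes)
            for pos, cls in zip(positions, repl):
                seq[pos] = cls
            seq = tuple(seq)
            assert not parse(grammar, seq).grammatical, (
                "violation table produced a grammatical sequence: "
                f"{' '.join(seq)} from {structure.class_string()} "
                f"layer {layer}"
            )
            out.append(seq)
    return tuple(out)


def violate_layer(
    structure: AbstractStructure,
    layer: int,
    grammar: Grammar,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], str]:
    """One violated class sequence for ``layer`` plus its locality tag.

    The constituent (when the layer holds two sibling CPs) and the
    substitution are chosen by ``rng``.
    """
    constituents = _layer_constituents(structure, layer)
    positions = constituents[int(rng.integers(len(constituents)))]
    table = (
        _LAYER1_VIOLATIONS if layer == 1 else _CP_VIOLATIONS[grammar.variant]
    )
    content = tuple(structure.classes[i] for i in positions)
    options = table[content]
    repl = options[int(rng.integers(len(options)))]
    seq = list(structure.classes)
    for pos, cls in zip(positions, repl):
        seq[pos] = cls
    seq = tuple(seq)
    assert not parse(grammar, seq).grammatical
    return seq, _positions_locality(positions)


def _positions_locality(positions: Sequence[int]) -> str:
    contiguous = all(
        b - a == 1 for a, b in zip(positions, positions[1:])
    )
    return "local" if contiguous else "nonlocal"


def tag_locality(structure: AbstractStructure, layer: int) -> str:
    """``nonlocal`` iff the layer's (sole) violable constituent is
    intermitted by embedded material.

    The main clause is nonlocal when a centre-attached CP splits it;
    a CP is nonlocal when a nested CP splits its direct content.  For
    a layer held by two sibling CPs each CP is contiguous, hence
    local.
    """
    if any(
        _positions_locality(pos) == "nonlocal"
        for pos in _layer_constituents(structure, layer)
    ):
        return "nonlocal"
    return "local"


# ---------------------------------------------------------------------------
# Old/new split and instantiation
# ---------------------------------------------------------------------------

def split_old_new(
    structures: Sequence[AbstractStructure], rng: np.random.Generator
) -> tuple[list[AbstractStructure], list[AbstractStructure]]:
    """Split the 18 structures into 10 old and 8 new.

    Both 1-layer structures go to the old set; the ten 2-layer and six
    3-layer structures are split half-half at random.
    """
    by_layer = {
        k: sorted(g)
        for k, g in itertools.groupby(
            sorted(structures, key=lambda s: s.n_layers),
            key=lambda s: s.n_layers,
        )
    }
    if {k: len(v) for k, v in by_layer.items()} != {1: 2, 2: 10, 3: 6}:
        raise ValueError(
            "expected the full 18-structure set (2/10/6 by layer); got "
            + str({k: len(v) for k, v in by_layer.items()})
        )
    old = list(by_layer[1])
    new: list[AbstractStructure] = []
    for depth, n_old in ((2, 5), (3, 3)):
        pool = by_layer[depth]
        chosen = set(rng.permutation(len(pool))[:n_old].tolist())
        old.extend(s for i, s in enumerate(pool) if i in chosen)
        new.extend(s for i, s in enumerate(pool) if i not in chosen)
    return sorted(old), sorted(new)


def instantiate(
    classes: Sequence[str] | AbstractStructure,
    lexicon: Lexicon,
    rng: np.random.Generator,
    **meta,
) -> Sentence:
    """Replace each class token by a uniformly drawn word of that class."""
    source = None
    if isinstance(classes, AbstractStructure):
        source = classes
        classes = classes.classes
    words = tuple(
        lexicon[c][int(rng.integers(len(lexicon[c])))] for c in classes
    )
    meta.setdefault("source", source)
    meta.setdefault("status", "old-grammatical")
    return Sentence(words=words, classes=tuple(classes), **meta)


def _distinct_instantiations(
    structure: AbstractStructure,
    n: int,
    lexicon: Lexicon,
    rng: np.random.Generator,
    status: str,
) -> list[Sentence]:
    capacity = 1
    for c in structure.classes:
        capacity *= len(lexicon[c])
    if capacity < n:
        raise ValueError(
            f"lexicon supports only {capacity} distinct instantiations of "
            f"{structure.class_string()}; {n} requested"
        )
    seen: set[tuple[str, ...]] = set()
    out: list[Sentence] = []
    while len(out) < n:  # resample on collision
        s = instantiate(structure, lexicon, rng, status=status)
        if s.words not in seen:
            seen.add(s.words)
            out.append(s)
    return out


def build_training_corpus(
    old: Sequence[AbstractStructure],
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> list[Sentence]:
    """168 distinct training sentences: 16 one-layer, 80 two-layer and
    72 three-layer items (x8 / x16 / x24 instantiations)."""
    corpus: list[Sentence] = []
    for st in sorted(old):
        corpus.extend(
            _distinct_instantiations(
                st,
                TRAINING_MULTIPLIERS[st.n_layers],
                lexicon,
                rng,
                "old-grammatical",
            )
        )
    assert len(corpus) == 168 and len({s.words for s in corpus}) == 168
    return corpus


# ---------------------------------------------------------------------------
# Ungrammatical sets
# ---------------------------------------------------------------------------

def build_layer_violation_set(
    structures: Sequence[AbstractStructure],
    grammar: Grammar,
    rng: np.random.Generator,
) -> list[Sentence]:
    """The 44 layer-violating class sequences (unlexicalised).

    Six 1-layer items (the four distinct violated forms plus one
    seed-chosen duplicate per 1-layer structure), twenty 2-layer items
    (each structure violated once per layer) and eighteen 3-layer
    items (once per layer).  Returned as class-only Sentences (words
    filled in at pairing time).
    """
    items: list[tuple[AbstractStructure, int, tuple[str, ...], str]] = []
    for st in sorted(structures):
        if st.n_layers == 1:
            opts = layer_violation_options(st, 1, grammar)
            chosen = list(opts)
            chosen.append(opts[int(rng.integers(len(opts)))])
            items.extend((st, 1, seq, "local") for seq in chosen)
        else:
            for layer in range(1, st.n_layers + 1):
                seq, loc = violate_layer(st, layer, grammar, rng)
                items.append((st, layer, seq, loc))
    out = [
        Sentence(
            words=seq,  # placeholder; lexicalised later
            classes=seq,
            status="layer-ungrammatical",
            source=st,
            violated_layer=layer,
            locality=loc,
        )
        for st, layer, seq, loc in items
    ]
    n_by_layer = {
        d: sum(1 for s in out if s.source.n_layers == d) for d in (1, 2, 3)
    }
    assert len(out) == 44 and n_by_layer == {1: 6, 2: 20, 3: 18}
    return out


def make_random_ungrammatical(
    template: AbstractStructure,
    grammar: Grammar,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> tuple[str, ...]:
    """A random permutation of the template's class multiset that does
    not parse (and differs from the template)."""
    for _ in range(max_tries):
        seq = tuple(
            np.array(template.classes)[rng.permutation(len(template))].tolist()
        )
        if seq != template.classes and not parse(grammar, seq).grammatical:
            return seq
    raise AssertionError(
        f"no ungrammatical permutation found for {template.class_string()}"
    )


def build_random_ungrammatical_set(
    structures: Sequence[AbstractStructure],
    grammar: Grammar,
    rng: np.random.Generator,
) -> list[Sentence]:
    """The 22 random-ungrammatical class sequences: three per 1-layer
    structure, one per 2-layer and one per 3-layer structure."""
    out: list[Sentence] = []
    for st in sorted(structures):
        reps = 3 if st.n_layers == 1 else 1
        for _ in range(reps):
            seq = make_random_ungrammatical(st, grammar, rng)
            out.append(
                Sentence(
                    words=seq,
                    classes=seq,
                    status="random-ungrammatical",
                    source=st,
                )
            )
    n_by_layer = {
        d: sum(1 for s in out if s.source.n_layers == d) for d in (1, 2, 3)
    }
    assert len(out) == 22 and n_by_layer == {1: 6, 2: 10, 3: 6}
    return out


# ---------------------------------------------------------------------------
# Test set and control corpus
# ---------------------------------------------------------------------------

def build_test_set(
    old: Sequence[AbstractStructure],
    new: Sequence[AbstractStructure],
    grammar: Grammar,
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> list[TestPair]:
    """Assemble the 66 length-matched test pairs.

    Each ungrammatical item (44 layer violations + 22 random) derives
    from a template structure; its grammatical partner is a fresh
    instantiation of that same template, which matches length exactly
    and yields 39 old-grammatical and 27 new-grammatical items.
    """
    old_set = {s.classes for s in old}
    structures = sorted(list(old) + list(new))
    violations = build_layer_violation_set(structures, grammar, rng)
    randoms = build_random_ungrammatical_set(structures, grammar, rng)
    pairs: list[TestPair] = []
    for i, ung in enumerate(violations + randoms):
        ung_lex = instantiate(
            ung.classes,
            lexicon,
            rng,
            status=ung.status,
            source=ung.source,
            violated_layer=ung.violated_layer,
            locality=ung.locality,
        )
        status = (
            "old-grammatical"
            if ung.source.classes in old_set
            else "new-grammatical"
        )
        gram = instantiate(ung.source, lexicon, rng, status=status)
        pairs.append(TestPair(pair_id=i, grammatical=gram, ungrammatical=ung_lex))
    n_old = sum(1 for p in pairs if p.grammatical.status == "old-grammatical")
    n_new = sum(1 for p in pairs if p.grammatical.status == "new-grammatical")
    assert (len(pairs), n_old, n_new) == (66, 39, 27)
    return pairs


def build_control_corpus(
    old: Sequence[AbstractStructure],
    grammar: Grammar,
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> list[Sentence]:
    """168 random-ungrammatical training sentences for the control
    group, with the same per-structure length blocking as the trained
    corpus."""
    corpus: list[Sentence] = []
    seen: set[tuple[str, ...]] = set()
    for st in sorted(old):
        for _ in range(TRAINING_MULTIPLIERS[st.n_layers]):
            while True:
                seq = make_random_ungrammatical(st, grammar, rng)
                s = instantiate(
                    seq, lexicon, rng, status="random-ungrammatical", source=st
                )
                if s.words not in seen:
                    seen.add(s.words)
                    corpus.append(s)
                    break
    assert len(corpus) == 168
    return corpus


@dataclass(frozen=True)
class StimulusSet:
    """Everything one condition needs: structures, split, corpora, pairs."""

    variant: str
    structures: tuple[AbstractStructure, ...]
    old: tuple[AbstractStructure, ...]
    new: tuple[AbstractStructure, ...]
    training: tuple[Sentence, ...]
    control_training: tuple[Sentence, ...]
    pairs: tuple[TestPair, ...]


def build_stimulus_set(
    variant: str,
    seed: int | np.random.Generator,
    lexicon: Lexicon = DEFAULT_LEXICON,
) -> StimulusSet:
    """Build the full stimulus bundle for one grammar variant."""
    from .grammar import enumerate_structures, make_grammar

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    grammar = make_grammar(variant)
    structures = enumerate_structures(grammar)
    old, new = split_old_new(structures, rng)
    training = build_training_corpus(old, lexicon, rng)
    control = build_control_corpus(old, grammar, lexicon, rng)
    pairs = build_test_set(old, new, grammar, lexicon, rng)
    return StimulusSet(
        variant=variant,
        structures=tuple(structures),
        old=tuple(old),
        new=tuple(new),
        training=tuple(training),
        control_training=tuple(control),
        pairs=tuple(pairs),
    )
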
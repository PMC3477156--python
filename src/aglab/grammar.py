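"""Recursive context-free grammars for artificial grammar learning.

Four small phrase-structure grammars over the word classes N (noun),
V (verb) and R (relative-clause marker), crossing two typological
contrasts found in natural languages:

* **branching direction** -- whether a relative clause (CP) attaches to
  the right of its head noun (``NP -> N CP``, as in English) or to the
  left (``NP -> CP N``, as in Chinese);
* **embedding type** -- whether a CP nested inside another CP sits at
  the edge of its host (*tail embedding*, leaving the host clause
  contiguous) or interrupts it (*centre embedding*, splitting the host
  clause into two spans and creating a long-distance dependency).

Each sentence token carries an embedding *layer*: 1 for the main
clause, 2 for tokens inside the first CP, 3 for tokens inside a CP
nested within a CP.  The study design caps derivations at three layers
and (equivalently, for these grammars) at most two CP constituents and
nine words, which yields exactly 18 abstract word-class structures per
grammar.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VARIANTS",
    "Grammar",
    "AbstractStructure",
    "ParseResult",
    "make_grammar",
    "enumerate_structures",
    "parse",
    "layer_spans",
    "cp_constituents",
]

VARIANTS = ("tail-left", "tail-right", "centre-left", "centre-right")

#: Surface word classes.
CLASSES = ("N", "V", "R")

# Terminal symbols used in derivation trees.  V1 (intransitive) and V2
# (transitive) are distinct in the rules but share the surface class V.
_TERMINALS = {"N": "N", "R": "R", "V1": "V", "V2": "V"}

# Rewrite rules per variant.  All right-hand sides have length <= 2.
# The main clause is subject-initial (S -> NP VP...) in every variant;
# the variants differ in where CP attaches to N and in the internal
# order of the embedded verb phrase.
_RULES: dict[str, dict[str, tuple[tuple[str, ...], ...]]] = {
    "tail-right": {
        "S": (("NP", "VP"),),
        "VP": (("V1",), ("V2", "NP")),
        "NP": (("N",), ("N", "CP")),
        "CP": (("R", "VP"),),
    },
    "tail-left": {
        "S": (("NP", "VP1"),),
        "VP1": (("V1",), ("V2", "NP")),
        "VP2": (("V1",), ("NP", "V2")),
        "NP": (("N",), ("CP", "N")),
        "CP": (("VP2", "R"),),
    },
    "centre-right": {
        "S": (("NP", "VP1"),),
        "VP1": (("V1",), ("V2", "NP")),
        "VP2": (("V1",), ("NP", "V2")),
        "NP": (("N",), ("N", "CP")),
        "CP": (("R", "VP2"),),
    },
    "centre-left": {
        "S": (("NP", "VP"),),
        "VP": (("V1",), ("V2", "NP")),
        "NP": (("N",), ("CP", "N")),
        "CP": (("VP", "R"),),
    },
}


@dataclass(frozen=True)
class Grammar:
    """A phrase-structure grammar for one of the four study variants.

    Attributes
    ----------
    variant:
        One of ``tail-left``, ``tail-right``, ``centre-left``,
        ``centre-right``.
    rules:
        Mapping from nonterminal to the tuple of alternative
        right-hand sides (each a tuple of symbols).
    """

    variant: str
    rules: Mapping[str, tuple[tuple[str, ...], ...]]

    @property
    def nonterminals(self) -> frozenset[str]:
        return frozenset(self.rules)

    @property
    def terminal_classes(self) -> tuple[str, ...]:
        return CLASSES

    @property
    def start(self) -> str:
        return "S"

    def __post_init__(self) -> None:
        declared = set(self.rules) | set(_TERMINALS)
        for lhs, alts in self.rules.items():
            for alt in alts:
                unknown = set(alt) - declared
                if unknown:
                    raise ValueError(
                        f"rule {lhs} -> {' '.join(alt)} uses undeclared "
                        f"symbols {sorted(unknown)}"
                    )


@dataclass(frozen=True, order=True)
class AbstractStructure:
    """A word-class sequence together with its embedding-layer profile.

    Ordering (and therefore the canonical enumeration order) is by
    length, then lexicographically on the class string, so that seeded
    old/new splits are reproducible.
    """

    sort_index: tuple[int, str] = field(init=False, repr=False)
    classes: tuple[str, ...]
    layers: tuple[int, ...]
    variant: str
    n_cps: int
    tree: tuple = field(compare=False, hash=False, default=())

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.layers):
            raise ValueError("classes and layers must have equal length")
        object.__setattr__(
            self, "sort_index", (len(self.classes), " ".join(self.classes))
        )

    @property
    def n_layers(self) -> int:
        return max(self.layers)

    def __len__(self) -> int:
        return len(self.classes)

    def class_string(self) -> str:
        return " ".join(self.classes)

    def layer_content(self, layer: int) -> tuple[str, ...]:
        """The tokens belonging to ``layer``, in sentence order."""
        return tuple(
            c for c, l in zip(self.classes, self.layers) if l == layer
        )

    def to_record(self) -> dict:
        return {
            "classes": " ".join(self.classes),
            "layers": " ".join(map(str, self.layers)),
            "variant": self.variant,
        }


@dataclass(frozen=True)
class ParseResult:
    grammatical: bool
    layers: tuple[int, ...] | None = None
    tree: tuple | None = None


def make_grammar(variant: str) -> Grammar:
    """Return the grammar for one study variant.

    Raises
    ------
    ValueError
        If ``variant`` is not one of the four defined variants.
    """
    if variant not in _RULES:
        raise ValueError(
            f"unknown grammar variant {variant!r}; valid variants are "
            + ", ".join(VARIANTS)
        )
    return Grammar(variant=variant, rules=_RULES[variant])


def _expand(
    rules: Mapping[str, tuple[tuple[str, ...], ...]],
    symbol: str,
    layer: int,
    budget: int,
    max_layers: int,
    max_length: int,
):
    """Yield (classes, layers, cps_used, tree) for derivations of ``symbol``.

    ``layer`` is the embedding layer of terminals produced directly by
    this symbol; expanding a CP increments the layer of everything
    below it and consumes one unit of the CP ``budget``.
    """
    if symbol in _TERMINALS:
        yield (_TERMINALS[symbol],), (layer,), 0, symbol
        return
    child_layer = layer
    cost = 0
    if symbol == "CP":
        child_layer = layer + 1
        cost = 1
        if child_layer > max_layers or budget < 1:
            return
    for alt in rules[symbol]:
        for classes, layers, used, trees in _expand_seq(
            rules, alt, child_layer, budget - cost, max_layers, max_length
        ):
            yield classes, layers, used + cost, (symbol, *trees)


def _expand_seq(rules, symbols, layer, budget, max_layers, max_length):
    if not symbols:
        yield (), (), 0, ()
        return
    head, rest = symbols[0], symbols[1:]
    for c1, l1, u1, t1 in _expand(
        rules, head, layer, budget, max_layers, max_length
    ):
        if len(c1) > max_length:
            continue
        for c2, l2, u2, t2 in _expand_seq(
            rules, rest, layer, budget - u1, max_layers, max_length - len(c1)
        ):
            yield c1 + c2, l1 + l2, u1 + u2, (t1, *t2)


def enumerate_structures(
    grammar: Grammar,
    max_layers: int = 3,
    max_cps: int = 2,
    max_length: int = 9,
) -> list[AbstractStructure]:
    """Enumerate all distinct abstract structures under the constraints.

    Returns structures in canonical order (length, then lexicographic
    on the class string).  Distinctness is at the level of class
    sequences; for these grammars the layer annotation of a derivable
    class sequence is unique, which is asserted.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    seen: dict[tuple[str, ...], AbstractStructure] = {}
    for classes, layers, used, tree in _expand(
        grammar.rules, grammar.start, 1, max_cps, max_layers, max_length
    ):
        if len(classes) > max_length:
            continue
        prev = seen.get(classes)
        if prev is None:
            seen[classes] = AbstractStructure(
                classes=classes,
                layers=layers,
                variant=grammar.variant,
                n_cps=used,
                tree=tree,
            )
        elif prev.layers != layers:
            raise AssertionError(
                f"ambiguous layer annotation for {' '.join(classes)}"
            )
    return sorted(seen.values())


def parse(
    grammar: Grammar,
    classes: Sequence[str],
    max_layers: int = 3,
    max_cps: int = 2,
) -> ParseResult:
    """Decide grammaticality of a class sequence by chart parsing.

    A sequence is grammatical iff it is derivable from S with at most
    ``max_layers`` embedding layers and at most ``max_cps`` CP
    constituents.  Independent of :func:`enumerate_structures` (span
    recursion with memoisation rather than generation), so the two can
    be checked against each other exhaustively.
    """
    classes = tuple(classes)
    bad = set(classes) - set(CLASSES)
    if bad:
        raise ValueError(
            f"tokens outside {{N, V, R}} are not parseable: {sorted(bad)}"
        )
    n = len(classes)

    memo: dict[tuple[str, int, int, int], frozenset[int]] = {}

    def derive(sym: str, i: int, j: int, layer: int) -> frozenset[int]:
        """Set of CP counts over derivations of classes[i:j] from sym."""
        if sym in _TERMINALS:
            ok = j - i == 1 and classes[i] == _TERMINALS[sym]
            return frozenset({0}) if ok else frozenset()
        key = (sym, i, j, layer)
        if key in memo:
            return memo[key]
        memo[key] = frozenset()  # guard (grammar is not left-recursive in
        # a way that recurses on identical spans, but be safe)
        child_layer, cost = layer, 0
        if sym == "CP":
            child_layer, cost = layer + 1, 1
            if child_layer > max_layers:
                return frozenset()
        counts: set[int] = set()
        for alt in grammar.rules[sym]:
            if len(alt) == 1:
                for c in derive(alt[0], i, j, child_layer):
                    if c + cost <= max_cps:
                        counts.add(c + cost)
            else:  # binary
                a, b = alt
                for k in range(i + 1, j):
                    left = derive(a, i, k, child_layer)
                    if not left:
                        continue
                    right = derive(b, k, j, child_layer)
                    for ca, cb in itertools.product(left, right):
                        if ca + cb + cost <= max_cps:
                            counts.add(ca + cb + cost)
        memo[key] = frozenset(counts)
        return memo[key]

    if n == 0 or not derive(grammar.start, 0, n, 1):
        return ParseResult(grammatical=False)

    # Reconstruct one derivation for the layer annotation.
    def build(sym: str, i: int, j: int, layer: int, budget: int):
        if sym in _TERMINALS:
            if j - i == 1 and classes[i] == _TERMINALS[sym]:
                return (layer,), 0, sym
            return None
        child_layer, cost = layer, 0
        if sym == "CP":
            child_layer, cost = layer + 1, 1
            if child_layer > max_layers or budget < 1:
                return None
        for alt in grammar.rules[sym]:
            if len(alt) == 1:
                if not derive(alt[0], i, j, child_layer):
                    continue
                sub = build(alt[0], i, j, child_layer, budget - cost)
                if sub is not None:
                    layers, used, tree = sub
                    return layers, used + cost, (sym, tree)
            else:
                a, b = alt
                for k in range(i + 1, j):
                    if not derive(a, i, k, child_layer) or not derive(
                        b, k, j, child_layer
                    ):
                        continue
                    for ca in sorted(derive(a, i, k, child_layer)):
                        sub_a = build(a, i, k, child_layer, ca)
                        if sub_a is None or sub_a[1] != ca:
                            continue
                        sub_b = build(
                            b, k, j, child_layer, budget - cost - ca
                        )
                        if sub_b is None:
                            continue
                        la, ua, ta = sub_a
                        lb, ub, tb = sub_b
                        return la + lb, ua + ub + cost, (sym, ta, tb)
        return None

    built = build(grammar.start, 0, n, 1, max_cps)
    assert built is not None, "derivable sequence must rebuild"
    layers, _, tree = built
    return ParseResult(grammatical=True, layers=layers, tree=tree)


def cp_constituents(
    structure: AbstractStructure,
) -> list[tuple[int, tuple[int, ...]]]:
    """CP constituents of a structure, from its derivation tree.

    Returns one ``(layer, positions)`` entry per CP, where ``layer``
    is the embedding layer of the CP's direct tokens and ``positions``
    are the token indices of exactly those tokens (tokens of deeper,
    nested CPs are excluded).  Two CPs at the same layer (sibling
    embeddings) yield separate entries.
    """
    out: list[tuple[int, tuple[int, ...]]] = []

    def walk(node, pos: int, layer: int) -> int:
        if isinstance(node, str):  # terminal
            return pos + 1
        sym = node[0]
        child_layer = layer + 1 if sym == "CP" else layer
        start = pos
        for child in node[1:]:
            pos = walk(child, pos, child_layer)
        if sym == "CP":
            direct = tuple(
                i
                for i in range(start, pos)
                if structure.layers[i] == child_layer
            )
            out.append((child_layer, direct))
        return pos

    walk(structure.tree, 0, 1)
    return sorted(out, key=lambda e: (e[0], e[1]))


def layer_spans(
    structure: AbstractStructure,
) -> dict[int, list[tuple[int, int]]]:
    """Maximal runs of token indices per embedding layer.

    Returns a mapping from layer index to a list of inclusive
    ``(start, end)`` intervals.  A layer occupying two or more
    intervals is *intermitted*: violating it spans the embedded
    material, creating a nonlocal (long-distance) dependency.
    """
    spans: dict[int, list[tuple[int, int]]] = {}
    for layer, group in itertools.groupby(
        range(len(structure.layers)), key=lambda i: structure.layers[i]
    ):
        idx = list(group)
        spans.setdefault(layer, []).append((idx[0], idx[-1]))
    return spans
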
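"""Predictor battery for grammaticality-choice regressions.

For each test pair the analysis regresses the choice on the
*difference* (grammatical minus ungrammatical item) of a set of
training-corpus statistics, computed in parallel at the level of
words and of word classes:

* **chunk strength** -- summed training frequency of the item's
  bigrams and trigrams, computed over sequences padded with distinct
  start/end symbols so that anchor (edge) positions act as cues;
* **repetition-structure frequency** -- how many training sentences
  share the item's adjacent (local) repetition code or its global
  (first-occurrence-rank) repetition code;
* **gapped bigram strength** -- summed training frequency of ordered
  token pairs separated by exactly two or three intervening tokens
  (unpadded), the fixed-length long-distance chunk alternative to
  genuine phrase structure;
* a **dummy** coding whether the ungrammatical member carries a local
  (1) rather than a long-distance/nonlocal (0) violation, so that the
  regression intercept captures sensitivity to nonlocal dependencies.

Two predictor sets are used: ``chunk-rep`` (chunk strength plus
repetition frequencies plus the dummy) and ``gapped`` (the four
gapped-bigram predictors plus the dummy).  The two are fit separately;
a single regression with all predictors is unstable at 132 trials.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .stimuli import Sentence, TestPair

__all__ = [
    "START_PAD",
    "END_PAD",
    "PREDICTOR_SPECS",
    "NGramTable",
    "build_ngram_table",
    "chunk_strength",
    "local_repetition_code",
    "global_repetition_code",
    "repetition_frequency",
    "build_gapped_table",
    "gapped_bigram_strength",
    "CorpusStatistics",
    "pair_features",
    "feature_matrix",
]

#: Distinct, non-lexical padding symbols marking sequence edges.
START_PAD = "<s>"
END_PAD = "</s>"

#: Feature columns per predictor set (the regression adds an intercept).
PREDICTOR_SPECS = {
    "chunk-rep": (
        "chunk_word",
        "chunk_class",
        "local_violation",
        "rep_global_word",
        "rep_global_class",
        "rep_local_word",
        "rep_local_class",
    ),
    "gapped": (
        "gap2_word",
        "gap3_word",
        "gap2_class",
        "gap3_class",
        "local_violation",
    ),
}


def _tokens(sentence: Sentence | Sequence[str], level: str) -> tuple[str, ...]:
    if isinstance(sentence, Sentence):
        return sentence.words if level == "word" else sentence.classes
    return tuple(sentence)


def _padded(tokens: Sequence[str]) -> tuple[str, ...]:
    return (START_PAD, *tokens, END_PAD)


@dataclass(frozen=True)
class NGramTable:
    """Token-frequency n-gram counts over a training corpus."""

    level: str  # word | class
    order: int  # 2 | 3
    padded: bool
    counts: Counter

    def __getitem__(self, ngram: tuple[str, ...]) -> int:
        return self.counts.get(tuple(ngram), 0)


def build_ngram_table(
    corpus: Iterable[Sentence | Sequence[str]],
    level: str = "word",
    order: int = 2,
    padded: bool = True,
) -> NGramTable:
    """Count n-grams of the given order over a corpus.

    With padding, each sentence receives one start and one end symbol,
    so a sentence of length L contributes L+1 bigrams and L trigrams.
    """
    if order not in (2, 3):
        raise ValueError(f"order must be 2 or 3, got {order}")
    counts: Counter = Counter()
    n = 0
    for sent in corpus:
        n += 1
        toks = _tokens(sent, level)
        if padded:
            toks = _padded(toks)
        counts.update(
            toks[i : i + order] for i in range(len(toks) - order + 1)
        )
    if n == 0:
        raise ValueError("corpus must be non-empty")
    return NGramTable(level=level, order=order, padded=padded, counts=counts)


def chunk_strength(
    item: Sentence | Sequence[str],
    bigrams: NGramTable,
    trigrams: NGramTable,
) -> int:
    """Summed training frequency of the item's padded 2- and 3-grams."""
    total = 0
    for table in (bigrams, trigrams):
        toks = _tokens(item, table.level)
        if table.padded:
            toks = _padded(toks)
        k = table.order
        total += sum(table[toks[i : i + k]] for i in range(len(toks) - k + 1))
    return total


def local_repetition_code(seq: Sequence[str]) -> str:
    """Adjacent repetition structure: position i is 1 iff token i+1
    repeats token i (AABBCC -> 10101)."""
    seq = tuple(seq)
    return "".join(
        "1" if b == a else "0" for a, b in zip(seq, seq[1:])
    )


def global_repetition_code(seq: Sequence[str]) -> str:
    """Global repetition structure: each token replaced by its
    first-occurrence rank (AABBCC -> 112233; ABABC and BCBCD -> 12123).

    Invariant under any one-to-one relabelling of tokens.
    """
    ranks: dict[str, int] = {}
    out = []
    for tok in seq:
        if tok not in ranks:
            ranks[tok] = len(ranks) + 1
            if ranks[tok] > 9:
                raise ValueError(
                    "global repetition codes support at most 9 distinct tokens"
                )
        out.append(str(ranks[tok]))
    return "".join(out)


def repetition_frequency(
    item: Sentence | Sequence[str],
    corpus_codes: Counter,
    kind: str,
    level: str = "word",
) -> int:
    """Number of training sentences sharing the item's repetition code."""
    coder = local_repetition_code if kind == "local" else global_repetition_code
    return corpus_codes.get(coder(_tokens(item, level)), 0)


def _corpus_repetition_codes(
    corpus: Iterable[Sentence], kind: str, level: str
) -> Counter:
    coder = local_repetition_code if kind == "local" else global_repetition_code
    return Counter(coder(_tokens(s, level)) for s in corpus)


def build_gapped_table(
    corpus: Iterable[Sentence | Sequence[str]], gap: int, level: str
) -> Counter:
    """Counts of ordered (first, last) token pairs at exactly ``gap``
    intervening tokens, over unpadded sequences."""
    if gap not in (2, 3):
        raise ValueError(f"gap must be 2 or 3, got {gap}")
    counts: Counter = Counter()
    for sent in corpus:
        toks = _tokens(sent, level)
        counts.update(
            (toks[i], toks[i + gap + 1])
            for i in range(len(toks) - gap - 1)
        )
    return counts


def gapped_bigram_strength(
    item: Sentence | Sequence[str], table: Counter, gap: int, level: str
) -> int:
    """Summed training frequency of the item's gapped pairs."""
    toks = _tokens(item, level)
    return sum(
        table.get((toks[i], toks[i + gap + 1]), 0)
        for i in range(len(toks) - gap - 1)
    )


@dataclass(frozen=True)
class CorpusStatistics:
    """All training-corpus tables the predictor battery needs."""

    bigrams: dict[str, NGramTable]
    trigrams: dict[str, NGramTable]
    rep_codes: dict[tuple[str, str], Counter]  # (kind, level) -> counts
    gapped: dict[tuple[int, str], Counter]  # (gap, level) -> counts

    @classmethod
    def from_corpus(cls, corpus: Sequence[Sentence]) -> "CorpusStatistics":
        corpus = list(corpus)
        return cls(
            bigrams={
                lv: build_ngram_table(corpus, lv, 2) for lv in ("word", "class")
            },
            trigrams={
                lv: build_ngram_table(corpus, lv, 3) for lv in ("word", "class")
            },
            rep_codes={
                (kind, lv): _corpus_repetition_codes(corpus, kind, lv)
                for kind in ("local", "global")
                for lv in ("word", "class")
            },
            gapped={
                (gap, lv): build_gapped_table(corpus, gap, lv)
                for gap in (2, 3)
                for lv in ("word", "class")
            },
        )

    def item_features(self, item: Sentence) -> dict[str, int]:
        feats: dict[str, int] = {}
        for lv in ("word", "class"):
            feats[f"chunk_{lv}"] = chunk_strength(
                item, self.bigrams[lv], self.trigrams[lv]
            )
            for kind in ("local", "global"):
                feats[f"rep_{kind}_{lv}"] = repetition_frequency(
                    item, self.rep_codes[(kind, lv)], kind, lv
                )
            for gap in (2, 3):
                feats[f"gap{gap}_{lv}"] = gapped_bigram_strength(
                    item, self.gapped[(gap, lv)], gap, lv
                )
        return feats


def pair_features(
    pair: TestPair, stats: CorpusStatistics, spec: str = "chunk-rep"
) -> dict[str, float]:
    """Difference features (grammatical minus ungrammatical) for one
    pair, plus the local-violation dummy.

    The dummy is 1 unless the ungrammatical member is a nonlocal layer
    violation; the intercept of a regression on these features then
    encodes sensitivity to nonlocal dependencies.
    """
    if spec not in PREDICTOR_SPECS:
        raise ValueError(
            f"unknown predictor spec {spec!r}; valid: "
            + ", ".join(PREDICTOR_SPECS)
        )
    g = stats.item_features(pair.grammatical)
    u = stats.item_features(pair.ungrammatical)
    feats = {k: float(g[k] - u[k]) for k in g}
    feats["local_violation"] = float(
        pair.ungrammatical.locality != "nonlocal"
    )
    return {k: feats[k] for k in PREDICTOR_SPECS[spec]}


def feature_matrix(
    pairs: Sequence[TestPair],
    stats: CorpusStatistics,
    spec: str = "chunk-rep",
) -> pd.DataFrame:
    """One row per test pair, indexed by pair_id."""
    rows = {p.pair_id: pair_features(p, stats, spec) for p in pairs}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "pair_id"
    return df
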
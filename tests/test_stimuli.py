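"""Stimulus construction: splits, corpora, violations, test pairs."""

from collections import Counter

import numpy as np
import pytest

from aglab.grammar import VARIANTS, enumerate_structures, make_grammar, parse
from aglab.stimuli import (
    DEFAULT_LEXICON,
    Lexicon,
    build_layer_violation_set,
    build_random_ungrammatical_set,
    build_stimulus_set,
    build_training_corpus,
    instantiate,
    layer_violation_options,
    make_random_ungrammatical,
    split_old_new,
    tag_locality,
)


@pytest.fixture(scope="module")
def cl_grammar():
    return make_grammar("centre-left")


@pytest.fixture(scope="module")
def cl_structures(cl_grammar):
    return enumerate_structures(cl_grammar)


def _by_string(structures, s):
    return next(x for x in structures if x.class_string() == s)


class TestLexicon:
    def test_default_lexicon_is_nine_disjoint_words(self):
        words = [w for ws in DEFAULT_LEXICON.words.values() for w in ws]
        assert len(words) == len(set(words)) == 9
        assert {c: len(ws) for c, ws in DEFAULT_LEXICON.words.items()} == {
            "N": 4,
            "V": 4,
            "R": 1,
        }

    def test_overlapping_word_lists_rejected(self):
        with pytest.raises(ValueError):
            Lexicon(words={"N": ("a", "b"), "V": ("b",)})


class TestSplitOldNew:
    def test_cardinalities_and_one_layer_assignment(self, cl_structures):
        for seed in (0, 1, 99):
            old, new = split_old_new(cl_structures, np.random.default_rng(seed))
            assert len(old) == 10 and len(new) == 8
            assert all(s.n_layers > 1 for s in new)
            assert sum(1 for s in old if s.n_layers == 1) == 2
            assert sum(1 for s in old if s.n_layers == 2) == 5
            assert sum(1 for s in old if s.n_layers == 3) == 3

    def test_same_seed_same_split(self, cl_structures):
        a = split_old_new(cl_structures, np.random.default_rng(5))
        b = split_old_new(cl_structures, np.random.default_rng(5))
        assert a == b

    def test_wrong_cardinality_rejected(self, cl_structures):
        with pytest.raises(ValueError):
            split_old_new(cl_structures[:-1], np.random.default_rng(0))


class TestInstantiate:
    def test_words_match_classes(self, cl_structures, rng):
        st = _by_string(cl_structures, "V N R N V N")
        s = instantiate(st, DEFAULT_LEXICON, rng)
        assert len(s.words) == len(st)
        for w, c in zip(s.words, s.classes):
            assert w in DEFAULT_LEXICON[c]

    def test_r_word_is_unique(self, cl_structures, rng):
        st = _by_string(cl_structures, "V R N V")
        for _ in range(5):
            s = instantiate(st, DEFAULT_LEXICON, rng)
            assert s.words[1] == "ki"

    def test_nv_supports_sixteen_instantiations(self, cl_structures, rng):
        st = _by_string(cl_structures, "N V")
        seen = {
            instantiate(st, DEFAULT_LEXICON, rng).words for _ in range(2000)
        }
        assert len(seen) == 16


class TestTrainingCorpus:
    def test_counts_by_layer_and_distinctness(self, cl_structures, rng):
        old, _ = split_old_new(cl_structures, rng)
        corpus = build_training_corpus(old, DEFAULT_LEXICON, rng)
        assert len(corpus) == 168
        assert len({s.words for s in corpus}) == 168
        by_layer = Counter(s.source.n_layers for s in corpus)
        assert (by_layer[1], by_layer[2], by_layer[3]) == (16, 80, 72)

    def test_insufficient_lexicon_rejected(self, cl_structures, rng):
        old, _ = split_old_new(cl_structures, rng)
        tiny = Lexicon(words={"N": ("n1",), "V": ("v1",), "R": ("r1",)})
        with pytest.raises(ValueError, match="distinct"):
            build_training_corpus(old, tiny, rng)


class TestLayerViolations:
    def test_printed_centre_left_examples(self, cl_grammar, cl_structures):
        st = _by_string(cl_structures, "N V V N R N")
        layer1 = {
            " ".join(s) for s in layer_violation_options(st, 1, cl_grammar)
        }
        assert layer1 == {"V N V N R N", "N R V N R V"}
        layer2 = {
            " ".join(s) for s in layer_violation_options(st, 2, cl_grammar)
        }
        assert layer2 == {"N V V V R N", "N V N R V N"}

    def test_printed_minimal_example(self, cl_grammar, cl_structures):
        nv = _by_string(cl_structures, "N V")
        assert {
            " ".join(s) for s in layer_violation_options(nv, 1, cl_grammar)
        } == {"R V", "V N"}

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_violations_ungrammatical_and_minimal(self, variant):
        """Every tabled violation of every structure/layer fails to
        parse and leaves all non-violated layers' contents intact."""
        g = make_grammar(variant)
        for st in enumerate_structures(g):
            for layer in range(1, st.n_layers + 1):
                for seq in layer_violation_options(st, layer, g):
                    assert not parse(g, seq).grammatical
                    assert len(seq) == len(st)
                    for other in range(1, st.n_layers + 1):
                        if other == layer:
                            continue
                        kept = tuple(
                            c
                            for c, l in zip(seq, st.layers)
                            if l == other
                        )
                        # sibling-CP layers: only one constituent is
                        # rewritten, so the other layer's tokens are a
                        # superset match; non-violated layers must be
                        # exactly preserved
                        assert kept == st.layer_content(other)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_violation_set_composition(self, variant):
        g = make_grammar(variant)
        structs = enumerate_structures(g)
        out = build_layer_violation_set(structs, g, np.random.default_rng(3))
        assert len(out) == 44
        by_layer = Counter(s.source.n_layers for s in out)
        assert (by_layer[1], by_layer[2], by_layer[3]) == (6, 20, 18)

    @pytest.mark.parametrize("variant,expected", [
        ("centre-left", 14),
        ("centre-right", 18),
        ("tail-left", 8),
        ("tail-right", 12),
    ])
    def test_nonlocal_trial_counts_per_condition(self, variant, expected):
        """Intermitted-layer violations per condition match the
        reported per-participant long-distance trial counts."""
        g = make_grammar(variant)
        structs = enumerate_structures(g)
        out = build_layer_violation_set(structs, g, np.random.default_rng(0))
        assert sum(1 for s in out if s.locality == "nonlocal") == expected


class TestLocality:
    def test_intermitted_main_clause_is_nonlocal(self, cl_structures):
        st = _by_string(cl_structures, "N V V N R N")
        assert tag_locality(st, 1) == "nonlocal"
        assert tag_locality(st, 2) == "local"

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_deepest_layer_always_local(self, variant):
        for st in enumerate_structures(make_grammar(variant)):
            assert tag_locality(st, st.n_layers) == "local"


class TestRandomUngrammatical:
    def test_rejection_contract(self, cl_grammar, cl_structures, rng):
        for st in cl_structures[:6]:
            seq = make_random_ungrammatical(st, cl_grammar, rng)
            assert len(seq) == len(st)
            assert Counter(seq) == Counter(st.classes)
            assert not parse(cl_grammar, seq).grammatical

    def test_set_composition(self, cl_grammar, cl_structures, rng):
        out = build_random_ungrammatical_set(cl_structures, cl_grammar, rng)
        assert len(out) == 22
        by_layer = Counter(s.source.n_layers for s in out)
        assert (by_layer[1], by_layer[2], by_layer[3]) == (6, 10, 6)


class TestTestSet:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_counts_and_length_matching(self, variant):
        design = build_stimulus_set(variant, 11)
        g = make_grammar(variant)
        assert len(design.pairs) == 66
        statuses = Counter(p.grammatical.status for p in design.pairs)
        assert statuses == {"old-grammatical": 39, "new-grammatical": 27}
        u_statuses = Counter(p.ungrammatical.status for p in design.pairs)
        assert u_statuses == {
            "layer-ungrammatical": 44,
            "random-ungrammatical": 22,
        }
        for p in design.pairs:
            assert len(p.grammatical) == len(p.ungrammatical)
            assert parse(g, p.grammatical.classes).grammatical
            assert not parse(g, p.ungrammatical.classes).grammatical

    def test_control_corpus(self, centre_left_design):
        g = make_grammar("centre-left")
        control = centre_left_design.control_training
        assert len(control) == 168
        assert all(
            not parse(g, s.classes).grammatical for s in control
        )
        # length-blocking matches the trained corpus
        trained_lengths = Counter(len(s) for s in centre_left_design.training)
        assert Counter(len(s) for s in control) == trained_lengths

    def test_stable_across_seeds(self):
        for seed in (0, 5, 123):
            d = build_stimulus_set("tail-left", seed)
            assert len(d.pairs) == 66 and len(d.training) == 168
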
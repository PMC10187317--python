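"""Condition generators: golden outputs, conservation laws, derangements."""

import itertools
from collections import Counter

import numpy as np
import pytest

from perturbenc.corpus import PERIOD
from perturbenc.perturb import (
    KEEP_SETS,
    CandidateExhaustion,
    InfeasibleSwapCount,
    adjacent_transposition_distance,
    count_inversions,
    derange,
    generate_condition,
    keep_classes,
    length_control,
    local_word_swaps,
    low_pmi,
    low_pmi_random,
    paraphrase_condition,
    rand_nouns_control,
    rand_sent,
    rand_word_list,
    reverse_order,
    scope_derangement,
)
from perturbenc.pmi import string_pmi


class TestLocalWordSwaps:
    def test_k_zero_identity(self, beekeeper_tokens):
        assert local_word_swaps(beekeeper_tokens, 0, 0) == beekeeper_tokens

    def test_verification_distance_equals_k(self, beekeeper_tokens):
        rng = np.random.default_rng(3)
        for k in (1, 3, 5, 7):
            out = local_word_swaps(beekeeper_tokens, k, rng)
            assert adjacent_transposition_distance(beekeeper_tokens, out) == k
            assert Counter(out) == Counter(beekeeper_tokens)

    def test_k1_output_in_enumerated_set(self):
        tokens = ("a", "b", "c", "d")
        # brute-force: all single adjacent transpositions
        allowed = {("b", "a", "c", "d"), ("a", "c", "b", "d"), ("a", "b", "d", "c")}
        seen = {local_word_swaps(tokens, 1, np.random.default_rng(s)) for s in range(50)}
        assert seen <= allowed
        assert seen == allowed  # all reachable under enough seeds

    def test_infeasible_k(self):
        with pytest.raises(InfeasibleSwapCount):
            local_word_swaps(("a", "b", "."), 5, 0)

    def test_inversion_count_matches_brute_force(self):
        for perm in itertools.permutations(range(4)):
            brute = sum(
                1
                for i, j in itertools.combinations(range(4), 2)
                if perm[i] > perm[j]
            )
            assert count_inversions(perm) == brute


class TestReverseOrder:
    def test_table_row(self, beekeeper_tokens):
        assert " ".join(reverse_order(beekeeper_tokens)) == (
            "pollen produce that plants local conserve to interest "
            "beekeeper's every in is it ."
        )

    def test_single_word_unchanged(self):
        assert reverse_order(("hi", ".")) == ("hi", ".")

    def test_involution(self, beekeeper_tokens):
        assert reverse_order(reverse_order(beekeeper_tokens)) == beekeeper_tokens


class TestLowPmi:
    def test_table_row(self, beekeeper_tokens, beekeeper_classes):
        assert " ".join(low_pmi(beekeeper_tokens, beekeeper_classes)) == (
            "it beekeeper's conserve plants pollen in to every that "
            "is interest local produce ."
        )

    def test_no_function_words(self):
        out = low_pmi(("cats", "chase", "mice", "."), ("NOUN", "VERB", "NOUN"))
        # oddContent ++ evenContent with an empty function block
        assert out == ("cats", "mice", "chase", ".")

    def test_one_word_unchanged(self):
        assert low_pmi(("hi", "."), ("NOUN",)) == ("hi", ".")


class TestLowPmiRandom:
    def test_reproducible_under_seed(self, beekeeper_tokens, toy_counts):
        tokens = ("a", "b", "c", "d", "e", ".")
        a = low_pmi_random(tokens, toy_counts, np.random.default_rng(9))
        b = low_pmi_random(tokens, toy_counts, np.random.default_rng(9))
        assert a == b

    def test_selects_sampled_argmin(self, toy_counts):
        tokens = ("a", "b", "c", "d", "e", ".")
        rng = np.random.default_rng(4)
        out = low_pmi_random(tokens, toy_counts, rng, n_candidates=10)
        # replay the same draws to enumerate the candidate set independently
        rng2 = np.random.default_rng(4)
        words = list(tokens[:-1])
        cands, seen = [], set()
        while len(cands) < 10:
            perm = rng2.permutation(5)
            cand = tuple(words[p] for p in perm)
            if cand == tuple(words) or cand in seen:
                continue
            seen.add(cand)
            cands.append(cand)
        best = min(cands, key=lambda c: string_pmi(c, toy_counts))
        assert out[:-1] == best
        assert string_pmi(out, toy_counts) == min(
            string_pmi(c, toy_counts) for c in cands
        )

    def test_excludes_forbidden_sequences(self, toy_counts):
        tokens = ("a", "b", ".")
        # only one non-identity permutation exists and it is excluded
        with pytest.raises(CandidateExhaustion):
            low_pmi_random(
                tokens, toy_counts, np.random.default_rng(0),
                n_candidates=1, exclusions=[("b", "a", ".")], max_tries=50,
            )


class TestKeepClasses:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("KeepContentW", "it is beekeeper's interest conserve local plants produce pollen ."),
            ("KeepNVAdj", "it is beekeeper's interest conserve local plants produce pollen ."),
            ("KeepNV", "it is beekeeper's interest conserve plants produce pollen ."),
            ("KeepN", "it beekeeper's interest plants pollen ."),
            ("KeepFunctionW", "in every to that ."),
        ],
    )
    def test_table_rows(self, beekeeper_tokens, beekeeper_classes, name, expected):
        out = keep_classes(beekeeper_tokens, beekeeper_classes, KEEP_SETS[name])
        assert " ".join(out) == expected

    def test_keep_all_is_identity(self, beekeeper_tokens, beekeeper_classes):
        out = keep_classes(
            beekeeper_tokens, beekeeper_classes,
            {"NOUN", "VERB", "ADJ", "ADV", "FUNCTION"},
        )
        assert out == beekeeper_tokens

    def test_nesting_and_partition(self, tiny_study):
        _, stim, classes = tiny_study
        for s, cls in zip(stim, classes):
            subsets = {
                name: keep_classes(s.tokens, cls, KEEP_SETS[name])[:-1]
                for name in KEEP_SETS
            }

            def is_subsequence(a, b):
                it = iter(b)
                return all(x in it for x in a)

            assert is_subsequence(subsets["KeepN"], subsets["KeepNV"])
            assert is_subsequence(subsets["KeepNV"], subsets["KeepNVAdj"])
            assert is_subsequence(subsets["KeepNVAdj"], subsets["KeepContentW"])
            assert Counter(subsets["KeepContentW"]) + Counter(
                subsets["KeepFunctionW"]
            ) == Counter(s.words)


class TestControls:
    def test_rand_word_list_conservation(self, tiny_study):
        _, stim, _ = tiny_study
        cond = rand_word_list(stim, np.random.default_rng(2))
        all_orig = Counter(w for s in stim for w in s.words)
        all_new = Counter(w for toks in cond.sentences for w in toks[:-1])
        assert all_new == all_orig
        for s, toks in zip(stim, cond.sentences):
            assert len(toks) - 1 == s.n

    def test_rand_nouns_lengths_and_pool(self, tiny_study):
        _, stim, classes = tiny_study
        cond = rand_nouns_control(stim, classes, np.random.default_rng(2))
        pool = {
            w for s, cls in zip(stim, classes)
            for w, c in zip(s.words, cls) if c == "NOUN"
        }
        for s, cls, toks in zip(stim, classes, cond.sentences):
            assert len(toks) - 1 == sum(1 for c in cls if c == "NOUN")
            assert set(toks[:-1]) <= pool

    def test_length_control(self):
        out = length_control(("a", "b", "c", "."), fill_word="blah")
        assert out == ("blah", "blah", "blah", ".")
        assert length_control(("x", "y", "z", "."), "blah") == out


class TestDerange:
    def test_two_elements_forced_swap(self):
        assert list(derange(2, np.random.default_rng(0))) == [1, 0]

    def test_singleton_identity(self):
        assert list(derange(1, np.random.default_rng(0))) == [0]

    def test_no_fixed_points(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            perm = derange(5, rng)
            assert not np.any(perm == np.arange(5))

    def test_scope_derangement_respects_groups(self):
        labels = ["g1"] * 4 + ["g2"] * 3 + ["g3"]
        perm = scope_derangement(labels, np.random.default_rng(0))
        for i, p in enumerate(perm):
            assert labels[i] == labels[p]
        # singleton stays; members of groups >= 2 all move
        assert perm[7] == 7
        assert not np.any(perm[:7] == np.arange(7))


class TestRandSent:
    def test_within_passage_derangement(self, tiny_study):
        _, stim, _ = tiny_study
        cond = rand_sent(stim, "passage", np.random.default_rng(0))
        for i, p in enumerate(cond.substitution_map):
            assert stim[i].passage_id == stim[p].passage_id
            assert i != p  # all passages here have >= 2 sentences
        assert cond.metadata["cross_passage_fraction"] == 0.0

    def test_whole_set_scope_stays_within_experiment(self, tiny_study):
        _, stim, _ = tiny_study
        cond = rand_sent(stim, "all", np.random.default_rng(0))
        for i, p in enumerate(cond.substitution_map):
            assert stim[i].experiment_id == stim[p].experiment_id
            assert i != p

    def test_singleton_topics_unchanged(self):
        from perturbenc.corpus import Sentence, StimulusSet

        stim = StimulusSet(
            [
                Sentence(("a", "."), "e", "t1", "p1", 1),
                Sentence(("b", "."), "e", "t2", "p2", 1),
            ]
        )
        cond = rand_sent(stim, "topic", np.random.default_rng(0))
        assert list(cond.substitution_map) == [0, 1]


class TestParaphrase:
    def test_identical_paraphrase(self, tiny_study):
        _, stim, _ = tiny_study
        texts = [" ".join(s.words) for s in stim]
        cond = paraphrase_condition(stim, texts)
        assert cond.metadata["mean_overlap"] == 1.0
        assert cond.metadata["mean_length_diff"] == 0.0

    def test_overlap_hand_count(self):
        from perturbenc.corpus import Sentence, StimulusSet

        stim = StimulusSet([Sentence(("a", "b", "c", "d", "e", "f", "."), "e", "t", "p", 1)])
        # paraphrase shares 3 types {a,b,c}; union has 9 types -> 1/3
        cond = paraphrase_condition(stim, ["a b c x y z"])
        assert cond.metadata["overlap_fractions"][0] == pytest.approx(3 / 9)

    def test_missing_rows_rejected(self, tiny_study):
        _, stim, _ = tiny_study
        with pytest.raises(ValueError, match="rows"):
            paraphrase_condition(stim, ["only one"])


class TestGenerateCondition:
    def test_word_order_conserves_multisets(self, study):
        _, stim, classes, counts = study
        for name in ("1LocalWordSwap", "ReverseOrder", "LowPMI"):
            cond = generate_condition(
                name, stim, classes_per_sentence=classes, counts=counts, seed=1
            )
            for s, toks in zip(stim, cond.sentences):
                assert Counter(toks) == Counter(s.tokens), name

    def test_low_pmi_lowers_score_on_most_sentences(self, study):
        _, stim, classes, counts = study
        lowered = 0
        eligible = 0
        for s, cls in zip(stim, classes):
            if s.n < 3:
                continue
            eligible += 1
            if string_pmi(low_pmi(s.tokens, cls), counts) <= string_pmi(s.tokens, counts):
                lowered += 1
        assert lowered / eligible >= 0.9

    def test_bit_reproducible_under_seed(self, tiny_study):
        _, stim, classes = tiny_study
        for name in ("3LocalWordSwaps", "RandWordList", "RandSent", "RandN"):
            a = generate_condition(name, stim, classes_per_sentence=classes, seed=77)
            b = generate_condition(name, stim, classes_per_sentence=classes, seed=77)
            assert a.sentences == b.sentences
            assert np.array_equal(a.substitution_map, b.substitution_map)

    def test_unknown_condition_rejected(self, tiny_study):
        _, stim, _ = tiny_study
        with pytest.raises(ValueError, match="unknown condition"):
            generate_condition("NotACondition", stim)
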
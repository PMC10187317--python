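"""Shared fixtures: hand-tagged sentence, toy counts, small synthetic study."""

import numpy as np
import pytest

from perturbenc.corpus import normalize_tokens
from perturbenc.pmi import NgramCounts
from perturbenc.synthetic import (
    SynthConfig,
    VocabularySpec,
    generate_ngram_counts,
    generate_stimulus_set,
    small_experiments,
)

# Hand-tagged fixture sentence: the classification is part of the fixture, so
# golden outputs never depend on a third-party tagger.
BEEKEEPER_RAW = (
    "It is in every beekeeper's interest to conserve local plants that produce pollen."
)
BEEKEEPER_CLASSES = (
    "NOUN",      # it (pronoun)
    "VERB",      # is
    "FUNCTION",  # in
    "FUNCTION",  # every
    "NOUN",      # beekeeper's
    "NOUN",      # interest
    "FUNCTION",  # to
    "VERB",      # conserve
    "ADJ",       # local
    "NOUN",      # plants
    "FUNCTION",  # that
    "VERB",      # produce
    "NOUN",      # pollen
)


@pytest.fixture(scope="session")
def beekeeper_tokens():
    return normalize_tokens(BEEKEEPER_RAW)


@pytest.fixture(scope="session")
def beekeeper_classes():
    return BEEKEEPER_CLASSES


@pytest.fixture(scope="session")
def toy_counts():
    """Tiny five-word count table with one strongly associated pair."""
    from collections import Counter

    unigrams = Counter({"a": 10, "b": 10, "c": 80, "d": 40, "e": 60})
    pairs = Counter(
        {
            ("a", "b"): 9,
            ("a", "c"): 4,
            ("b", "c"): 4,
            ("c", "d"): 16,
            ("c", "e"): 24,
            ("d", "e"): 12,
            ("a", "e"): 3,
            ("b", "d"): 2,
        }
    )
    return NgramCounts(unigrams=unigrams, pairs=pairs, alpha=0.1)


@pytest.fixture(scope="session")
def tiny_study():
    """Very small two-experiment stimulus set with known classes."""
    config = SynthConfig(
        experiments=small_experiments(
            n_topics=3, passages_per_topic=2, sentences_per_passage=3,
            n_experiments=2,
        )
    )
    stim, classes = generate_stimulus_set(config, seed=11)
    return config, stim, classes


@pytest.fixture(scope="session")
def study():
    """Moderately sized study used by encoding-level tests (288 sentences)."""
    config = SynthConfig(experiments=small_experiments(n_experiments=2))
    stim, classes = generate_stimulus_set(config, seed=5)
    counts = generate_ngram_counts(stim, 150, seed=5, config=config)
    return config, stim, classes, counts
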
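"""Synthetic study inputs with known ground truth.

Everything the pipeline consumes can be generated here without downloads:

* a stimulus hierarchy mirroring the study structure — experiment 2 with
  384 sentences (24 topics x 4 passages x 4 sentences, lengths 7-18) and
  experiment 3 with 243 sentences (24 topics x 3 passages; 27 passages of
  four sentences and 45 of three, lengths 5-20) — built from topic-specific
  content-word pools and a shared function-word pool, so every token's class
  is known by construction and no tagger is needed;
* an n-gram count table accumulated over the stimuli plus a topic-coherent
  background corpus, standing in for a large external n-gram corpus;
* a deterministic mock embedding backend with a tunable order sensitivity
  and a per-layer schedule mixing token identity with accumulated context;
* simulated voxel responses as a noisy linear readout of a known sentence
  feature map (bag of content words, or a random subspace of a backend
  layer), with ground-truth weights returned for recovery tests.

The synthetic sentences are not grammatical English; they carry the
statistical structure the analyses rely on (topic-specific content
vocabulary, shared function words, realistic length range).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import (
    ADJ,
    ADV,
    FUNCTION,
    NOUN,
    PERIOD,
    VERB,
    Sentence,
    StimulusSet,
)
from .embeddings import Backend
from .encoding import BrainData
from .perturb import PerturbedCondition
from .pmi import DEFAULT_ALPHA, NgramCounts

FUNCTION_WORDS = (
    "the", "a", "an", "of", "in", "to", "and", "that", "with", "for",
    "on", "as", "by", "at", "from", "this", "but", "or", "if", "when",
)

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

_CLASS_TAG = {NOUN: "NN", VERB: "VB", ADJ: "JJ", ADV: "RB"}


def _stable_seed(*parts) -> int:
    return zlib.crc32("|".join(map(str, parts)).encode())


def _pseudo_word(seed_parts, n_syllables: int = 2) -> str:
    rng = np.random.default_rng(_stable_seed(*seed_parts))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))]
        + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables + int(rng.integers(0, 2)))
    )


@dataclass
class ExperimentSpec:
    """Hierarchy of one experiment: topics -> passages -> sentences."""

    name: str
    n_topics: int
    passage_sizes_per_topic: list[list[int]]  # sentences per passage, per topic
    length_range: tuple[int, int]

    @property
    def n_sentences(self) -> int:
        return sum(sum(sizes) for sizes in self.passage_sizes_per_topic)


@dataclass
class VocabularySpec:
    nouns_per_topic: int = 8
    verbs_per_topic: int = 5
    adjs_per_topic: int = 3
    advs_per_topic: int = 2
    function_rate: float = 0.35
    class_weights: tuple[float, float, float, float] = (0.5, 0.25, 0.15, 0.10)


@dataclass
class SynthConfig:
    experiments: list[ExperimentSpec] = field(default_factory=list)
    vocabulary: VocabularySpec = field(default_factory=VocabularySpec)

    def __post_init__(self):
        if not self.experiments:
            self.experiments = default_experiments()


def default_experiments() -> list[ExperimentSpec]:
    """The reference study structure: 384 + 243 sentences across two experiments."""
    exp2 = ExperimentSpec(
        name="exp2",
        n_topics=24,
        passage_sizes_per_topic=[[4, 4, 4, 4] for _ in range(24)],
        length_range=(7, 18),
    )
    # 72 passages in 24 topics (3 each); 27 passages of four sentences and 45
    # of three is the unique split reaching 243 sentences: every topic gets
    # one four-sentence passage and the first three topics get a second.
    sizes3 = [[4, 4, 3] if t < 3 else [4, 3, 3] for t in range(24)]
    exp3 = ExperimentSpec(
        name="exp3", n_topics=24, passage_sizes_per_topic=sizes3, length_range=(5, 20)
    )
    return [exp2, exp3]


def small_experiments(
    n_topics: int = 12, passages_per_topic: int = 3, sentences_per_passage: int = 4,
    length_range: tuple[int, int] = (5, 12), n_experiments: int = 1,
) -> list[ExperimentSpec]:
    """Reduced hierarchies for fast simulation studies."""
    return [
        ExperimentSpec(
            name=f"exp{e + 2}",
            n_topics=n_topics,
            passage_sizes_per_topic=[
                [sentences_per_passage] * passages_per_topic for _ in range(n_topics)
            ],
            length_range=length_range,
        )
        for e in range(n_experiments)
    ]


def topic_vocabulary(
    exp_name: str, topic: int, vocab: VocabularySpec
) -> dict[str, list[str]]:
    """Deterministic topic-specific content-word pools (hash-seeded)."""
    pools: dict[str, list[str]] = {}
    for cls, count in (
        (NOUN, vocab.nouns_per_topic),
        (VERB, vocab.verbs_per_topic),
        (ADJ, vocab.adjs_per_topic),
        (ADV, vocab.advs_per_topic),
    ):
        pools[cls] = [
            _pseudo_word(("word", exp_name, topic, cls, i)) for i in range(count)
        ]
    return pools


def _build_sentence(
    length: int,
    pools: dict[str, list[str]],
    vocab: VocabularySpec,
    rng: np.random.Generator,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    classes_order = (NOUN, VERB, ADJ, ADV)
    words, classes = [], []
    for _ in range(length):
        if rng.random() < vocab.function_rate:
            words.append(FUNCTION_WORDS[rng.integers(len(FUNCTION_WORDS))])
            classes.append(FUNCTION)
        else:
            cls = classes_order[
                rng.choice(len(classes_order), p=np.asarray(vocab.class_weights))
            ]
            pool = pools[cls]
            words.append(pool[rng.integers(len(pool))])
            classes.append(cls)
    if NOUN not in classes:  # every sentence carries at least one noun
        slot = int(rng.integers(length))
        words[slot] = pools[NOUN][rng.integers(len(pools[NOUN]))]
        classes[slot] = NOUN
    return tuple(words) + (PERIOD,), tuple(classes)


def generate_stimulus_set(
    config: SynthConfig | None = None, seed: int = 0
) -> tuple[StimulusSet, list[tuple[str, ...]]]:
    """Generate a stimulus set plus per-sentence token classes (by construction)."""
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _stable_seed("stim")]))
    sentences: list[Sentence] = []
    classes: list[tuple[str, ...]] = []
    for exp in config.experiments:
        lo, hi = exp.length_range
        passage_counter = 0
        for topic in range(exp.n_topics):
            pools = topic_vocabulary(exp.name, topic, config.vocabulary)
            for passage_size in exp.passage_sizes_per_topic[topic]:
                passage_id = f"{exp.name}_p{passage_counter:03d}"
                passage_counter += 1
                for pos in range(1, passage_size + 1):
                    length = int(rng.integers(lo, hi + 1))
                    tokens, cls = _build_sentence(length, pools, config.vocabulary, rng)
                    sentences.append(
                        Sentence(tokens, exp.name, f"{exp.name}_t{topic:02d}", passage_id, pos)
                    )
                    classes.append(cls)
    return StimulusSet(sentences), classes


def build_lexicon(config: SynthConfig | None = None) -> dict[str, str]:
    """Word -> Penn-Treebank tag for everything the generator can emit."""
    config = config or SynthConfig()
    lexicon = {w: "IN" for w in FUNCTION_WORDS}
    for exp in config.experiments:
        for topic in range(exp.n_topics):
            for cls, words in topic_vocabulary(exp.name, topic, config.vocabulary).items():
                for w in words:
                    lexicon[w] = _CLASS_TAG[cls]
    return lexicon


def generate_ngram_counts(
    stimulus_set: StimulusSet,
    background_sentences: int = 500,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    config: SynthConfig | None = None,
) -> NgramCounts:
    """Counts over the stimuli plus a topic-coherent background corpus.

    The background reuses the stimulus vocabulary with topic-coherent
    co-occurrence (sentences drawn topic by topic), so adjacent stimulus
    words co-occur more often than random cross-topic pairs and every
    stimulus token has a nonzero marginal.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _stable_seed("ngram")]))
    corpus = [s.tokens for s in stimulus_set]
    for exp in config.experiments:
        lo, hi = exp.length_range
        for _ in range(background_sentences // max(1, len(config.experiments))):
            topic = int(rng.integers(exp.n_topics))
            pools = topic_vocabulary(exp.name, topic, config.vocabulary)
            tokens, _ = _build_sentence(
                int(rng.integers(lo, hi + 1)), pools, config.vocabulary, rng
            )
            corpus.append(tokens)
    return NgramCounts.from_corpus(corpus, alpha=alpha)


# ---------------------------------------------------------------------------
# Mock embedding backend


class MockBackend:
    """Deterministic embedding backend with tunable order sensitivity.

    Each word has a hash-seeded base vector (stable under vocabulary growth).
    A token's contribution is its base vector plus, weighted by
    ``order_sensitivity``, a component keyed to (word, position). Per layer,
    the token representation mixes the token's own contribution with the
    running mean of all contributions so far (context included), with the
    mixing weight increasing across layers — later layers are more
    context-aggregating, as in deep causal language models. With
    ``order_sensitivity=0`` the final-period summary vector is invariant to
    any word reordering of the input.

    Surprisal models: ``uniform`` (log V nats per token), ``oracle``
    (a perfectly confident predictor, 0 nats), or ``bigram`` (Laplace-
    smoothed first-order model; build via :meth:`with_bigram_surprisal`).

    With ``surprisal_coupling > 0`` (requires the bigram model), each
    token's contribution receives a deterministic distortion vector scaled
    by coupling * surprisal, so strings that are harder to predict carry
    more distorted representations — emulating a language model whose
    representations degrade on out-of-distribution input.
    """

    def __init__(
        self,
        num_layers: int = 4,
        dim: int = 32,
        order_sensitivity: float = 0.0,
        seed: int = 0,
        surprisal_model: str = "uniform",
        vocab_size: int = 1000,
        bigram_counts: dict | None = None,
        unigram_counts: dict | None = None,
        alpha: float = DEFAULT_ALPHA,
        surprisal_coupling: float = 0.0,
    ):
        self.num_layers = int(num_layers)
        self.dim = int(dim)
        self.order_sensitivity = float(order_sensitivity)
        self.seed = int(seed)
        self.surprisal_model = surprisal_model
        self.vocab_size = int(vocab_size)
        self.bigram_counts = bigram_counts or {}
        self.unigram_counts = unigram_counts or {}
        self.alpha = float(alpha)
        self.surprisal_coupling = float(surprisal_coupling)
        if self.surprisal_coupling > 0 and self.surprisal_model != "bigram":
            raise ValueError("surprisal_coupling requires the bigram surprisal model")
        self._mix = np.linspace(0.25, 0.9, self.num_layers)
        self._base_cache: dict[str, np.ndarray] = {}

    @classmethod
    def with_bigram_surprisal(
        cls, corpus: Sequence[Sequence[str]], **kwargs
    ) -> "MockBackend":
        """Build a backend whose surprisal comes from corpus bigram counts."""
        bigrams: dict[tuple[str, str], int] = {}
        unigrams: dict[str, int] = {}
        vocab = set()
        for seq in corpus:
            prev = "<s>"
            unigrams[prev] = unigrams.get(prev, 0) + 1
            for w in seq:
                vocab.add(w)
                bigrams[(prev, w)] = bigrams.get((prev, w), 0) + 1
                unigrams[w] = unigrams.get(w, 0) + 1
                prev = w
        kwargs.setdefault("vocab_size", len(vocab))
        return cls(
            surprisal_model="bigram",
            bigram_counts=bigrams,
            unigram_counts=unigrams,
            **kwargs,
        )

    # -- vectors -----------------------------------------------------------
    def _base(self, word: str) -> np.ndarray:
        vec = self._base_cache.get(word)
        if vec is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 1, _stable_seed(word)])
            )
            vec = rng.standard_normal(self.dim) / np.sqrt(self.dim)
            self._base_cache[word] = vec
        return vec

    def _positional(self, word: str, position: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 2, _stable_seed(word), position])
        )
        return rng.standard_normal(self.dim) / np.sqrt(self.dim)

    def _distortion(self, word: str, position: int) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 3, _stable_seed(word), position])
        )
        return rng.standard_normal(self.dim) / np.sqrt(self.dim)

    def token_vectors(self, tokens, context=()) -> np.ndarray:
        all_tokens = list(context) + list(tokens)
        T = len(all_tokens)
        surps = None
        if self.surprisal_coupling > 0:
            surps = self.token_surprisals(all_tokens)
        contribs = np.empty((T, self.dim))
        for i, w in enumerate(all_tokens):
            c = self._base(w)
            if self.order_sensitivity > 0:
                c = c + self.order_sensitivity * self._positional(w, i)
            if surps is not None:
                c = c + self.surprisal_coupling * surps[i] * self._distortion(w, i)
            contribs[i] = c
        running_mean = np.cumsum(contribs, axis=0) / np.arange(1, T + 1)[:, None]
        out = np.empty((self.num_layers, len(tokens), self.dim))
        start = len(context)
        for layer, lam in enumerate(self._mix):
            out[layer] = (1 - lam) * contribs[start:] + lam * running_mean[start:]
        return out

    # -- surprisal ---------------------------------------------------------
    def token_surprisals(self, tokens, context=()) -> np.ndarray:
        if self.surprisal_model == "uniform":
            return np.full(len(tokens), np.log(self.vocab_size))
        if self.surprisal_model == "oracle":
            return np.zeros(len(tokens))
        if self.surprisal_model == "bigram":
            prev = context[-1] if context else "<s>"
            out = np.empty(len(tokens))
            V = max(1, self.vocab_size)
            for i, w in enumerate(tokens):
                num = self.bigram_counts.get((prev, w), 0) + self.alpha
                den = self.unigram_counts.get(prev, 0) + self.alpha * V
                out[i] = -np.log(num / den)
                prev = w
            return out
        raise ValueError(f"unknown surprisal model {self.surprisal_model!r}")


# ---------------------------------------------------------------------------
# Simulated brain responses


def content_bag_features(
    stimulus_set: StimulusSet, classes_per_sentence: Sequence[Sequence[str]]
) -> tuple[np.ndarray, list[str]]:
    """Bag-of-content-words count features (sentences x content vocabulary)."""
    vocab = sorted(
        {
            w
            for s, cls in zip(stimulus_set, classes_per_sentence)
            for w, c in zip(s.words, cls)
            if c != FUNCTION
        }
    )
    index = {w: i for i, w in enumerate(vocab)}
    F = np.zeros((len(stimulus_set), len(vocab)))
    for i, (s, cls) in enumerate(zip(stimulus_set, classes_per_sentence)):
        for w, c in zip(s.words, cls):
            if c != FUNCTION:
                F[i, index[w]] += 1.0
    return F, vocab


def generate_brain_data(
    stimulus_set: StimulusSet,
    classes_per_sentence: Sequence[Sequence[str]] | None = None,
    backend: Backend | None = None,
    readout: str = "content_bag",
    participants: int = 5,
    voxels: int = 20,
    noise_sigma: float = 1.0,
    seed: int = 0,
    layer: int = -1,
    proj_dim: int = 10,
) -> tuple[list[BrainData], dict]:
    """Simulate voxel responses as a noisy linear readout of sentence features.

    voxel response = w^T f(sentence) + eps, eps ~ N(0, noise_sigma^2) i.i.d.
    per voxel and participant. ``readout`` picks the ground-truth feature map
    f: ``content_bag`` (bag-of-content-words counts; needs the token classes)
    or ``embedding_subspace`` (a fixed random projection of a backend layer's
    decontextualized last-token summaries). The noise-free signal is
    standardized to unit variance per voxel within each experiment, so the
    per-voxel SNR is exactly 1/noise_sigma^2 and all participants share the
    signal exactly. Returns one BrainData per experiment plus ground truth
    (weights, feature matrix, per-experiment signal).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _stable_seed("brain")]))
    if readout == "content_bag":
        if classes_per_sentence is None:
            raise ValueError("content_bag readout requires token classes")
        F, _ = content_bag_features(stimulus_set, classes_per_sentence)
    elif readout == "embedding_subspace":
        if backend is None:
            raise ValueError("embedding_subspace readout requires a backend")
        from .embeddings import embed_condition  # local import to avoid cycle

        original = PerturbedCondition(
            "Original",
            [s.tokens for s in stimulus_set],
            np.arange(len(stimulus_set)),
        )
        tensor = embed_condition(
            backend, original, stimulus_set, contextualized=False,
            summary_mode="last_token",
        )
        E = tensor.layers[layer]
        proj = rng.standard_normal((E.shape[1], proj_dim)) / np.sqrt(E.shape[1])
        F = E @ proj
    else:
        raise ValueError(f"unknown readout {readout!r}")

    W = rng.standard_normal((F.shape[1], voxels))
    signal = F @ W
    brain: list[BrainData] = []
    signals: dict[str, np.ndarray] = {}
    pids = [f"P{p:02d}" for p in range(participants)]
    for exp_id, rows in stimulus_set.experiment_index.items():
        sig = signal[np.asarray(rows)]
        sig = sig - sig.mean(axis=0)
        std = sig.std(axis=0)
        std[std == 0] = 1.0
        sig = sig / std
        signals[exp_id] = sig
        responses = {
            pid: sig + noise_sigma * rng.standard_normal(sig.shape) for pid in pids
        }
        brain.append(BrainData(exp_id, responses))
    ground_truth = {
        "weights": W,
        "features": F,
        "signals": signals,
        "noise_sigma": noise_sigma,
        "readout": readout,
    }
    return brain, ground_truth
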
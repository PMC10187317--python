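"""Perturbation and control condition generators.

Conditions fall into four families:

* word-order manipulations that permute each sentence's words in place
  (k local adjacent swaps, full reversal, deterministic and stochastic
  low-PMI scrambles);
* information-loss manipulations that keep an ordered subsequence of words
  by part-of-speech class;
* semantic-distance manipulations that substitute whole sentences within a
  scope of the hierarchy (passage, topic, or the whole experiment) via
  fixed-point-free permutations, plus externally supplied paraphrases;
* controls: a dataset-wide random word list, length-matched random nouns,
  and a single-word length control.

Every stochastic generator takes a numpy Generator (or seed) and is
bit-reproducible. The terminal period token never participates in swaps,
scrambles, filters, or substitutions; it stays terminal in every condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    CONTENT_CLASSES,
    FUNCTION,
    NOUN,
    PERIOD,
    StimulusSet,
    normalize_tokens,
)
from .pmi import NgramCounts, string_pmi

WORD_ORDER_CONDITIONS = (
    "1LocalWordSwap",
    "3LocalWordSwaps",
    "5LocalWordSwaps",
    "7LocalWordSwaps",
    "ReverseOrder",
    "LowPMI",
    "LowPMIRandom",
)
INFORMATION_LOSS_CONDITIONS = (
    "KeepContentW",
    "KeepNVAdj",
    "KeepNV",
    "KeepN",
    "KeepFunctionW",
)
SEMANTIC_DISTANCE_CONDITIONS = (
    "Paraphrase",
    "RandSentFromPassage",
    "RandSentFromTopic",
    "RandSent",
)
CONTROL_CONDITIONS = ("RandWordList", "RandN", "LengthControl")
ALL_CONDITIONS = (
    ("Original",)
    + WORD_ORDER_CONDITIONS
    + INFORMATION_LOSS_CONDITIONS
    + SEMANTIC_DISTANCE_CONDITIONS
    + CONTROL_CONDITIONS
)

KEEP_SETS = {
    "KeepContentW": frozenset(CONTENT_CLASSES),
    "KeepNVAdj": frozenset({"NOUN", "VERB", "ADJ"}),
    "KeepNV": frozenset({"NOUN", "VERB"}),
    "KeepN": frozenset({"NOUN"}),
    "KeepFunctionW": frozenset({FUNCTION}),
}

#: scope of the sentence-substitution derangement per condition
SUBSTITUTION_SCOPE = {
    "RandSent": "all",
    "RandSentFromPassage": "passage",
    "RandSentFromTopic": "topic",
}


class InfeasibleSwapCount(ValueError):
    """No admissible k-swap scramble found within the retry budget."""


class CandidateExhaustion(RuntimeError):
    """Could not sample enough distinct admissible permutations."""


class SamplingFailure(RuntimeError):
    """Rejection sampling exhausted max_tries (derangements)."""


@dataclass
class PerturbedCondition:
    """Per-sentence perturbed token sequences plus generation metadata.

    ``substitution_map[i]`` gives the index of the original sentence whose
    (perturbed) content now sits at position i; it is the identity for all
    non-substitution conditions.
    """

    condition_name: str
    sentences: list[tuple[str, ...]]
    substitution_map: np.ndarray
    seed: int | None = None
    k: int | None = None
    pmi_scores: list[float] | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sentences)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _with_period(words: Sequence[str]) -> tuple[str, ...]:
    return tuple(words) + (PERIOD,)


# ---------------------------------------------------------------------------
# Word-order manipulations


def count_inversions(perm: Sequence[int]) -> int:
    """Number of inversions = minimum adjacent-transposition (Kendall) distance."""
    perm = list(perm)
    return sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )


def adjacent_transposition_distance(
    original: Sequence[str], perturbed: Sequence[str]
) -> int:
    """Minimum number of adjacent swaps turning ``original`` into ``perturbed``.

    Duplicate words are matched stably (leftmost unused occurrence), which
    minimizes the distance over all consistent matchings. Terminal periods
    are ignored. Raises ValueError if the word multisets differ.
    """
    a = list(original)
    b = list(perturbed)
    if a and a[-1] == PERIOD:
        a = a[:-1]
    if b and b[-1] == PERIOD:
        b = b[:-1]
    if sorted(a) != sorted(b):
        raise ValueError("sequences are not permutations of each other")
    positions: dict[str, list[int]] = {}
    for idx, w in enumerate(a):
        positions.setdefault(w, []).append(idx)
    used: dict[str, int] = {w: 0 for w in positions}
    perm = []
    for w in b:
        perm.append(positions[w][used[w]])
        used[w] += 1
    return count_inversions(perm)


def local_word_swaps(
    tokens: Sequence[str], k: int, rng, max_retries: int = 1000
) -> tuple[str, ...]:
    """Apply exactly k effective adjacent-neighbor swaps to the word tokens.

    Performs k random adjacent transpositions and verifies that none undid
    another: the adjacent-transposition distance of the resulting index
    permutation from the identity must equal k; otherwise resample.
    """
    words = list(tokens)
    has_period = words and words[-1] == PERIOD
    if has_period:
        words = words[:-1]
    n = len(words)
    if k == 0:
        return _with_period(words) if has_period else tuple(words)
    if n < k + 1:
        raise InfeasibleSwapCount(f"need at least {k + 1} words for k={k}, got {n}")
    rng = _as_rng(rng)
    for _ in range(max_retries):
        perm = list(range(n))
        for _ in range(k):
            i = int(rng.integers(0, n - 1))
            perm[i], perm[i + 1] = perm[i + 1], perm[i]
        if count_inversions(perm) == k:
            out = [words[p] for p in perm]
            return _with_period(out) if has_period else tuple(out)
    raise InfeasibleSwapCount(
        f"no admissible k={k} scramble for n={n} within {max_retries} tries"
    )


def reverse_order(tokens: Sequence[str]) -> tuple[str, ...]:
    """Reverse the word tokens; the terminal period stays terminal."""
    words = list(tokens)
    has_period = words and words[-1] == PERIOD
    if has_period:
        words = words[:-1]
    out = list(reversed(words))
    return _with_period(out) if has_period else tuple(out)


def low_pmi(tokens: Sequence[str], classes: Sequence[str]) -> tuple[str, ...]:
    """Deterministic low-PMI scramble via the four-list construction.

    Content and function words are listed in sentence order; each list is
    split into odd- and even-numbered members (1-based position within the
    list) and re-concatenated as oddContent ++ oddFunction ++ evenFunction ++
    evenContent, so all function words intervene between the two content-word
    lists and originally adjacent content words end up maximally far apart.
    """
    words = list(tokens)
    if words and words[-1] == PERIOD:
        words = words[:-1]
    if len(classes) != len(words):
        raise ValueError("classes must align with word tokens")
    content = [w for w, c in zip(words, classes) if c in CONTENT_CLASSES]
    function = [w for w, c in zip(words, classes) if c not in CONTENT_CLASSES]
    out = content[0::2] + function[0::2] + function[1::2] + content[1::2]
    return _with_period(out)


def low_pmi_random(
    tokens: Sequence[str],
    counts: NgramCounts,
    rng,
    n_candidates: int = 10,
    exclusions: Sequence[Sequence[str]] = (),
    max_tries: int = 1000,
) -> tuple[str, ...]:
    """Lowest-PMI permutation among ``n_candidates`` sampled word scrambles.

    Candidates are distinct full token sequences, never equal to the identity
    or to any excluded sequence (typically the k-local-swap outputs of the
    same sentence). Ties go to the first-sampled candidate.
    """
    words = list(tokens)
    has_period = words and words[-1] == PERIOD
    if has_period:
        words = words[:-1]
    if len(words) < 2:
        raise ValueError("need >= 2 word tokens")
    rng = _as_rng(rng)
    banned = {tuple(words)}
    for seq in exclusions:
        seq = tuple(seq)
        banned.add(seq[:-1] if seq and seq[-1] == PERIOD else seq)
    candidates: list[tuple[str, ...]] = []
    seen = set()
    tries = 0
    while len(candidates) < n_candidates:
        if tries >= max_tries:
            raise CandidateExhaustion(
                f"found {len(candidates)}/{n_candidates} admissible permutations "
                f"in {max_tries} tries"
            )
        tries += 1
        perm = rng.permutation(len(words))
        cand = tuple(words[p] for p in perm)
        if cand in banned or cand in seen:
            continue
        seen.add(cand)
        candidates.append(cand)
    scores = [string_pmi(c, counts) for c in candidates]
    best = candidates[int(np.argmin(scores))]
    return _with_period(best) if has_period else best


# ---------------------------------------------------------------------------
# Information-loss manipulations


def keep_classes(
    tokens: Sequence[str], classes: Sequence[str], keep_set
) -> tuple[str, ...]:
    """Ordered subsequence of word tokens whose class is in ``keep_set``."""
    words = list(tokens)
    if words and words[-1] == PERIOD:
        words = words[:-1]
    if len(classes) != len(words):
        raise ValueError("classes must align with word tokens")
    keep_set = frozenset(keep_set)
    out = [w for w, c in zip(words, classes) if c in keep_set]
    return _with_period(out)


# ---------------------------------------------------------------------------
# Controls


def rand_word_list(stimulus_set: StimulusSet, rng) -> PerturbedCondition:
    """Replace every word by a draw without replacement from the pooled words.

    Equivalent to one global permutation of all word tokens across the
    dataset, partitioned back into the original sentence lengths; the
    corpus-wide token multiset and per-sentence lengths are conserved.
    """
    rng = _as_rng(rng)
    pool = [w for s in stimulus_set for w in s.words]
    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]
    sentences = []
    cursor = 0
    for s in stimulus_set:
        sentences.append(_with_period(shuffled[cursor : cursor + s.n]))
        cursor += s.n
    return PerturbedCondition(
        "RandWordList", sentences, np.arange(len(stimulus_set))
    )


def rand_nouns_control(
    stimulus_set: StimulusSet,
    classes_per_sentence: Sequence[Sequence[str]],
    rng,
) -> PerturbedCondition:
    """KeepN-length strings of nouns sampled from the dataset-wide noun pool."""
    rng = _as_rng(rng)
    pool = [
        w
        for s, cls in zip(stimulus_set, classes_per_sentence)
        for w, c in zip(s.words, cls)
        if c == NOUN
    ]
    if not pool:
        raise ValueError("noun pool is empty")
    sentences = []
    for s, cls in zip(stimulus_set, classes_per_sentence):
        n_nouns = sum(1 for c in cls if c == NOUN)
        if n_nouns == 0:
            sentences.append(_with_period(()))
            continue
        draw = rng.choice(len(pool), size=n_nouns, replace=n_nouns > len(pool))
        sentences.append(_with_period([pool[i] for i in draw]))
    return PerturbedCondition("RandN", sentences, np.arange(len(stimulus_set)))


DEFAULT_FILL_WORD = "thing"


def length_control(tokens: Sequence[str], fill_word: str = DEFAULT_FILL_WORD) -> tuple[str, ...]:
    """n copies of ``fill_word`` plus the terminal period."""
    if not fill_word:
        raise ValueError("fill_word must be nonempty")
    words = list(tokens)
    if words and words[-1] == PERIOD:
        words = words[:-1]
    return _with_period([fill_word] * len(words))


# ---------------------------------------------------------------------------
# Semantic-distance manipulations


def derange(n: int, rng, max_tries: int = 100) -> np.ndarray:
    """Uniformly sampled fixed-point-free permutation of range(n).

    For n == 1 no derangement exists and the identity is returned (the
    "whenever possible" rule for singleton scope groups). Rejection sampling
    from uniform permutations; acceptance probability tends to 1/e.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.zeros(1, dtype=np.intp)
    rng = _as_rng(rng)
    idx = np.arange(n)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            return perm
    raise SamplingFailure(f"no derangement of size {n} in {max_tries} tries")


def scope_derangement(labels: Sequence, rng, max_tries: int = 100) -> np.ndarray:
    """Permutation of sentence indices deranging within each scope group.

    ``labels[i]`` is the group label of sentence i; within each group a
    uniform derangement is applied (singleton groups map to themselves).
    """
    rng = _as_rng(rng)
    labels = list(labels)
    perm = np.arange(len(labels), dtype=np.intp)
    groups: dict = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    for idxs in groups.values():
        idxs = np.asarray(idxs, dtype=np.intp)
        perm[idxs] = idxs[derange(len(idxs), rng, max_tries)]
    return perm


def rand_sent(
    stimulus_set: StimulusSet,
    level: str,
    rng,
    condition_name: str | None = None,
) -> PerturbedCondition:
    """Substitute each sentence by another from the same scope group.

    ``level`` is 'passage', 'topic', or 'all' (the whole experiment; the two
    experiments' sentences never mix). Reports the proportion of sentences
    whose replacement comes from a different topic / passage.
    """
    rng = _as_rng(rng)
    labels = stimulus_set.group_labels(level)
    perm = scope_derangement(labels, rng)
    sentences = [stimulus_set[i].tokens for i in perm]
    topics = [(s.experiment_id, s.topic_id) for s in stimulus_set]
    passages = [(s.experiment_id, s.passage_id) for s in stimulus_set]
    meta = {
        "cross_topic_fraction": float(
            np.mean([topics[p] != topics[i] for i, p in enumerate(perm)])
        ),
        "cross_passage_fraction": float(
            np.mean([passages[p] != passages[i] for i, p in enumerate(perm)])
        ),
        "scope": level,
    }
    if condition_name is None:
        condition_name = {
            "all": "RandSent",
            "passage": "RandSentFromPassage",
            "topic": "RandSentFromTopic",
        }[level]
    return PerturbedCondition(condition_name, sentences, perm, metadata=meta)


def paraphrase_condition(
    stimulus_set: StimulusSet, paraphrases: Sequence[str]
) -> PerturbedCondition:
    """Substitute normalized paraphrases 1:1 and report validation stats.

    ``paraphrases`` holds one raw paraphrase text per sentence, aligned with
    the stimulus order. The metadata records per-sentence word-count
    differences (paraphrase minus original) and word-overlap fractions
    (|shared types| / |union of types|).
    """
    if len(paraphrases) != len(stimulus_set):
        raise ValueError(
            f"expected {len(stimulus_set)} paraphrase rows, got {len(paraphrases)}"
        )
    sentences = []
    length_diffs = []
    overlaps = []
    for s, para in zip(stimulus_set, paraphrases):
        tokens = normalize_tokens(para)
        sentences.append(tokens)
        p_words = set(tokens[:-1])
        o_words = set(s.words)
        length_diffs.append(len(tokens) - 1 - s.n)
        overlaps.append(len(p_words & o_words) / len(p_words | o_words))
    return PerturbedCondition(
        "Paraphrase",
        sentences,
        np.arange(len(stimulus_set)),
        metadata={
            "length_diffs": length_diffs,
            "overlap_fractions": overlaps,
            "mean_length_diff": float(np.mean(length_diffs)),
            "mean_overlap": float(np.mean(overlaps)),
        },
    )


# ---------------------------------------------------------------------------
# Orchestration

_SWAP_K = {"1LocalWordSwap": 1, "3LocalWordSwaps": 3, "5LocalWordSwaps": 5, "7LocalWordSwaps": 7}


def generate_condition(
    name: str,
    stimulus_set: StimulusSet,
    classes_per_sentence: Sequence[Sequence[str]] | None = None,
    counts: NgramCounts | None = None,
    seed: int | None = None,
    paraphrases: Sequence[str] | None = None,
    fill_word: str = DEFAULT_FILL_WORD,
    swap_exclusions: Mapping[int, Sequence[Sequence[str]]] | None = None,
    score_pmi: bool = False,
) -> PerturbedCondition:
    """Generate any named condition from a stimulus set.

    ``swap_exclusions`` maps sentence index -> token sequences that
    LowPMIRandom must avoid (the local-swap outputs for that sentence).
    """
    if name not in ALL_CONDITIONS:
        raise ValueError(f"unknown condition {name!r}; known: {ALL_CONDITIONS}")
    rng = np.random.default_rng(seed)
    identity = np.arange(len(stimulus_set))

    def _needs_classes():
        if classes_per_sentence is None:
            raise ValueError(f"condition {name} requires token classifications")

    def _needs_counts():
        if counts is None:
            raise ValueError(f"condition {name} requires n-gram counts")

    if name == "Original":
        cond = PerturbedCondition(name, [s.tokens for s in stimulus_set], identity)
    elif name in _SWAP_K:
        k = _SWAP_K[name]
        # short sentences receive the largest feasible swap count (k <= n-1)
        cond = PerturbedCondition(
            name,
            [
                local_word_swaps(s.tokens, min(k, s.n - 1), rng)
                for s in stimulus_set
            ],
            identity,
            k=k,
        )
    elif name == "ReverseOrder":
        cond = PerturbedCondition(
            name, [reverse_order(s.tokens) for s in stimulus_set], identity
        )
    elif name == "LowPMI":
        _needs_classes()
        cond = PerturbedCondition(
            name,
            [
                low_pmi(s.tokens, cls)
                for s, cls in zip(stimulus_set, classes_per_sentence)
            ],
            identity,
        )
    elif name == "LowPMIRandom":
        _needs_counts()
        sentences = []
        for i, s in enumerate(stimulus_set):
            excl = swap_exclusions.get(i, ()) if swap_exclusions else ()
            sentences.append(low_pmi_random(s.tokens, counts, rng, exclusions=excl))
        cond = PerturbedCondition(name, sentences, identity)
    elif name in KEEP_SETS:
        _needs_classes()
        cond = PerturbedCondition(
            name,
            [
                keep_classes(s.tokens, cls, KEEP_SETS[name])
                for s, cls in zip(stimulus_set, classes_per_sentence)
            ],
            identity,
        )
    elif name in SUBSTITUTION_SCOPE:
        cond = rand_sent(stimulus_set, SUBSTITUTION_SCOPE[name], rng, name)
    elif name == "Paraphrase":
        if paraphrases is None:
            raise ValueError("Paraphrase condition requires a paraphrase table")
        cond = paraphrase_condition(stimulus_set, paraphrases)
    elif name == "RandWordList":
        cond = rand_word_list(stimulus_set, rng)
    elif name == "RandN":
        _needs_classes()
        cond = rand_nouns_control(stimulus_set, classes_per_sentence, rng)
    elif name == "LengthControl":
        cond = PerturbedCondition(
            name,
            [length_control(s.tokens, fill_word) for s in stimulus_set],
            identity,
            metadata={"fill_word": fill_word},
        )
    else:  # pragma: no cover
        raise AssertionError(name)

    cond.seed = seed
    if score_pmi and counts is not None:
        cond.pmi_scores = [
            string_pmi(toks, counts) if len(toks) > 2 else 0.0
            for toks in cond.sentences
        ]
    return cond
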
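"""Positive pointwise-mutual-information scoring of token strings.

A string's PMI score averages the positive PMI of all word pairs that occur
within a sliding four-word window — equivalently all pairs (i, j) with
1 <= j - i <= 3 — using Laplace-smoothed probabilities from an n-gram count
table:

    PMI(w_1..w_n) = 1/(3n - 2) * sum_i sum_{j=i+1}^{min(i+3, n)}
                    max(0, ln P(w_i, w_j) / (P(w_i) P(w_j)))

The 1/(3n - 2) normalizer is used as printed in the source analysis, although
the number of windowed pairs is 3n - 6 for n >= 4; the constant scales all
scores equally and does not affect any argmin/argmax use. Pair probabilities
are estimated over *unordered* pairs, which makes the score exactly invariant
to sequence reversal. The terminal period token is excluded throughout.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import PERIOD

DEFAULT_ALPHA = 0.1
WINDOW_GAP = 3  # max index gap inside a sliding four-word window


class DegenerateStringError(ValueError):
    """Fewer than two word tokens: no windowed pairs exist."""


def _pair_key(w: str, v: str) -> tuple[str, str]:
    return (w, v) if w <= v else (v, w)


def strip_period(tokens: Sequence[str]) -> tuple[str, ...]:
    toks = tuple(tokens)
    return toks[:-1] if toks and toks[-1] == PERIOD else toks


def window_pairs(tokens: Sequence[str]) -> list[tuple[int, int]]:
    """0-based index pairs (i, j) with 1 <= j - i <= 3; period excluded.

    Yields exactly 3n - 6 pairs for n >= 4 word tokens.
    """
    words = strip_period(tokens)
    n = len(words)
    if n < 2:
        raise DegenerateStringError(f"need >= 2 word tokens, got {n}")
    return [
        (i, j)
        for i in range(n - 1)
        for j in range(i + 1, min(i + WINDOW_GAP, n - 1) + 1)
    ]


@dataclass
class NgramCounts:
    """Unigram and unordered windowed-pair counts with Laplace smoothing.

    Smoothing adds ``alpha`` to every unigram count over the declared
    vocabulary (size V) and to every unordered pair count over the V(V+1)/2
    unordered pairs (self-pairs included, since a word may co-occur with
    itself inside a window); denominators are adjusted accordingly so each
    smoothed distribution sums to one.
    """

    unigrams: Counter = field(default_factory=Counter)
    pairs: Counter = field(default_factory=Counter)
    total_unigrams: int = 0
    total_pairs: int = 0
    alpha: float = DEFAULT_ALPHA
    vocabulary_size: int = 0

    def __post_init__(self):
        if self.vocabulary_size == 0:
            self.vocabulary_size = len(self.unigrams)
        if self.total_unigrams == 0:
            self.total_unigrams = sum(self.unigrams.values())
        if self.total_pairs == 0:
            self.total_pairs = sum(self.pairs.values())

    # -- probabilities -----------------------------------------------------
    def unigram_count(self, w: str) -> int:
        return self.unigrams.get(w, 0)

    def pair_count(self, w: str, v: str) -> int:
        return self.pairs.get(_pair_key(w, v), 0)

    def p_word(self, w: str) -> float:
        V = self.vocabulary_size
        return (self.unigram_count(w) + self.alpha) / (
            self.total_unigrams + self.alpha * V
        )

    def p_pair(self, w: str, v: str) -> float:
        V = self.vocabulary_size
        n_pair_types = V * (V + 1) // 2
        return (self.pair_count(w, v) + self.alpha) / (
            self.total_pairs + self.alpha * n_pair_types
        )

    # -- construction ------------------------------------------------------
    @classmethod
    def from_corpus(
        cls,
        token_sequences: Iterable[Sequence[str]],
        alpha: float = DEFAULT_ALPHA,
        vocabulary: Iterable[str] | None = None,
    ) -> "NgramCounts":
        """Accumulate counts over token sequences (terminal periods ignored)."""
        unigrams: Counter = Counter()
        pairs: Counter = Counter()
        for seq in token_sequences:
            words = strip_period(seq)
            unigrams.update(words)
            if len(words) >= 2:
                for i, j in window_pairs(words):
                    pairs[_pair_key(words[i], words[j])] += 1
        counts = cls(unigrams=unigrams, pairs=pairs, alpha=alpha)
        if vocabulary is not None:
            vocab = set(vocabulary) | set(unigrams)
            counts.vocabulary_size = len(vocab)
        return counts

    # -- TSV I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write counts: a header record then (w, count) and (w, v, count) rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "#total_unigrams\t%d\t#total_pairs\t%d\t#vocabulary_size\t%d\t#alpha\t%g\n"
                % (self.total_unigrams, self.total_pairs, self.vocabulary_size, self.alpha)
            )
            for w, c in sorted(self.unigrams.items()):
                fh.write(f"{w}\t{c}\n")
            for (w, v), c in sorted(self.pairs.items()):
                fh.write(f"{w}\t{v}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NgramCounts":
        unigrams: Counter = Counter()
        pairs: Counter = Counter()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            meta = dict(zip(header[::2], header[1::2]))
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 2:
                    unigrams[parts[0]] = int(parts[1])
                elif len(parts) == 3:
                    pairs[_pair_key(parts[0], parts[1])] = int(parts[2])
                else:
                    raise ValueError(f"{path}: malformed counts row {line!r}")
        return cls(
            unigrams=unigrams,
            pairs=pairs,
            total_unigrams=int(meta.get("#total_unigrams", 0)),
            total_pairs=int(meta.get("#total_pairs", 0)),
            alpha=float(meta.get("#alpha", DEFAULT_ALPHA)),
            vocabulary_size=int(meta.get("#vocabulary_size", 0)),
        )


def positive_pmi(w: str, v: str, counts: NgramCounts) -> float:
    """max(0, ln P(w,v) / (P(w) P(v))) under Laplace smoothing."""
    ratio = counts.p_pair(w, v) / (counts.p_word(w) * counts.p_word(v))
    return max(0.0, math.log(ratio))


def string_pmi(tokens: Sequence[str], counts: NgramCounts) -> float:
    """Normalized sum of positive PMI over all windowed pairs of the string.

    Uses exact summation (math.fsum), so the score is bit-identical under any
    reordering of the pair multiset — in particular under full reversal.
    """
    words = strip_period(tokens)
    pairs = window_pairs(words)
    n = len(words)
    total = math.fsum(positive_pmi(words[i], words[j], counts) for i, j in pairs)
    return total / (3 * n - 2)
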
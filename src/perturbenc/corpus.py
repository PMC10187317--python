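"""Stimulus corpus: sentence normalization, hierarchical stimulus sets, token
classification, and tab-separated file I/O.

A stimulus set is organized hierarchically: experiment -> topic -> passage ->
sentence. Every sentence is stored as lowercase word tokens followed by a
distinguished terminal period token; sentence-internal punctuation other than
hyphens and apostrophes is stripped during normalization. The terminal period
is excluded from word counts, class filters, and all perturbation operations.

Part-of-speech classification is total over word tokens and maps every token to
one of five classes: NOUN (including pronouns and proper names), VERB, ADJ,
ADV, or FUNCTION. Taggers are pluggable callables returning Penn-Treebank-style
tags, so analyses never depend on a particular third-party tagger version.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

PERIOD = "."

NOUN = "NOUN"
VERB = "VERB"
ADJ = "ADJ"
ADV = "ADV"
FUNCTION = "FUNCTION"

WORD_CLASSES = (NOUN, VERB, ADJ, ADV, FUNCTION)
CONTENT_CLASSES = frozenset({NOUN, VERB, ADJ, ADV})

#: Penn-Treebank tag prefix -> word class. Pronouns (PRP, PRP$, WP, WP$) and
#: proper names (NNP, NNPS) map to NOUN; modals and everything unlisted are
#: FUNCTION words.
DEFAULT_TAG_MAP: dict[str, str] = {
    "NN": NOUN, "NNS": NOUN, "NNP": NOUN, "NNPS": NOUN,
    "PRP": NOUN, "PRP$": NOUN, "WP": NOUN, "WP$": NOUN,
    "VB": VERB, "VBD": VERB, "VBG": VERB, "VBN": VERB, "VBP": VERB, "VBZ": VERB,
    "JJ": ADJ, "JJR": ADJ, "JJS": ADJ,
    "RB": ADV, "RBR": ADV, "RBS": ADV,
}


class StimulusError(ValueError):
    """Invalid stimulus text or malformed stimulus table."""


class TaggingError(RuntimeError):
    """A pluggable tagger failed on a token; carries the token index."""

    def __init__(self, message: str, token_index: int | None = None):
        super().__init__(message)
        self.token_index = token_index


_KEEP_CHARS = re.compile(r"[^a-z0-9'\-]+")


def normalize_tokens(raw_text: str) -> tuple[str, ...]:
    """Normalize a raw sentence into lowercase tokens plus a terminal period.

    Internal punctuation is stripped except hyphens and apostrophes (curly
    apostrophes are mapped to ASCII). A terminal period token is appended
    whether or not the raw text ended in one. Idempotent on its own output.
    """
    if raw_text is None or not raw_text.strip():
        raise StimulusError("empty or whitespace-only stimulus text")
    text = raw_text.lower().replace("’", "'").replace("‘", "'")
    text = text.replace("—", " ").replace("–", " ")
    tokens = []
    for piece in text.split():
        if piece == PERIOD:
            continue
        word = _KEEP_CHARS.sub("", piece)
        word = word.strip("'-")  # keep clitics/hyphens only word-internally
        if word:
            tokens.append(word)
    if not tokens:
        raise StimulusError(f"no word tokens after normalization: {raw_text!r}")
    return tuple(tokens) + (PERIOD,)


@dataclass(frozen=True)
class Sentence:
    """One normalized sentence with its position in the stimulus hierarchy.

    ``tokens`` includes the terminal period; ``words``/``n`` exclude it.
    ``position`` is the 1-based index within the passage.
    """

    tokens: tuple[str, ...]
    experiment_id: str
    topic_id: str
    passage_id: str
    position: int

    def __post_init__(self):
        if not self.tokens or self.tokens[-1] != PERIOD:
            raise StimulusError("sentence tokens must end with the period token")
        if any(t == PERIOD for t in self.tokens[:-1]):
            raise StimulusError("internal period token not allowed")

    @property
    def words(self) -> tuple[str, ...]:
        return self.tokens[:-1]

    @property
    def n(self) -> int:
        return len(self.tokens) - 1

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


class StimulusSet:
    """Ordered sentences plus the experiment/topic/passage hierarchy index."""

    def __init__(self, sentences: Sequence[Sentence]):
        self.sentences: list[Sentence] = list(sentences)
        if not self.sentences:
            raise StimulusError("stimulus set is empty")
        self._index()

    def _index(self):
        self.passage_index: dict[tuple[str, str], list[int]] = defaultdict(list)
        self.topic_index: dict[tuple[str, str], list[int]] = defaultdict(list)
        self.experiment_index: dict[str, list[int]] = defaultdict(list)
        passage_topic: dict[tuple[str, str], str] = {}
        topic_exp: dict[tuple[str, str], str] = {}
        seen_keys = set()
        for i, s in enumerate(self.sentences):
            pkey = (s.experiment_id, s.passage_id)
            key = (s.experiment_id, s.passage_id, s.position)
            if key in seen_keys:
                raise StimulusError(f"duplicate (passage, position) key {key}")
            seen_keys.add(key)
            if pkey in passage_topic and passage_topic[pkey] != s.topic_id:
                raise StimulusError(f"passage {pkey} spans multiple topics")
            passage_topic[pkey] = s.topic_id
            tkey = (s.experiment_id, s.topic_id)
            if tkey in topic_exp and topic_exp[tkey] != s.experiment_id:
                raise StimulusError(f"topic {tkey} spans multiple experiments")
            topic_exp[tkey] = s.experiment_id
            self.passage_index[pkey].append(i)
            self.topic_index[tkey].append(i)
            self.experiment_index[s.experiment_id].append(i)
        for pkey, idxs in self.passage_index.items():
            positions = [self.sentences[i].position for i in idxs]
            if sorted(positions) != list(range(1, len(idxs) + 1)):
                raise StimulusError(
                    f"passage {pkey}: positions {positions} are not contiguous 1..k"
                )
            if idxs != sorted(idxs):
                raise StimulusError(f"passage {pkey}: sentences are not contiguous")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __getitem__(self, i: int) -> Sentence:
        return self.sentences[i]

    @property
    def experiments(self) -> list[str]:
        return list(self.experiment_index)

    def group_labels(self, level: str) -> list[tuple]:
        """Per-sentence scope-group label at ``level`` in {'all','topic','passage'}."""
        if level == "all":
            return [(s.experiment_id,) for s in self.sentences]
        if level == "topic":
            return [(s.experiment_id, s.topic_id) for s in self.sentences]
        if level == "passage":
            return [(s.experiment_id, s.passage_id) for s in self.sentences]
        raise ValueError(f"unknown scope level {level!r}")


# ---------------------------------------------------------------------------
# Token classification


class LexiconTagger:
    """Dictionary-backed Penn-Treebank tagger for fixtures and synthetic data."""

    def __init__(self, lexicon: Mapping[str, str], default: str | None = None):
        self.lexicon = dict(lexicon)
        self.default = default

    def __call__(self, words: Sequence[str]) -> list[str]:
        tags = []
        for i, w in enumerate(words):
            tag = self.lexicon.get(w, self.default)
            if tag is None:
                raise TaggingError(f"no tag for token {w!r} at index {i}", i)
            tags.append(tag)
        return tags


def classify_tokens(
    sentence: Sentence,
    tagger: Callable[[Sequence[str]], Sequence[str]],
    tag_map: Mapping[str, str] | None = None,
) -> tuple[str, ...]:
    """Classify every word token of ``sentence`` into one of the five classes.

    The terminal period is not classified. Unknown tags fall back to FUNCTION.
    """
    tag_map = DEFAULT_TAG_MAP if tag_map is None else tag_map
    words = sentence.words
    try:
        tags = list(tagger(words))
    except TaggingError:
        raise
    except Exception as exc:  # tagger implementations vary
        raise TaggingError(f"tagger failed on {words!r}: {exc}") from exc
    if len(tags) != len(words):
        raise TaggingError(
            f"tagger returned {len(tags)} tags for {len(words)} tokens"
        )
    return tuple(tag_map.get(tag, FUNCTION) for tag in tags)


# ---------------------------------------------------------------------------
# Stimulus table I/O (UTF-8 TSV)

TABLE_COLUMNS = ["experiment_id", "topic_id", "passage_id", "position", "text"]


def read_stimulus_table(path: str | Path) -> StimulusSet:
    """Read a stimulus TSV (experiment_id, topic_id, passage_id, position, text)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise StimulusError(f"{path}: missing columns {missing}")
    sentences = []
    for row in df.itertuples():
        line_no = row.Index + 2  # header is line 1
        try:
            position = int(row.position)
            tokens = normalize_tokens(row.text)
        except (ValueError, StimulusError) as exc:
            raise StimulusError(f"{path}: malformed row at line {line_no}: {exc}") from exc
        sentences.append(
            Sentence(tokens, row.experiment_id, row.topic_id, row.passage_id, position)
        )
    try:
        return StimulusSet(sentences)
    except StimulusError as exc:
        raise StimulusError(f"{path}: {exc}") from exc


def _table_frame(stimulus_set: StimulusSet, texts: Iterable[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "experiment_id": [s.experiment_id for s in stimulus_set],
            "topic_id": [s.topic_id for s in stimulus_set],
            "passage_id": [s.passage_id for s in stimulus_set],
            "position": [s.position for s in stimulus_set],
            "text": list(texts),
        }
    )


def write_stimulus_table(stimulus_set: StimulusSet, path: str | Path) -> None:
    """Write a stimulus TSV whose text column round-trips byte-exactly."""
    df = _table_frame(stimulus_set, (s.text for s in stimulus_set))
    df.to_csv(path, sep="\t", index=False)


def write_condition_table(condition, stimulus_set: StimulusSet, path: str | Path) -> None:
    """Write a perturbed condition as a stimulus TSV aligned with ``stimulus_set``."""
    texts = (" ".join(tokens) for tokens in condition.sentences)
    df = _table_frame(stimulus_set, texts)
    df.to_csv(path, sep="\t", index=False)
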
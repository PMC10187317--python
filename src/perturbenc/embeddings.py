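"""Per-layer sentence representations from a pluggable embedding backend.

A backend exposes per-token, per-layer vectors for a token sequence given an
optional preceding-context token sequence, plus per-token surprisal (natural
log) — see :class:`Backend`. The functions here turn backend outputs into
per-condition sentence representation tensors under two policies:

* contextualization — a sentence's context is the concatenation of the
  same-condition perturbed versions of all preceding sentences in its
  passage (first sentence: empty context), mirroring passage-by-passage
  presentation;
* sequence summary — either the final period token's vector (``last_token``)
  or the mean over the sentence's own token vectors (``mean_token``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import StimulusSet
from .perturb import PerturbedCondition

SUMMARY_MODES = ("last_token", "mean_token")


class ContextTooLongError(RuntimeError):
    """Backend cannot accept the supplied context; carries the sentence index."""

    def __init__(self, message: str, sentence_index: int | None = None):
        super().__init__(message)
        self.sentence_index = sentence_index


@runtime_checkable
class Backend(Protocol):
    """Contract for embedding backends.

    Implementations must be deterministic (identical inputs give identical
    outputs) and may depend on preceding text only through ``context``.
    """

    num_layers: int
    dim: int

    def token_vectors(
        self, tokens: Sequence[str], context: Sequence[str] = ()
    ) -> np.ndarray:
        """Per-layer vectors for ``tokens``, shape (num_layers, len(tokens), dim)."""
        ...

    def token_surprisals(
        self, tokens: Sequence[str], context: Sequence[str] = ()
    ) -> np.ndarray:
        """Per-token next-token surprisal in nats, shape (len(tokens),)."""
        ...


@dataclass
class EmbeddingTensor:
    """Sentence representations for one condition: array (layers, sentences, dim)."""

    condition_name: str
    contextualized: bool
    summary_mode: str
    layers: np.ndarray

    def __post_init__(self):
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must have shape (L, S, D)")
        if not np.all(np.isfinite(self.layers)):
            raise ValueError("non-finite values in embedding tensor")

    @property
    def num_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def num_sentences(self) -> int:
        return self.layers.shape[1]

    def save(self, path: str | Path) -> None:
        header = json.dumps(
            {
                "condition_name": self.condition_name,
                "contextualized": self.contextualized,
                "summary_mode": self.summary_mode,
                "num_layers": int(self.layers.shape[0]),
                "num_sentences": int(self.layers.shape[1]),
                "dim": int(self.layers.shape[2]),
            }
        )
        np.savez_compressed(path, header=np.array(header), layers=self.layers)

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTensor":
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            return cls(
                header["condition_name"],
                header["contextualized"],
                header["summary_mode"],
                data["layers"],
            )


def passage_contexts(
    condition: PerturbedCondition, stimulus_set: StimulusSet
) -> list[tuple[str, ...]]:
    """Same-condition context tokens (with periods) preceding each sentence."""
    contexts: list[tuple[str, ...]] = []
    for i, s in enumerate(stimulus_set):
        preceding = [
            j
            for j in stimulus_set.passage_index[(s.experiment_id, s.passage_id)]
            if stimulus_set[j].position < s.position
        ]
        ctx: list[str] = []
        for j in sorted(preceding, key=lambda j: stimulus_set[j].position):
            ctx.extend(condition.sentences[j])
        contexts.append(tuple(ctx))
    return contexts


def embed_condition(
    backend: Backend,
    condition: PerturbedCondition,
    stimulus_set: StimulusSet,
    contextualized: bool = True,
    summary_mode: str = "last_token",
) -> EmbeddingTensor:
    """Summarize each sentence of a condition into per-layer vectors."""
    if summary_mode not in SUMMARY_MODES:
        raise ValueError(f"summary_mode must be one of {SUMMARY_MODES}")
    if len(condition) != len(stimulus_set):
        raise ValueError("condition and stimulus set lengths differ")
    contexts = (
        passage_contexts(condition, stimulus_set)
        if contextualized
        else [()] * len(stimulus_set)
    )
    out = np.empty((backend.num_layers, len(stimulus_set), backend.dim))
    for i, tokens in enumerate(condition.sentences):
        try:
            vecs = backend.token_vectors(tokens, contexts[i])
        except ContextTooLongError as exc:
            raise ContextTooLongError(
                f"context too long for sentence {i}: {exc}", i
            ) from exc
        if summary_mode == "last_token":
            out[:, i, :] = vecs[:, -1, :]
        else:
            out[:, i, :] = vecs.mean(axis=1)
    return EmbeddingTensor(condition.condition_name, contextualized, summary_mode, out)


def mean_string_surprisal(
    backend: Backend,
    condition: PerturbedCondition,
    stimulus_set: StimulusSet,
    contextualized: bool = False,
) -> tuple[np.ndarray, float]:
    """Mean token surprisal (nats) per string, and the condition mean.

    The terminal period counts as part of the input string and is included
    in each string's average.
    """
    contexts = (
        passage_contexts(condition, stimulus_set)
        if contextualized
        else [()] * len(stimulus_set)
    )
    per_sentence = np.array(
        [
            float(np.mean(backend.token_surprisals(tokens, contexts[i])))
            for i, tokens in enumerate(condition.sentences)
        ]
    )
    return per_sentence, float(per_sentence.mean())
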
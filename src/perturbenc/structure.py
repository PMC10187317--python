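"""Structural simulations over the stimulus hierarchy.

These quantify properties of the sentence-substitution machinery that depend
only on the experiment/topic/passage structure, not on sentence content:

* how often a whole-experiment derangement replaces a sentence with one from
  a different topic or passage;
* what fraction of sentences cannot be shuffled (sole member of their scope
  group within a cross-validation test fold) under within-passage or
  within-topic test-set derangement.

Percentages are computed per experiment and averaged with equal weight across
experiments, matching how the encoding pipeline aggregates its results; the
substitution percentages pool all sentences instead (they describe the
condition's composition, not a per-experiment score).
"""

from __future__ import annotations

import numpy as np

from .encoding import make_folds, unshuffled_fraction
from .perturb import derange
from .synthetic import ExperimentSpec, SynthConfig


def hierarchy_labels(config: SynthConfig | None = None) -> list[dict]:
    """Per-experiment topic and passage labels for each sentence position."""
    config = config or SynthConfig()
    out = []
    for exp in config.experiments:
        topics, passages = [], []
        passage = 0
        for topic in range(exp.n_topics):
            for size in exp.passage_sizes_per_topic[topic]:
                topics.extend([topic] * size)
                passages.extend([passage] * size)
                passage += 1
        out.append(
            {
                "experiment": exp.name,
                "topics": np.asarray(topics),
                "passages": np.asarray(passages),
            }
        )
    return out


def substitution_cross_percentages(
    config: SynthConfig | None = None, n_seeds: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Percent of sentences whose whole-experiment derangement image comes
    from a different topic / different passage, pooled over all sentences
    and averaged over ``n_seeds`` derangements."""
    labels = hierarchy_labels(config)
    rng = np.random.default_rng(seed)
    cross_topic = []
    cross_passage = []
    for _ in range(n_seeds):
        n_total = ct = cp = 0
        for lab in labels:
            n = len(lab["topics"])
            perm = derange(n, rng)
            ct += int(np.sum(lab["topics"][perm] != lab["topics"]))
            cp += int(np.sum(lab["passages"][perm] != lab["passages"]))
            n_total += n
        cross_topic.append(100.0 * ct / n_total)
        cross_passage.append(100.0 * cp / n_total)
    return float(np.mean(cross_topic)), float(np.mean(cross_passage))


def unshuffled_percentage(
    scope: str,
    n_folds: int = 5,
    config: SynthConfig | None = None,
    n_seeds: int = 200,
    seed: int = 0,
) -> float:
    """Average percent of sentences left unshuffled by within-scope test-set
    derangement under ``n_folds``-fold by-sentence cross-validation.

    A sentence is unshuffled when it is the sole member of its scope group
    (``scope`` in {'passage', 'topic'}) inside its test fold. Per-experiment
    fractions are averaged with equal weight, then over seeds.
    """
    if scope not in ("passage", "topic"):
        raise ValueError("scope must be 'passage' or 'topic'")
    labels = hierarchy_labels(config)
    rng = np.random.default_rng(seed)
    key = "passages" if scope == "passage" else "topics"
    out = []
    for _ in range(n_seeds):
        per_exp = []
        for lab in labels:
            groups = lab[key]
            folds = make_folds(len(groups), "by_sentence", n_folds, rng)
            per_exp.append(unshuffled_fraction(folds.test_sets, list(groups)))
        out.append(100.0 * float(np.mean(per_exp)))
    return float(np.mean(out))
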
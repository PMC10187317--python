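"""Voxelwise linear encoding under cross-validation and the 2x2 design.

For each participant-specific voxel, an ordinary-least-squares regression maps
sentence representations to that voxel's repetition-averaged response. Under
k-fold cross-validation (default 5-fold, holding out 20% of sentences per
fold), predicted and measured responses on the held-out split are compared
with the Pearson correlation; per-voxel scores are averaged over folds, each
participant's score is the median over their voxels, and experiments are
fitted separately with their scores averaged (equal weight) per participant.

The 2x2 computational experimental design crosses (i) the training source of
the mapping — intact (Original) vs perturbed representations — with (ii) the
contextualization of the representations. Under TrainIntact-TestPerturbed,
sentence-substitution conditions (RandSent / RandSentFromPassage /
RandSentFromTopic) are realized by deranging the *Original* test-split
representations relative to the brain data within the applicable scope group
per fold; sentences that are the sole member of their scope group inside a
test fold cannot move, and their average fraction is reported as the
unshuffled fraction.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from .corpus import StimulusSet
from .embeddings import EmbeddingTensor
from .perturb import SUBSTITUTION_SCOPE, scope_derangement

DESIGN_NAMES = (
    "TrainIntact-TestPerturbed_Contextualized",
    "TrainPerturbed-TestPerturbed_Contextualized",
    "TrainIntact-TestPerturbed_Decontextualized",
    "TrainPerturbed-TestPerturbed_Decontextualized",
)


@dataclass(frozen=True)
class Design:
    """One cell of the 2x2 computational experimental design."""

    train_intact: bool
    contextualized: bool

    @property
    def name(self) -> str:
        train = "TrainIntact" if self.train_intact else "TrainPerturbed"
        ctx = "Contextualized" if self.contextualized else "Decontextualized"
        return f"{train}-TestPerturbed_{ctx}"

    @classmethod
    def from_name(cls, name: str) -> "Design":
        if name not in DESIGN_NAMES:
            raise ValueError(f"unknown design {name!r}; known: {DESIGN_NAMES}")
        return cls("TrainIntact" in name, name.endswith("_Contextualized"))


@dataclass
class BrainData:
    """Repetition-averaged sentence x voxel responses for one experiment."""

    experiment_id: str
    responses: dict[str, np.ndarray]  # participant id -> (n_sentences, n_voxels)

    def __post_init__(self):
        n = {pid: m.shape[0] for pid, m in self.responses.items()}
        if len(set(n.values())) > 1:
            raise ValueError(f"sentence counts differ across participants: {n}")
        for pid, m in self.responses.items():
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite responses for participant {pid}")

    @property
    def n_sentences(self) -> int:
        return next(iter(self.responses.values())).shape[0]

    @property
    def participants(self) -> list[str]:
        return list(self.responses)


@dataclass
class FoldSpec:
    """A partition of sentence indices into cross-validation test sets."""

    scheme: str
    n_folds: int
    test_sets: list[np.ndarray]
    seed: int | None = None

    def __post_init__(self):
        all_idx = np.concatenate(self.test_sets)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")


def make_folds(
    n_sentences: int,
    scheme: str = "by_sentence",
    n_folds: int = 5,
    rng=None,
    passage_labels: Sequence | None = None,
) -> FoldSpec:
    """Partition sentences into near-equal test folds.

    ``by_sentence`` shuffles sentences uniformly; fold sizes are as equal as
    possible with the remainder assigned to the earliest folds.
    ``by_passage`` shuffles whole passages (``passage_labels`` required), so a
    passage's sentences never straddle folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if scheme == "by_sentence":
        if n_folds > n_sentences:
            raise ValueError("more folds than sentences")
        order = rng.permutation(n_sentences)
        sizes = [n_sentences // n_folds + (1 if i < n_sentences % n_folds else 0)
                 for i in range(n_folds)]
        test_sets, start = [], 0
        for sz in sizes:
            test_sets.append(np.sort(order[start : start + sz]))
            start += sz
    elif scheme == "by_passage":
        if passage_labels is None:
            raise ValueError("by_passage requires passage_labels")
        labels = list(passage_labels)
        groups: dict = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        keys = list(groups)
        if n_folds > len(keys):
            raise ValueError("more folds than passages")
        order = rng.permutation(len(keys))
        sizes = [len(keys) // n_folds + (1 if i < len(keys) % n_folds else 0)
                 for i in range(n_folds)]
        test_sets, start = [], 0
        for sz in sizes:
            idx = [j for k in order[start : start + sz] for j in groups[keys[k]]]
            test_sets.append(np.sort(np.asarray(idx, dtype=np.intp)))
            start += sz
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")
    return FoldSpec(scheme, n_folds, test_sets)


def fit_linear_map(features: np.ndarray, responses: np.ndarray) -> LinearRegression:
    """OLS mapping from features to (possibly multi-voxel) responses.

    Backed by an lstsq solver: when features outnumber samples the solution
    is the minimum-norm one.
    """
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(responses))):
        raise ValueError("non-finite inputs to linear mapping")
    model = LinearRegression()
    model.fit(features, responses)
    return model


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two equally shaped matrices.

    Columns with zero variance on either side get r = 0 (no linear
    association is demonstrable for a constant signal).
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def unshuffled_fraction(
    test_sets: Sequence[np.ndarray], group_labels: Sequence
) -> float:
    """Fraction of sentences that are sole members of their scope group
    within their test fold (hence cannot be moved by the derangement)."""
    labels = list(group_labels)
    n_total = 0
    n_single = 0
    for fold in test_sets:
        fold_labels = [labels[i] for i in fold]
        tallies = Counter(fold_labels)
        n_total += len(fold_labels)
        n_single += sum(1 for lab in fold_labels if tallies[lab] == 1)
    return n_single / n_total


def expected_unshuffled_fraction(group_size: int, n_sentences: int, fold_size: int) -> float:
    """Exact hypergeometric probability that a sentence in a test fold of
    ``fold_size`` has none of its ``group_size``-1 group mates in the fold."""
    p = 1.0
    for i in range(group_size - 1):
        p *= (n_sentences - fold_size - i) / (n_sentences - 1 - i)
    return p


@dataclass
class PredictivityResult:
    """Scores for one design x condition: array (layers, participants)."""

    design: str
    condition: str
    participants: list[str]
    scores: np.ndarray  # (L, P): per-participant median-over-voxel r, mean over folds
    unshuffled_fraction: float | None = None
    per_voxel: dict = field(default_factory=dict)  # (experiment, participant) -> (L, V)


def _stable_key(*parts) -> int:
    """Process-independent 31-bit key for seeding from heterogeneous parts."""
    return zlib.crc32("|".join(map(str, parts)).encode()) % (2**31)


def _design_fold_rng(seed: int | None, experiment_id: str, fold: int, scope: str):
    ss = np.random.SeedSequence(
        [0 if seed is None else int(seed)],
        spawn_key=(_stable_key(experiment_id, fold, scope),),
    )
    return np.random.default_rng(ss)


def run_design(
    design: Design | str,
    condition_name: str,
    embeddings_by_condition: Mapping[str, EmbeddingTensor],
    brain: Sequence[BrainData],
    stimulus_set: StimulusSet,
    n_folds: int = 5,
    seed: int | None = 0,
    keep_per_voxel: bool = False,
) -> PredictivityResult:
    """Score one condition under one cell of the 2x2 design.

    ``embeddings_by_condition`` must contain 'Original' and ``condition_name``
    tensors whose contextualization flag matches the design. Experiments are
    fitted separately (folds drawn independently per experiment, seeded from
    ``seed``) and participant scores averaged across the experiments a
    participant appears in.
    """
    if isinstance(design, str):
        design = Design.from_name(design)
    orig = embeddings_by_condition["Original"]
    cond = embeddings_by_condition[condition_name]
    for tensor in (orig, cond):
        if tensor.contextualized != design.contextualized:
            raise ValueError(
                f"embedding tensor for {tensor.condition_name!r} has "
                f"contextualized={tensor.contextualized}, design wants "
                f"{design.contextualized}"
            )
    if orig.num_sentences != len(stimulus_set):
        raise ValueError("embedding/stimulus sentence count mismatch")
    L = orig.num_layers
    shuffle_scope = (
        SUBSTITUTION_SCOPE.get(condition_name) if design.train_intact else None
    )

    per_participant: dict[str, list[np.ndarray]] = {}
    per_voxel_detail: dict = {}
    unshuffled: list[float] = []
    for bd in brain:
        exp_rows = np.asarray(stimulus_set.experiment_index[bd.experiment_id])
        if bd.n_sentences != len(exp_rows):
            raise ValueError(
                f"brain data for {bd.experiment_id} has {bd.n_sentences} sentences, "
                f"stimulus set has {len(exp_rows)}"
            )
        fold_rng = np.random.default_rng(
            np.random.SeedSequence(
                [0 if seed is None else int(seed)],
                spawn_key=(_stable_key("folds", bd.experiment_id),),
            )
        )
        folds = make_folds(len(exp_rows), "by_sentence", n_folds, fold_rng)

        X_orig = orig.layers[:, exp_rows, :]  # (L, S_exp, D)
        X_cond = cond.layers[:, exp_rows, :]
        X_train_src = X_orig if design.train_intact else X_cond

        # Test-set feature rows per fold. For substitution conditions under
        # TrainIntact, the Original features are deranged within the scope
        # group inside each test fold; otherwise the condition's own features
        # are used as-is.
        test_features: list[np.ndarray] = []
        if shuffle_scope is not None:
            group_labels = [
                stimulus_set.group_labels(shuffle_scope)[g] for g in exp_rows
            ]
            for f, test_idx in enumerate(folds.test_sets):
                rng = _design_fold_rng(seed, bd.experiment_id, f, shuffle_scope)
                local_labels = [group_labels[i] for i in test_idx]
                perm = scope_derangement(local_labels, rng)
                test_features.append(X_orig[:, test_idx[perm], :])
            unshuffled.append(
                unshuffled_fraction(folds.test_sets, group_labels)
            )
        else:
            for test_idx in folds.test_sets:
                test_features.append(X_cond[:, test_idx, :])

        train_sets = [
            np.setdiff1d(np.arange(len(exp_rows)), test_idx)
            for test_idx in folds.test_sets
        ]
        for pid, Y in bd.responses.items():
            voxel_scores = np.zeros((L, Y.shape[1]))
            for layer in range(L):
                for f, test_idx in enumerate(folds.test_sets):
                    train_idx = train_sets[f]
                    model = fit_linear_map(
                        X_train_src[layer, train_idx, :], Y[train_idx]
                    )
                    pred = model.predict(test_features[f][layer])
                    voxel_scores[layer] += pearson_columns(pred, Y[test_idx])
            voxel_scores /= n_folds
            if keep_per_voxel:
                per_voxel_detail[(bd.experiment_id, pid)] = voxel_scores
            per_participant.setdefault(pid, []).append(
                np.median(voxel_scores, axis=1)
            )

    participants = sorted(per_participant)
    scores = np.column_stack(
        [np.mean(per_participant[pid], axis=0) for pid in participants]
    )
    return PredictivityResult(
        design.name,
        condition_name,
        participants,
        scores,
        unshuffled_fraction=float(np.mean(unshuffled)) if unshuffled else None,
        per_voxel=per_voxel_detail,
    )


def select_layer(
    result: PredictivityResult,
    policy: str = "best_per_condition",
    reference: PredictivityResult | None = None,
) -> tuple[int, float]:
    """Pick a layer and return (layer index, median-over-participant score).

    ``best_per_condition`` takes the argmax over layers of the participant-
    median score for this condition; ``best_on_original`` fixes the layer
    chosen the same way on the supplied Original-condition ``reference``.
    Ties break toward the lowest layer index.
    """
    if policy == "best_per_condition":
        med = np.median(result.scores, axis=1)
        layer = int(np.argmax(med))
    elif policy == "best_on_original":
        if reference is None:
            raise ValueError("best_on_original requires a reference result")
        layer = int(np.argmax(np.median(reference.scores, axis=1)))
    else:
        raise ValueError(f"unknown layer policy {policy!r}")
    return layer, float(np.median(result.scores[layer]))
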
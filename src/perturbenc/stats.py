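"""Follow-up analyses and statistical tests.

Covers (i) representational similarity between intact and perturbed sentence
representations (per-sentence Spearman rank correlation over vector units,
averaged over sentences, per layer), (ii) correlating similarity or surprisal
differences with brain-predictivity differences across conditions, and
(iii) the paired dependent-samples t-tests with Bonferroni correction and the
centered median-absolute-deviation dispersion used for error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .embeddings import EmbeddingTensor


@dataclass
class SimilarityResult:
    """Mean Spearman rho between original and perturbed vectors, per layer."""

    condition: str
    rho: np.ndarray  # (L,)
    n_skipped: int = 0  # sentence pairs with undefined rho (constant vectors)


def representational_similarity(
    orig: EmbeddingTensor, pert: EmbeddingTensor
) -> SimilarityResult:
    """Per layer, average over sentences of Spearman rho between the
    original and perturbed representation vectors (over vector units).

    Pairs where either vector is constant (rho undefined) are skipped with a
    warning and counted in ``n_skipped``.
    """
    if orig.layers.shape != pert.layers.shape:
        raise ValueError("embedding tensors have mismatched shapes")
    L, S, _ = orig.layers.shape
    rho = np.zeros(L)
    skipped = 0
    for layer in range(L):
        vals = []
        for i in range(S):
            a, b = orig.layers[layer, i], pert.layers[layer, i]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                skipped += 1
                continue
            vals.append(sps.spearmanr(a, b).statistic)
        rho[layer] = float(np.mean(vals)) if vals else np.nan
    if skipped:
        warnings.warn(
            f"skipped {skipped} constant-vector pairs in representational similarity"
        )
    return SimilarityResult(pert.condition_name, rho, skipped)


def similarity_vs_predictivity(
    similarities: Mapping[str, np.ndarray],
    predictivities: Mapping[str, np.ndarray],
) -> tuple[float, dict[str, float]]:
    """Pearson r between similarity and predictivity over condition x layer.

    Both mappings give per-condition arrays of per-layer values on matching
    grids. Returns the pooled r over all points plus per-condition r values.
    """
    conditions = sorted(similarities)
    if sorted(predictivities) != conditions:
        raise ValueError("condition sets differ between similarity and predictivity")
    xs, ys = [], []
    per_condition = {}
    for c in conditions:
        sim = np.asarray(similarities[c], dtype=float)
        pred = np.asarray(predictivities[c], dtype=float)
        if sim.shape != pred.shape:
            raise ValueError(f"layer grids differ for condition {c}")
        xs.append(sim)
        ys.append(pred)
        if sim.size >= 3 and np.ptp(sim) > 0 and np.ptp(pred) > 0:
            per_condition[c] = float(sps.pearsonr(sim, pred).statistic)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.size < 3:
        raise ValueError("need at least 3 condition x layer points")
    return float(sps.pearsonr(x, y).statistic), per_condition


def surprisal_vs_predictivity(
    condition_surprisals: Mapping[str, float],
    condition_scores: Mapping[str, float],
    included_conditions: Sequence[str],
) -> float:
    """Pearson r over per-condition (surprisal increase, predictivity drop)
    pairs, both relative to the Original condition.

    A positive r means conditions that make strings more surprising also
    predict brain responses less well. Sentence-substitution conditions must
    be excluded by the caller (their pooled surprisal is identical to
    Original's by construction).
    """
    if "Original" not in condition_surprisals or "Original" not in condition_scores:
        raise ValueError("Original condition required as the reference")
    included = [c for c in included_conditions if c != "Original"]
    if len(included) < 3:
        raise ValueError("need at least 3 non-Original conditions")
    ds = np.array(
        [condition_surprisals[c] - condition_surprisals["Original"] for c in included]
    )
    dp = np.array(
        [condition_scores["Original"] - condition_scores[c] for c in included]
    )
    if np.ptp(ds) == 0 or np.ptp(dp) == 0:
        raise ValueError("degenerate deltas: correlation undefined")
    return float(sps.pearsonr(ds, dp).statistic)


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""


def paired_tests(
    per_participant_scores: Mapping[str, np.ndarray],
    comparisons: Sequence[tuple[str, str]],
    family: int | None = None,
) -> pd.DataFrame:
    """Two-sided dependent-samples t-tests with Bonferroni correction.

    ``per_participant_scores`` maps condition name -> per-participant score
    vector (aligned across conditions). ``family`` defaults to the number of
    comparisons. Zero-variance differences give t = NaN, p = NaN (reported,
    not imputed).
    """
    family = len(comparisons) if family is None else int(family)
    rows = []
    for a, b in comparisons:
        x = np.asarray(per_participant_scores[a], dtype=float)
        y = np.asarray(per_participant_scores[b], dtype=float)
        if x.shape != y.shape or x.size < 2:
            raise ValueError(f"paired samples misaligned for ({a}, {b})")
        d = x - y
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                t, p = 0.0, 1.0  # identical samples: no difference
            else:
                t, p = np.nan, np.nan  # constant nonzero difference: undefined
        else:
            res = sps.ttest_rel(x, y)
            t, p = float(res.statistic), float(res.pvalue)
        p_corr = min(1.0, p * family) if np.isfinite(p) else np.nan
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "t": t,
                "p": p,
                "p_bonferroni": p_corr,
                "family": family,
                "significance": _stars(p_corr) if np.isfinite(p_corr) else "",
            }
        )
    return pd.DataFrame(rows)


def design_comparison_tests(
    scores_by_design: Mapping[str, Mapping[str, np.ndarray]],
    comparisons: Sequence[tuple[str, str]],
    family: int | None = None,
) -> pd.DataFrame:
    """Paired t-tests between design cells on participant scores concatenated
    across a manipulation's conditions.

    Note: concatenating conditions treats each participant x condition entry
    as an independent pair (pseudo-replication); reported as in the source
    procedure, so interpret the p-values with care.
    """
    pooled = {
        design: np.concatenate(
            [np.asarray(conds[c], dtype=float) for c in sorted(conds)]
        )
        for design, conds in scores_by_design.items()
    }
    return paired_tests(pooled, comparisons, family)


def centered_mad(scores: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Within-participant centered m.a.d. per condition.

    ``scores`` is participants x conditions. Each participant's mean across
    conditions is subtracted; the per-condition dispersion is the median
    absolute deviation over participants of the centered values, scaled for
    normal consistency (divided by ~0.6745).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 participants")
    centered = arr - arr.mean(axis=1, keepdims=True)
    return sps.median_abs_deviation(centered, axis=0, scale="normal")
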
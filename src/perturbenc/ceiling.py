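"""Noise-ceiling estimation via brain-to-brain predictivity.

Measurement noise bounds how well *any* model can predict single-voxel
responses. The ceiling is estimated by predicting each "target" participant's
voxel responses from the pooled voxel responses of subsampled "predictor"
participants (using the same cross-validated OLS mapping as the encoding
pipeline), then extrapolating mean predictivity to an infinite predictor pool
with a saturating curve

    v(s) = v_inf * s / (s + tau),

whose asymptote v_inf is the reported ceiling. For participants that share a
common signal with independent additive noise of known relative variance, the
asymptote has the closed form sqrt(SNR / (SNR + 1)) — the attenuation of a
correlation by noise on one side only — which synthetic tests recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .encoding import BrainData, fit_linear_map, make_folds, pearson_columns


class ExtrapolationError(ValueError):
    """Fewer than two pool sizes: the saturating fit is underdetermined."""


@dataclass
class CeilingEstimate:
    """Subsampled brain-to-brain predictivities and the extrapolated asymptote."""

    pool_sizes: list[int]
    records: pd.DataFrame  # pool_size, subsample, target, score
    mean_scores: np.ndarray  # mean predictivity per pool size
    v_inf: float
    tau: float
    aggregation: str = "median_voxels_then_participants"

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _saturating(s, v_inf, tau):
    return v_inf * s / (s + tau)


def estimate_ceiling(
    brain: Sequence[BrainData],
    pool_sizes: Sequence[int],
    n_subsamples: int = 3,
    rng=None,
    n_folds: int = 5,
) -> CeilingEstimate:
    """Estimate the noise ceiling from participants sharing all stimuli.

    Only participants present in every experiment of ``brain`` are used
    (full stimulus overlap); at least 3 are required. For each target
    participant, pool size s, and subsample, s predictor participants are
    drawn without replacement, their voxels concatenated into the feature
    matrix, and the encoding module's cross-validated OLS mapping predicts
    each target voxel. The per-(target, subsample) score is the median over
    target voxels of mean-over-folds Pearson r, averaged across experiments;
    scores are aggregated per pool size as mean over subsamples then median
    over targets, and the saturating curve is fitted to the pool-size means.
    """
    pool_sizes = sorted(set(int(s) for s in pool_sizes))
    if len(pool_sizes) < 2:
        raise ExtrapolationError("need at least two pool sizes to extrapolate")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    shared = set(brain[0].participants)
    for bd in brain[1:]:
        shared &= set(bd.participants)
    participants = sorted(shared)
    if len(participants) < 3:
        raise ValueError("need >= 3 participants with identical stimulus coverage")
    if max(pool_sizes) > len(participants) - 1:
        raise ValueError("largest pool size exceeds available predictors")

    rows = []
    for target in participants:
        predictors_all = [p for p in participants if p != target]
        for s in pool_sizes:
            for sub in range(n_subsamples):
                chosen_idx = rng.choice(len(predictors_all), size=s, replace=False)
                chosen = [predictors_all[i] for i in sorted(chosen_idx)]
                exp_scores = []
                for bd in brain:
                    X = np.hstack([bd.responses[p] for p in chosen])
                    Y = bd.responses[target]
                    folds = make_folds(X.shape[0], "by_sentence", n_folds, rng)
                    voxel_r = np.zeros(Y.shape[1])
                    for test_idx in folds.test_sets:
                        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
                        model = fit_linear_map(X[train_idx], Y[train_idx])
                        voxel_r += pearson_columns(model.predict(X[test_idx]), Y[test_idx])
                    voxel_r /= folds.n_folds
                    exp_scores.append(float(np.median(voxel_r)))
                rows.append(
                    {
                        "pool_size": s,
                        "subsample": sub,
                        "target": target,
                        "score": float(np.mean(exp_scores)),
                    }
                )
    records = pd.DataFrame(rows)
    per_target = records.groupby(["pool_size", "target"])["score"].mean().reset_index()
    mean_scores = (
        per_target.groupby("pool_size")["score"].median().reindex(pool_sizes).to_numpy()
    )

    p0 = [min(1.0, max(mean_scores.max(), 1e-3)), 1.0]
    try:
        with warnings.catch_warnings():
            # an exact fit (e.g. noiseless data) makes the covariance singular
            warnings.simplefilter("ignore", OptimizeWarning)
            (v_inf, tau), _ = curve_fit(
                _saturating,
                np.asarray(pool_sizes, dtype=float),
                mean_scores,
                p0=p0,
                bounds=([0.0, 1e-6], [1.0, 100.0]),
                maxfev=10000,
            )
    except RuntimeError:
        v_inf, tau = float(mean_scores.max()), 1.0
    return CeilingEstimate(pool_sizes, records, mean_scores, float(v_inf), float(tau))


def analytic_attenuation_ceiling(snr: float) -> float:
    """Closed-form ceiling sqrt(SNR/(SNR+1)) for shared-signal participants."""
    return float(np.sqrt(snr / (snr + 1.0)))
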
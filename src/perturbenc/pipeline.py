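"""End-to-end orchestration: stimuli -> perturb -> embed -> encode -> stats.

A run is driven by a flat :class:`RunConfig` (loadable from YAML). Every
stochastic stage is seeded deterministically from the global seed via stable
per-stage keys, so a rerun with the same config produces byte-identical
result tables. Stage outputs are written under the output directory; with
``resume=True`` existing condition tables, embedding tensors, and result
tables are reused instead of recomputed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corpus import (
    LexiconTagger,
    StimulusSet,
    classify_tokens,
    read_stimulus_table,
    write_condition_table,
)
from .embeddings import EmbeddingTensor, embed_condition, mean_string_surprisal
from .encoding import Design, PredictivityResult, run_design, select_layer
from .perturb import (
    ALL_CONDITIONS,
    SEMANTIC_DISTANCE_CONDITIONS,
    PerturbedCondition,
    generate_condition,
)
from .pmi import NgramCounts
from .stats import (
    centered_mad,
    paired_tests,
    representational_similarity,
    similarity_vs_predictivity,
    surprisal_vs_predictivity,
)
from .synthetic import (
    MockBackend,
    SynthConfig,
    build_lexicon,
    generate_brain_data,
    generate_ngram_counts,
    generate_stimulus_set,
    small_experiments,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending item."""


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "perturbenc_run"
    seed: int = 0
    conditions: list[str] = field(
        default_factory=lambda: [
            "Original", "ReverseOrder", "KeepN", "KeepFunctionW",
            "RandWordList", "RandSent",
        ]
    )
    designs: list[str] = field(
        default_factory=lambda: ["TrainIntact-TestPerturbed_Contextualized"]
    )
    n_folds: int = 5
    summary_mode: str = "last_token"
    layer_policy: str = "best_per_condition"
    # stimulus source: "synthetic_full", "synthetic_small", or a TSV path
    stimuli: str = "synthetic_small"
    counts_path: str | None = None
    paraphrases_path: str | None = None
    background_sentences: int = 300
    # mock backend
    num_layers: int = 4
    dim: int = 64
    order_sensitivity: float = 0.0
    surprisal_coupling: float = 0.0
    # simulated brain
    participants: int = 5
    voxels: int = 20
    noise_sigma: float = 1.0
    readout: str = "content_bag"
    # ceiling
    run_ceiling: bool = False
    ceiling_pool_sizes: list[int] = field(default_factory=lambda: [1, 2, 3])
    ceiling_subsamples: int = 2
    resume: bool = False

    def validate(self):
        unknown = [c for c in self.conditions if c not in ALL_CONDITIONS]
        if unknown:
            raise PipelineError(f"config: unknown condition names {unknown}")
        from .encoding import DESIGN_NAMES

        bad = [d for d in self.designs if d not in DESIGN_NAMES]
        if bad:
            raise PipelineError(f"config: unknown designs {bad}")
        if "Original" not in self.conditions:
            self.conditions = ["Original"] + list(self.conditions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage_seed(seed: int, *parts) -> np.random.SeedSequence:
    key = zlib.crc32("|".join(map(str, parts)).encode()) % (2**31)
    return np.random.SeedSequence([int(seed)], spawn_key=(key,))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True)
    return f"{zlib.crc32(blob.encode()):08x}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the results bundle.

    Writes, under ``config.out_dir``: one TSV + JSON sidecar per condition,
    per-condition embedding tensors, ``results.csv`` (long format),
    ``stats.csv``, ``similarity.csv``, ``surprisal.csv``, optionally
    ``ceiling.csv``, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stimuli + classes ------------------------------------------------
    synth_config = None
    try:
        if config.stimuli == "synthetic_full":
            synth_config = SynthConfig()
            stim, classes = generate_stimulus_set(synth_config, seed=config.seed)
        elif config.stimuli == "synthetic_small":
            synth_config = SynthConfig(experiments=small_experiments(n_experiments=2))
            stim, classes = generate_stimulus_set(synth_config, seed=config.seed)
        else:
            stim = read_stimulus_table(config.stimuli)
            tagger = LexiconTagger(build_lexicon(SynthConfig()), default="NN")
            classes = [classify_tokens(s, tagger) for s in stim]
    except Exception as exc:
        raise PipelineError(f"stage 'stimuli' failed: {exc}") from exc

    # --- n-gram counts ----------------------------------------------------
    try:
        if config.counts_path:
            counts = NgramCounts.from_tsv(config.counts_path)
        else:
            counts = generate_ngram_counts(
                stim, config.background_sentences, seed=config.seed,
                config=synth_config,
            )
    except Exception as exc:
        raise PipelineError(f"stage 'counts' failed: {exc}") from exc

    paraphrases = None
    if config.paraphrases_path:
        paraphrases = (
            pd.read_csv(config.paraphrases_path, sep="\t", dtype=str)["text"].tolist()
        )

    # --- conditions -------------------------------------------------------
    conditions: dict[str, PerturbedCondition] = {}
    for name in config.conditions:
        path = out / f"condition_{name}.tsv"
        try:
            cond_seed = int(_stage_seed(config.seed, "condition", name).generate_state(1)[0])
            cond = generate_condition(
                name, stim,
                classes_per_sentence=classes,
                counts=counts,
                seed=cond_seed,
                paraphrases=paraphrases,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'perturb' failed on condition {name}: {exc}") from exc
        conditions[name] = cond
        if not (config.resume and path.exists()):
            write_condition_table(cond, stim, path)
            sidecar = {
                "condition": name, "seed": cond.seed, "k": cond.k,
                "metadata": {
                    k: v for k, v in cond.metadata.items()
                    if isinstance(v, (int, float, str))
                },
            }
            (out / f"condition_{name}.json").write_text(json.dumps(sidecar, indent=1))

    # --- embeddings -------------------------------------------------------
    backend = MockBackend.with_bigram_surprisal(
        [s.tokens for s in stim],
        num_layers=config.num_layers,
        dim=config.dim,
        order_sensitivity=config.order_sensitivity,
        surprisal_coupling=config.surprisal_coupling,
        seed=config.seed,
    )
    needed_ctx = sorted({Design.from_name(d).contextualized for d in config.designs})
    embeddings: dict[bool, dict[str, EmbeddingTensor]] = {}
    for ctx in needed_ctx:
        embeddings[ctx] = {}
        for name, cond in conditions.items():
            path = out / f"embeddings_{name}_{'ctx' if ctx else 'noctx'}.npz"
            if config.resume and path.exists():
                embeddings[ctx][name] = EmbeddingTensor.load(path)
                continue
            try:
                tensor = embed_condition(
                    backend, cond, stim, contextualized=ctx,
                    summary_mode=config.summary_mode,
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage 'embed' failed on condition {name}: {exc}"
                ) from exc
            tensor.save(path)
            embeddings[ctx][name] = tensor

    # --- simulated brain responses ---------------------------------------
    brain, ground_truth = generate_brain_data(
        stim,
        classes_per_sentence=classes,
        backend=backend,
        readout=config.readout,
        participants=config.participants,
        voxels=config.voxels,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )

    # --- encoding ---------------------------------------------------------
    results_path = out / "results.csv"
    results: dict[tuple[str, str], PredictivityResult] = {}
    rows = []
    for design_name in config.designs:
        design = Design.from_name(design_name)
        for name in config.conditions:
            try:
                res = run_design(
                    design, name, embeddings[design.contextualized], brain, stim,
                    n_folds=config.n_folds, seed=config.seed,
                )
            except Exception as exc:
                raise PipelineError(
                    f"stage 'encode' failed on {design_name}/{name}: {exc}"
                ) from exc
            results[(design_name, name)] = res
            for layer in range(res.scores.shape[0]):
                for p, pid in enumerate(res.participants):
                    rows.append(
                        {
                            "design": design_name,
                            "condition": name,
                            "layer": layer,
                            "participant": pid,
                            "score": res.scores[layer, p],
                            "unshuffled_fraction": res.unshuffled_fraction,
                        }
                    )
    results_df = pd.DataFrame(rows)
    if not (config.resume and results_path.exists()):
        results_df.to_csv(results_path, index=False, float_format="%.10g")

    # --- layer selection + stats -----------------------------------------
    stats_rows = []
    best_scores: dict[tuple[str, str], np.ndarray] = {}
    for design_name in config.designs:
        orig_res = results[(design_name, "Original")]
        for name in config.conditions:
            res = results[(design_name, name)]
            layer, _ = select_layer(
                res, config.layer_policy,
                reference=orig_res if config.layer_policy == "best_on_original" else None,
            )
            best_scores[(design_name, name)] = res.scores[layer]
        per_cond = {
            name: best_scores[(design_name, name)] for name in config.conditions
        }
        comparisons = [("Original", c) for c in config.conditions if c != "Original"]
        table = paired_tests(per_cond, comparisons)
        table.insert(0, "design", design_name)
        mad = centered_mad(np.column_stack([per_cond[c] for c in config.conditions]).T)
        mad_map = dict(zip(config.conditions, mad))
        table["mad_b"] = table["condition_b"].map(mad_map)
        stats_rows.append(table)
    stats_df = pd.concat(stats_rows, ignore_index=True)
    stats_df.to_csv(out / "stats.csv", index=False, float_format="%.10g")

    # --- representational similarity --------------------------------------
    sim_ctx = Design.from_name(config.designs[0]).contextualized
    sims = {}
    for name in config.conditions:
        if name == "Original":
            continue
        sims[name] = representational_similarity(
            embeddings[sim_ctx]["Original"], embeddings[sim_ctx][name]
        ).rho
    sim_df = pd.DataFrame(sims).T
    sim_df.index.name = "condition"
    sim_df.to_csv(out / "similarity.csv", float_format="%.10g")
    preds = {
        name: np.median(results[(config.designs[0], name)].scores, axis=1)
        for name in sims
    }
    sim_pred_r, _ = similarity_vs_predictivity(sims, preds) if len(sims) >= 1 else (np.nan, {})

    # --- surprisal --------------------------------------------------------
    surprisals = {}
    for name, cond in conditions.items():
        _, mean_surp = mean_string_surprisal(backend, cond, stim, contextualized=False)
        surprisals[name] = mean_surp
    surp_df = pd.DataFrame(
        {"condition": list(surprisals), "mean_surprisal_nats": list(surprisals.values())}
    )
    surp_df.to_csv(out / "surprisal.csv", index=False, float_format="%.10g")
    included = [
        c for c in config.conditions
        if c not in SEMANTIC_DISTANCE_CONDITIONS and c != "Original"
    ]
    cond_best = {
        c: float(np.median(best_scores[(config.designs[0], c)]))
        for c in config.conditions
    }
    try:
        surp_pred_r = surprisal_vs_predictivity(surprisals, cond_best, included)
    except ValueError:
        surp_pred_r = float("nan")

    # --- ceiling ----------------------------------------------------------
    ceiling_estimate = None
    if config.run_ceiling:
        from .ceiling import estimate_ceiling

        rng = np.random.default_rng(_stage_seed(config.seed, "ceiling"))
        ceiling_estimate = estimate_ceiling(
            brain, config.ceiling_pool_sizes, config.ceiling_subsamples, rng,
            n_folds=config.n_folds,
        )
        ceiling_estimate.to_csv(out / "ceiling.csv")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "n_sentences": len(stim),
        "similarity_vs_predictivity_r": sim_pred_r,
        "surprisal_vs_predictivity_r": surp_pred_r,
        "ceiling_v_inf": None if ceiling_estimate is None else ceiling_estimate.v_inf,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "stimulus_set": stim,
        "classes": classes,
        "conditions": conditions,
        "embeddings": embeddings,
        "brain": brain,
        "ground_truth": ground_truth,
        "results": results,
        "results_df": results_df,
        "stats": stats_df,
        "similarity": sims,
        "similarity_vs_predictivity_r": sim_pred_r,
        "surprisals": surprisals,
        "surprisal_vs_predictivity_r": surp_pred_r,
        "ceiling": ceiling_estimate,
    }
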
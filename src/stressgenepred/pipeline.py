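"""End-to-end orchestration: simulate/ingest -> embed -> train -> evaluate.

A run produces a directory with every stage artifact (weights, filter
parameters, gene rankings, per-sample predictions, metrics, log).  The
single top-level seed fans out to per-stage sub-seeds through stage-name
hashing, so stages are individually reproducible and do not share RNG
streams.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np

from . import io as sgp_io
from .datatypes import StressGeneLayer, TimeSeriesSample
from .discovery import StressGeneDiscovery
from .embedding import FoldChangeEmbedder
from .exceptions import ConfigError
from .prediction import StressTypeClassifier, evaluate_accuracy
from .simulate import (
    SyntheticConfig,
    SyntheticGroundTruth,
    generate_dataset,
    split_train_test,
)

logger = logging.getLogger("stressgenepred")

_SEED_MOD = 2**31


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the run seed."""
    return (int(seed) + zlib.crc32(stage.encode("utf-8"))) % _SEED_MOD


def planted_precision_at_k(
    rankings, truth: SyntheticGroundTruth, gene_vocabulary: list[str], k: int | None = None
) -> dict[str, float]:
    """Fraction of each stress's planted *specific* genes in its top-k ranks.

    ``k`` defaults to the number of planted specific genes per stress, so a
    perfect recovery scores 1.0.
    """
    out = {}
    for stress, ranked in rankings.items():
        planted = {gene_vocabulary[g] for g in truth.specific_genes(stress)}
        if not planted:
            continue
        kk = k if k is not None else len(planted)
        top = {r.gene for r in ranked[:kk]}
        out[stress] = len(top & planted) / len(planted)
    return out


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "run",
    samples: list[TimeSeriesSample] | None = None,
    gene_vocabulary: list[str] | None = None,
    truth: SyntheticGroundTruth | None = None,
    expression_path=None,
    metadata_path=None,
    synthetic: bool = False,
    synthetic_config: SyntheticConfig | None = None,
    n_test: int = 30,
    cmcl_variant: str = "printed",
) -> dict:
    """Execute the full twin-model pipeline and write all artifacts.

    Input is one of: an in-memory dataset (``samples`` + ``gene_vocabulary``),
    expression/metadata paths, or ``synthetic=True`` (with an optional
    :class:`SyntheticConfig`).  Returns the metrics dictionary that is also
    written to ``out_dir/metrics.tsv``.
    """
    cfg = dict(sgp_io.CONFIG_DEFAULTS)
    if config:
        cfg.update(config)
    n_test = int(cfg.get("n_test", n_test))
    cmcl_variant = cfg.get("cmcl_variant", cmcl_variant)
    seed = int(cfg["seed"])

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("run config: %s", {**cfg, "n_test": n_test,
                                       "cmcl_variant": cmcl_variant})

        # --- stage: input ---------------------------------------------------
        if synthetic:
            syn = synthetic_config or SyntheticConfig(
                seed=stage_seed(seed, "simulate")
            )
            logger.info("stage simulate: %d stresses, %d genes",
                        len(syn.stress_vocabulary), syn.n_genes)
            samples, truth = generate_dataset(syn)
            gene_vocabulary = [f"G{i:05d}" for i in range(syn.n_genes)]
            sgp_io.write_ground_truth(
                truth, list(syn.stress_vocabulary), gene_vocabulary,
                out / "ground_truth.tsv",
            )
        elif samples is None:
            if expression_path is None or metadata_path is None:
                raise ConfigError(
                    "provide samples, expression/metadata paths, or synthetic=True"
                )
            logger.info("stage ingest: %s", expression_path)
            samples, gene_vocabulary, _ = sgp_io.read_dataset(
                expression_path, metadata_path
            )
        if gene_vocabulary is None:
            gene_vocabulary = [f"G{i:05d}" for i in range(samples[0].n_genes)]

        # --- stage: embed ----------------------------------------------------
        embedder = FoldChangeEmbedder(threshold=float(cfg["fc_threshold"]))
        embedder.fit(samples)
        vocab = embedder.stress_vocabulary_
        logger.info("stage embed: %d samples, stress vocabulary %s",
                    len(samples), vocab)

        train_samples, test_samples = split_train_test(
            samples, n_test=n_test, seed=stage_seed(seed, "split")
        )
        X_train = embedder.transform(train_samples).astype(float)
        y_train = embedder.stress_labels(train_samples)
        X_test = embedder.transform(test_samples).astype(float)

        # --- stage: discovery ------------------------------------------------
        logger.info("stage discovery: alpha=%s, lr=%s, epochs=%s",
                    cfg["alpha"], cfg["learning_rate"], cfg["epochs_discovery"])
        disc = StressGeneDiscovery(
            alpha=float(cfg["alpha"]),
            learning_rate=float(cfg["learning_rate"]),
            epochs=int(cfg["epochs_discovery"]),
            random_state=stage_seed(seed, "discovery"),
            stress_vocabulary=vocab,
            gene_vocabulary=gene_vocabulary,
        ).fit(X_train, y_train)
        for e in range(0, len(disc.loss_trace_), 100):
            logger.info("discovery epoch %d: loss %.4f", e, disc.loss_trace_[e])
        sgp_io.write_weights(disc.layer_, out / "weights.tsv")

        top_k = min(int(cfg["top_k"]), len(gene_vocabulary))
        rankings = disc.rank_genes(top_k=top_k)
        sgp_io.write_rankings(rankings, out / "rankings.tsv")

        # --- stage: prediction -----------------------------------------------
        logger.info("stage prediction: beta=%s, epochs=%s, variant=%s",
                    cfg["beta"], cfg["epochs_prediction"], cmcl_variant)
        clf = StressTypeClassifier(
            layer=disc.layer_,
            beta=float(cfg["beta"]),
            epochs=int(cfg["epochs_prediction"]),
            cmcl_variant=cmcl_variant,
            random_state=stage_seed(seed, "prediction"),
        ).fit(X_train, y_train)
        sgp_io.write_params(clf.params_, vocab, out / "params.tsv")

        pred_rankings = clf.predict_ranking(X_test)
        predictions = [
            (s.sample_id, s.stress, r)
            for s, r in zip(test_samples, pred_rankings)
        ]
        sgp_io.write_predictions(predictions, out / "predictions.tsv")

        # --- stage: evaluate -------------------------------------------------
        top1 = [
            (r[0][0] if r else "unclassifiable") for r in pred_rankings
        ]
        accuracy = evaluate_accuracy(top1, [s.stress for s in test_samples])
        metrics = {
            "n_train": len(train_samples),
            "n_test": len(test_samples),
            "heldout_accuracy": round(accuracy, 6),
        }
        if truth is not None:
            prec = planted_precision_at_k(rankings, truth, gene_vocabulary)
            for stress, p in prec.items():
                metrics[f"precision_at_k_{stress}"] = round(p, 6)
            metrics["precision_at_k_mean"] = round(
                float(np.mean(list(prec.values()))), 6
            )
        logger.info("metrics: %s", metrics)
        with open(out / "metrics.tsv", "w") as fh:
            for key, value in metrics.items():
                fh.write(f"{key}\t{value}\n")
        return metrics
    finally:
        logger.removeHandler(handler)
        handler.close()
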
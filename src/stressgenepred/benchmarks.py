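"""Evaluation protocols for the twin model on synthetic corpora.

Each function measures one quantitative property of the implementation
against an oracle that is independent of the code path it checks: the
closed-form cross-entropy optimum (empirical feature frequencies), central
finite differences, or the generator's planted ground truth.  The test
suite asserts thresholds on these measurements; ``scripts/acceptance.py``
reports them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit

from .discovery import StressGeneDiscovery, _loss_and_grad, _suff_stats, rank_genes
from .embedding import FoldChangeEmbedder
from .pipeline import stage_seed
from .prediction import StressTypeClassifier, evaluate_accuracy
from .prediction import _cmcl_objective_and_grad
from .simulate import SyntheticConfig, generate_dataset, split_train_test

__all__ = [
    "frequency_oracle_error",
    "discovery_gradient_error",
    "cmcl_gradient_error",
    "planted_recovery_precision",
    "specificity_pressure",
    "repeated_split_accuracy",
    "noiseless_embedding_errors",
]


def frequency_oracle_error(
    seed: int = 0, n_per_stress: int = 20, n_genes: int = 10, epochs: int = 2000
) -> float:
    """Max |sigmoid(W) - empirical frequency| after training at alpha = 0.

    With one-hot labels and no group penalty the cross-entropy optimum is
    available in closed form: each weight's sigmoid equals the empirical
    frequency of its feature among that stress's samples.  Frequencies are
    planned on a non-saturating grid (0.15..0.85) over a 2-stress,
    ``n_genes``-per-stress instance.
    """
    rng = np.random.default_rng(seed)
    L, F = 2, 2 * n_genes
    freqs = np.linspace(0.15, 0.85, L * F).reshape(L, F)
    X = np.zeros((L * n_per_stress, F))
    labels = np.repeat(np.arange(L), n_per_stress)
    for l in range(L):
        rows = np.where(labels == l)[0]
        counts = np.round(freqs[l] * n_per_stress).astype(int)
        for j, c in enumerate(counts):
            X[rng.permutation(rows)[:c], j] = 1.0
    disc = StressGeneDiscovery(alpha=0.0, epochs=epochs, random_state=seed).fit(
        X, labels
    )
    empirical = np.stack([X[labels == l].mean(axis=0) for l in range(L)])
    return float(np.max(np.abs(expit(disc.W_) - empirical)))


def discovery_gradient_error(
    seed: int = 0, L: int = 2, n_genes: int = 5, alpha: float = 0.06
) -> float:
    """Max relative error of the analytic discovery gradient vs central FD."""
    rng = np.random.default_rng(seed)
    W = rng.normal(scale=0.5, size=(L, 2 * n_genes))
    X = (rng.random((8, 2 * n_genes)) < 0.4).astype(float)
    labels = rng.integers(0, L, size=8)
    n_l, C = _suff_stats(X, labels, L)
    _, grad = _loss_and_grad(W, n_l, C, alpha)
    h = 1e-5
    fd = np.zeros_like(W)
    for l in range(L):
        for j in range(2 * n_genes):
            Wp, Wm = W.copy(), W.copy()
            Wp[l, j] += h
            Wm[l, j] -= h
            fd[l, j] = (
                _loss_and_grad(Wp, n_l, C, alpha)[0]
                - _loss_and_grad(Wm, n_l, C, alpha)[0]
            ) / (2 * h)
    return float(np.max(np.abs(grad - fd) / np.maximum(np.abs(fd), 1.0)))


def cmcl_gradient_error(
    seed: int = 0, K: int = 7, L: int = 3, beta: float = 0.01,
    variant: str = "printed",
) -> float:
    """Max relative error of the CMCL gradient in (a, log b) vs central FD."""
    rng = np.random.default_rng(seed)
    anorm = rng.uniform(0.05, 0.45, size=(K, L))
    y = rng.integers(0, L, size=K)
    a = rng.normal(scale=0.5, size=L)
    log_b = rng.normal(scale=0.5, size=L)
    _, ga, glb = _cmcl_objective_and_grad(a, log_b, anorm, y, beta, variant)
    h = 1e-6
    worst = 0.0
    for which, (vec, grad) in enumerate(((a, ga), (log_b, glb))):
        fd = np.zeros(L)
        for l in range(L):
            vp, vm = vec.copy(), vec.copy()
            vp[l] += h
            vm[l] -= h
            args_p = (vp, log_b) if which == 0 else (a, vp)
            args_m = (vm, log_b) if which == 0 else (a, vm)
            fd[l] = (
                _cmcl_objective_and_grad(*args_p, anorm, y, beta, variant)[0]
                - _cmcl_objective_and_grad(*args_m, anorm, y, beta, variant)[0]
            ) / (2 * h)
        worst = max(worst, float(np.max(np.abs(grad - fd) / np.maximum(np.abs(fd), 1.0))))
    return worst


def _embed_corpus(config: SyntheticConfig):
    samples, truth = generate_dataset(config)
    embedder = FoldChangeEmbedder(
        stress_vocabulary=list(config.stress_vocabulary)
    ).fit(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        X = embedder.transform(samples).astype(float)
    y = embedder.stress_labels(samples)
    return samples, truth, embedder, X, y


def planted_recovery_precision(
    seed: int = 0,
    n_seeds: int = 5,
    config: SyntheticConfig | None = None,
    alpha: float = 0.06,
    epochs: int = 2000,
) -> dict[str, float]:
    """Per-stress precision@k of planted specific genes, averaged over seeds.

    Under the default study conditions (2000 genes, 4 stresses, 40 specific
    genes per stress, 3x signal, 10% noise) the discovery model should place
    nearly all planted specific genes in the top 40 ranks of their stress.
    Returns per-stress mean precision plus the overall ``"mean"``.
    """
    base = config or SyntheticConfig()
    vocab = list(base.stress_vocabulary)
    k = base.specific_genes_per_stress
    per_stress = {s: [] for s in vocab}
    for i in range(n_seeds):
        cfg = SyntheticConfig(**{**base.__dict__, "seed": (seed + i) % 2**31})
        _, truth, _, X, y = _embed_corpus(cfg)
        disc = StressGeneDiscovery(
            alpha=alpha, epochs=epochs, random_state=cfg.seed,
            stress_vocabulary=vocab,
        ).fit(X, y)
        rankings = disc.rank_genes(top_k=k)
        for stress in vocab:
            planted = {f"G{g:05d}" for g in truth.specific_genes(stress)}
            top = {r.gene for r in rankings[stress]}
            per_stress[stress].append(len(top & planted) / len(planted))
    out = {s: float(np.mean(v)) for s, v in per_stress.items()}
    out["mean"] = float(np.mean(list(out.values())))
    return out


def _median_shared_rank(layer, truth) -> float:
    """Median within-stress rank of planted two-stress genes."""
    full = rank_genes(layer, top_k=layer.n_genes)
    position = {
        stress: {r.gene: i + 1 for i, r in enumerate(ranked)}
        for stress, ranked in full.items()
    }
    ranks = []
    for gene, pair, _ in truth.shared:
        for stress in pair:
            ranks.append(position[stress][f"G{gene:05d}"])
    return float(np.median(ranks))


def specificity_pressure(
    seed: int = 0,
    n_replicates: int = 10,
    config: SyntheticConfig | None = None,
    alpha: float = 0.06,
    epochs: int = 2000,
) -> float:
    """Fraction of replicates where two-stress genes rank worse with the penalty.

    Trains the discovery model twice per replicate — with the group penalty
    (``alpha``) and without (0) — and compares the median within-stress rank
    of the planted shared genes.  The penalty should demote them, so the
    fraction of replicates with a strictly worse (larger) median rank at
    ``alpha`` is the reported statistic.
    """
    base = config or SyntheticConfig()
    vocab = list(base.stress_vocabulary)
    worse = 0
    for i in range(n_replicates):
        cfg = SyntheticConfig(**{**base.__dict__, "seed": (seed + i) % 2**31})
        _, truth, _, X, y = _embed_corpus(cfg)
        medians = {}
        for a in (alpha, 0.0):
            disc = StressGeneDiscovery(
                alpha=a, epochs=epochs, random_state=cfg.seed,
                stress_vocabulary=vocab,
            ).fit(X, y)
            medians[a] = _median_shared_rank(disc.layer_, truth)
        if medians[alpha] > medians[0.0]:
            worse += 1
    return worse / n_replicates


def repeated_split_accuracy(
    seed: int = 0,
    n_splits: int = 20,
    config: SyntheticConfig | None = None,
    n_test: int = 30,
    alpha: float = 0.06,
    epochs_discovery: int = 2000,
    epochs_prediction: int = 500,
    cmcl_variant: str = "printed",
) -> dict[str, float]:
    """Mean held-out top-1 accuracy over repeated random train/test splits.

    Mirrors the repeated-split evaluation protocol: the corpus (default 138
    samples) is split randomly ``n_splits`` times into train/test
    (default 108/30); the full twin model is retrained on each training set
    and scored on its test set.  Degenerate test samples count as wrong.
    """
    cfg = config or SyntheticConfig(seed=stage_seed(seed, "corpus"))
    samples, _, embedder, X, y = _embed_corpus(cfg)
    vocab = embedder.stress_vocabulary_
    accuracies = []
    for i in range(n_splits):
        split_seed = stage_seed(seed + i, "split")
        rng = np.random.default_rng(split_seed)
        order = rng.permutation(len(samples))
        test_idx, train_idx = order[:n_test], order[n_test:]
        disc = StressGeneDiscovery(
            alpha=alpha, epochs=epochs_discovery, random_state=split_seed,
            stress_vocabulary=vocab,
        ).fit(X[train_idx], y[train_idx])
        clf = StressTypeClassifier(
            layer=disc.layer_, epochs=epochs_prediction,
            cmcl_variant=cmcl_variant, random_state=split_seed,
        ).fit(X[train_idx], y[train_idx])
        predicted = list(clf.predict(X[test_idx]))
        true = [vocab[l] for l in y[test_idx]]
        accuracies.append(evaluate_accuracy(predicted, true))
    return {
        "mean": float(np.mean(accuracies)),
        "min": float(np.min(accuracies)),
        "max": float(np.max(accuracies)),
    }


def noiseless_embedding_errors(
    seed: int = 0, config: SyntheticConfig | None = None
) -> int:
    """Count of embedded bits that disagree with the planted truth at zero noise.

    In the noiseless limit the realised fold change of a planted gene equals
    the configured signal exactly and every other gene is flat, so the
    embedding must recover the planted (gene, direction) bits exactly.
    Returns the total number of mismatched bits (0 = exact recovery).
    """
    base = config or SyntheticConfig()
    cfg = SyntheticConfig(**{**base.__dict__, "noise_cv": 0.0, "seed": seed % 2**31})
    samples, truth = generate_dataset(cfg)
    embedder = FoldChangeEmbedder(
        stress_vocabulary=list(cfg.stress_vocabulary)
    ).fit(samples)
    mismatches = 0
    for sample in samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            x = embedder.transform([sample])[0]
        expected = np.zeros_like(x)
        for gene, direction in truth.responders_for(sample.stress):
            expected[2 * gene + (1 if direction == "up" else 0)] = 1
        mismatches += int(np.sum(x != expected))
    return mismatches
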
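"""Seeded generator of heterogeneous multi-stress time-series datasets.

The generator emulates the statistical shape of a real multi-stress
transcriptome corpus: four unbalanced stress groups (49 cold, 43 heat,
33 salt, 13 drought samples by default), per-sample time grids of 2-8
points with two-point series making up 65% of samples, at least two
replicates per time point, and log-normal baseline intensities.

Ground truth is *planted*: a disjoint set of single-stress-specific genes
per stress plus a pool of shared genes responding to two stresses.  A
planted gene's expression at every post-baseline time point is multiplied
(up) or divided (down) by ``fold_change_signal``; multiplicative log-normal
noise with a given coefficient of variation is then applied per replicate.
With ``noise_cv = 0`` the realised fold change equals the planted signal
exactly, so the embedding recovers the truth bit-for-bit — the noiseless
limit is the generator's own oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import DEFAULT_STRESSES, TimeSeriesSample
from .exceptions import ConfigError

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_ground_truth",
    "simulate_sample",
    "generate_dataset",
    "split_train_test",
    "default_gene_vocabulary",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the real corpus the generator emulates: 138 samples in
    the 49/43/33/13 stress proportions, 65% two-time-point series, two
    replicates, and a 3x planted fold change against log-normal baselines
    (median intensity 100, log-sd 1) with 10% multiplicative noise.
    """

    n_genes: int = 2000
    stress_vocabulary: tuple[str, ...] = DEFAULT_STRESSES
    samples_per_stress: tuple[int, ...] = (49, 43, 33, 13)
    specific_genes_per_stress: int = 40
    shared_gene_pairs: int = 10
    fold_change_signal: float = 3.0
    time_point_range: tuple[int, int] = (2, 8)
    two_timepoint_prob: float = 0.65
    replicates: int = 2
    noise_cv: float = 0.1
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        L = len(self.stress_vocabulary)
        if len(self.samples_per_stress) != L:
            raise ConfigError("samples_per_stress must match the stress vocabulary")
        if min(self.samples_per_stress) < 1 or self.n_genes < 1:
            raise ConfigError("sample and gene counts must be positive")
        needed = self.specific_genes_per_stress * L + 2 * self.shared_gene_pairs
        if needed > self.n_genes:
            raise ConfigError(
                f"planted genes ({needed}) exceed n_genes ({self.n_genes})"
            )
        lo, hi = self.time_point_range
        if not 2 <= lo <= hi:
            raise ConfigError("time_point_range must satisfy 2 <= lo <= hi")
        if self.fold_change_signal <= 1:
            raise ConfigError("fold_change_signal must exceed 1")
        if self.replicates < 1 or self.noise_cv < 0:
            raise ConfigError("replicates must be >= 1 and noise_cv >= 0")
        if not 0 <= self.two_timepoint_prob <= 1:
            raise ConfigError("two_timepoint_prob must be a probability")


@dataclass
class SyntheticGroundTruth:
    """Planted gene -> stress -> direction assignments.

    ``specific`` maps each stress to its single-stress genes; ``shared``
    lists (gene, (stress_a, stress_b), (dir_a, dir_b)) triples for genes
    responding to two stresses.
    """

    specific: dict[str, list[tuple[int, str]]]
    shared: list[tuple[int, tuple[str, str], tuple[str, str]]] = field(
        default_factory=list
    )

    def responders_for(self, stress: str) -> list[tuple[int, str]]:
        """All (gene, direction) pairs planted for ``stress``."""
        out = list(self.specific.get(stress, []))
        for gene, pair, dirs in self.shared:
            if stress in pair:
                out.append((gene, dirs[pair.index(stress)]))
        return out

    def specific_genes(self, stress: str) -> list[int]:
        return [g for g, _ in self.specific.get(stress, [])]

    def shared_genes(self, stress: str) -> list[int]:
        return [g for g, pair, _ in self.shared if stress in pair]


def generate_ground_truth(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticGroundTruth:
    """Draw disjoint planted assignments (seeded via ``config.seed``)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vocab = config.stress_vocabulary
    L = len(vocab)
    perm = rng.permutation(config.n_genes)
    k = config.specific_genes_per_stress
    specific = {
        vocab[l]: [
            (int(g), "up" if rng.random() < 0.5 else "down")
            for g in perm[l * k : (l + 1) * k]
        ]
        for l in range(L)
    }
    # shared pool: 2 * shared_gene_pairs genes, each tied to a stress pair
    shared = []
    pool = perm[L * k : L * k + 2 * config.shared_gene_pairs]
    for gene in pool:
        pair_idx = sorted(rng.choice(L, size=2, replace=False).tolist())
        pair = (vocab[pair_idx[0]], vocab[pair_idx[1]])
        dirs = tuple("up" if rng.random() < 0.5 else "down" for _ in range(2))
        shared.append((int(gene), pair, dirs))
    return SyntheticGroundTruth(specific=specific, shared=shared)


def simulate_sample(
    stress: str,
    truth: SyntheticGroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str,
) -> TimeSeriesSample:
    """Simulate one time-series sample under ``stress``."""
    if stress not in config.stress_vocabulary:
        raise ConfigError(f"unknown stress {stress!r}")
    lo, hi = config.time_point_range
    if lo == hi:
        T = lo
    elif rng.random() < config.two_timepoint_prob:
        T = lo
    else:
        T = int(rng.integers(max(lo + 1, 3), hi + 1))
    time_points = np.concatenate(
        [[0.0], np.sort(rng.uniform(1.0, 48.0, size=T - 1))]
    )
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes
    )
    values = np.repeat(
        baseline[:, None, None], T, axis=1
    ).repeat(config.replicates, axis=2)
    for gene, direction in truth.responders_for(stress):
        factor = (
            config.fold_change_signal
            if direction == "up"
            else 1.0 / config.fold_change_signal
        )
        values[gene, 1:, :] *= factor
    if config.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
        noise = rng.lognormal(
            -0.5 * sigma**2, sigma, size=values.shape
        )
        values = values * noise
    return TimeSeriesSample(
        sample_id=sample_id, stress=stress, values=values, time_points=time_points
    )


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[TimeSeriesSample], SyntheticGroundTruth]:
    """Full corpus: ``samples_per_stress[l]`` samples per stress, seeded."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = generate_ground_truth(config, rng)
    samples = []
    for stress, count in zip(config.stress_vocabulary, config.samples_per_stress):
        for i in range(count):
            samples.append(
                simulate_sample(
                    stress, truth, config, rng, sample_id=f"{stress}_{i:03d}"
                )
            )
    return samples, truth


def split_train_test(
    samples: list[TimeSeriesSample], n_test: int = 30, seed: int = 0
) -> tuple[list[TimeSeriesSample], list[TimeSeriesSample]]:
    """Random (unstratified) train/test split, e.g. 108/30 of a 138-sample corpus."""
    if not 0 < n_test < len(samples):
        raise ConfigError(
            f"n_test must be in (0, {len(samples)}), got {n_test}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    test_idx = set(order[:n_test].tolist())
    train = [s for i, s in enumerate(samples) if i not in test_idx]
    test = [s for i, s in enumerate(samples) if i in test_idx]
    return train, test


def default_gene_vocabulary(n_genes: int) -> list[str]:
    """Zero-padded synthetic gene names, lexicographically ordered."""
    return [f"G{i:05d}" for i in range(n_genes)]


def with_noise_cv(config: SyntheticConfig, noise_cv: float) -> SyntheticConfig:
    """Copy of ``config`` at a different noise level (e.g. the noiseless limit)."""
    return replace(config, noise_cv=noise_cv)
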
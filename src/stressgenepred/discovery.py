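"""Submodel 1: biomarker gene discovery.

The discovery model reconstructs each sample's observed binary regulation
vector from its stress label alone, through a single shared linear layer W
(one row per stress, one down and one up column per gene) followed by a
sigmoid:

    x_hat_k = sigmoid(y_k @ W)

Training minimises the summed binary cross-entropy between observed and
reconstructed vectors plus a *group penalty* that pushes each gene to
associate with a single stress.  For gene n the per-stress score is

    g[n, l] = max(sigmoid(W[l, 2n]), sigmoid(W[l, 2n + 1]))

and the penalty is ``alpha * sum_n (sum_l g[n, l])**2``: a gene fully
specific to one stress contributes 1 (unscaled), while a gene responding to
m stresses contributes ~m**2, so multi-stress responders are demoted
quadratically.  Genes are ranked per stress by g, which is also the score
reported alongside the dominant regulation direction.

Because y is one-hot and the loss decomposes per weight, the cross-entropy
optimum at alpha=0 is available in closed form — sigmoid(W[l, j]) equals the
empirical frequency of feature j among stress-l samples — which the test
suite uses as an independent oracle for the trainer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .datatypes import EmbeddedSample, StressGeneLayer
from .exceptions import DataError, TrainingError

_LOG_EPS = 1e-12


@dataclass
class RankedGene:
    """One row of a per-stress gene ranking."""

    gene: str
    direction: str  # "up" or "down"
    score: float


def predict_biomarker_vector(y: np.ndarray, layer: StressGeneLayer) -> np.ndarray:
    """Reconstructed regulation probabilities ``sigmoid(y @ W)`` for one label."""
    y = np.asarray(y, dtype=float)
    if y.shape != (layer.n_stresses,):
        raise DataError(
            f"label vector has shape {y.shape}, expected ({layer.n_stresses},)"
        )
    return expit(y @ layer.W)


def reconstruction_loss(
    x_batch: np.ndarray, y_batch: np.ndarray, layer: StressGeneLayer
) -> float:
    """Summed binary cross-entropy between observed and reconstructed vectors."""
    X = np.atleast_2d(np.asarray(x_batch, dtype=float))
    Y = np.atleast_2d(np.asarray(y_batch, dtype=float))
    if X.shape[0] != Y.shape[0] or X.shape[0] == 0:
        raise DataError("x and y batches must be non-empty and equally long")
    if Y.shape[1] != layer.n_stresses or X.shape[1] != 2 * layer.n_genes:
        raise DataError("batch width does not match the layer")
    P = np.clip(expit(Y @ layer.W), _LOG_EPS, 1.0 - _LOG_EPS)
    return float(-(X * np.log(P) + (1.0 - X) * np.log1p(-P)).sum())


def gene_stress_scores(layer: StressGeneLayer | np.ndarray) -> np.ndarray:
    """Per-gene per-stress association scores in (0, 1).

    Returns an ``(n_genes, n_stresses)`` matrix: the larger of the sigmoid-
    transformed down and up weights of each gene under each stress.
    """
    W = layer.W if isinstance(layer, StressGeneLayer) else np.asarray(layer, float)
    S = expit(W)
    return np.maximum(S[:, 0::2], S[:, 1::2]).T


def group_penalty(scores: np.ndarray, alpha: float) -> float:
    """``alpha * sum_n (sum_l g[n, l])**2`` over the (n_genes, L) score matrix."""
    if alpha < 0:
        raise DataError("alpha must be non-negative")
    g = np.atleast_2d(np.asarray(scores, dtype=float))
    return float(alpha * (g.sum(axis=1) ** 2).sum())


def _suff_stats(X: np.ndarray, labels: np.ndarray, n_stresses: int):
    """Per-stress sample counts and per-feature set-bit counts."""
    n_l = np.bincount(labels, minlength=n_stresses).astype(float)
    C = np.zeros((n_stresses, X.shape[1]))
    for l in range(n_stresses):
        C[l] = X[labels == l].sum(axis=0)
    return n_l, C


def _loss_and_grad(
    W: np.ndarray, n_l: np.ndarray, C: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Total loss (cross-entropy + group penalty) and its gradient in W.

    Uses the one-hot structure: the cross-entropy separates per weight with
    sufficient statistics (n_l, C), so the gradient is
    ``n_l * sigmoid(W) - C`` row-wise.  The penalty routes its gradient to
    whichever direction weight attains the per-gene max (ties go to up, the
    same convention the direction report uses).
    """
    P = expit(W)
    Pc = np.clip(P, _LOG_EPS, 1.0 - _LOG_EPS)
    loss_ce = -(C * np.log(Pc) + (n_l[:, None] - C) * np.log1p(-Pc)).sum()
    grad = n_l[:, None] * P - C

    Sd, Su = P[:, 0::2], P[:, 1::2]
    up_wins = Su >= Sd
    g = np.where(up_wins, Su, Sd)          # (L, N)
    rowsum = g.sum(axis=0)                 # per gene, over stresses
    loss_gp = alpha * (rowsum**2).sum()
    dg = 2.0 * alpha * rowsum[None, :]     # dLoss/dg[l, n]
    dS = dg * g * (1.0 - g)                # chain through sigmoid at the max
    grad[:, 0::2] += np.where(up_wins, 0.0, dS)
    grad[:, 1::2] += np.where(up_wins, dS, 0.0)
    return float(loss_ce + loss_gp), grad


class StressGeneDiscovery(BaseEstimator):
    """Learn the shared stress-gene layer and rank stress-specific genes.

    Fit on a binary feature matrix ``X`` of shape (n_samples, 2 * n_genes)
    and integer stress labels ``y`` by full-batch gradient descent on the
    reconstruction cross-entropy plus the group penalty.

    Parameters
    ----------
    alpha : float, default=0.06
        Group-penalty weight.  0 disables the single-stress pressure; large
        values force every gene onto at most one stress.
    learning_rate : float, default=0.1
        Gradient-descent step size.
    epochs : int, default=2000
        Full-batch gradient steps.
    init_scale : float, default=0.01
        Weights start uniform in [-init_scale, init_scale] so every
        reconstruction probability begins near 0.5.
    random_state : int, default=0
        Seed for the weight initialisation.
    stress_vocabulary, gene_vocabulary : sequences of str, optional
        Names attached to the fitted layer; defaults are generated.

    Attributes
    ----------
    layer_ : StressGeneLayer
        The fitted shared layer.
    W_ : ndarray of shape (L, 2 * n_genes)
        Alias of ``layer_.W``.
    loss_trace_ : ndarray of shape (epochs + 1,)
        Total training loss before each step and after the last.
    """

    def __init__(
        self,
        alpha: float = 0.06,
        learning_rate: float = 0.1,
        epochs: int = 2000,
        init_scale: float = 0.01,
        random_state: int = 0,
        stress_vocabulary: list[str] | None = None,
        gene_vocabulary: list[str] | None = None,
    ):
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.init_scale = init_scale
        self.random_state = random_state
        self.stress_vocabulary = stress_vocabulary
        self.gene_vocabulary = gene_vocabulary

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StressGeneDiscovery":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        labels = np.asarray(y)
        if labels.dtype.kind not in "iu":
            raise DataError("y must be integer stress indices")
        if X.shape[0] == 0:
            raise DataError("cannot fit on an empty batch")
        if X.shape[0] != labels.shape[0]:
            raise DataError("X and y have different lengths")
        if X.shape[1] % 2:
            raise DataError("X must have an even number of columns (down/up pairs)")
        if self.alpha < 0 or self.learning_rate <= 0 or self.epochs < 1:
            raise DataError("invalid training configuration")

        n_genes = X.shape[1] // 2
        if self.stress_vocabulary is not None:
            vocab = list(self.stress_vocabulary)
        else:
            vocab = [f"stress{l}" for l in range(int(labels.max()) + 1)]
        L = len(vocab)
        if labels.min() < 0 or labels.max() >= L:
            raise DataError("stress index out of vocabulary range")
        genes = (
            list(self.gene_vocabulary)
            if self.gene_vocabulary is not None
            else [f"G{i:05d}" for i in range(n_genes)]
        )
        if len(genes) != n_genes:
            raise DataError("gene vocabulary length does not match X")

        missing = [vocab[l] for l in range(L) if not np.any(labels == l)]
        if missing:
            warnings.warn(
                f"no training samples for stresses {missing}; their rows "
                "will only be shaped by the group penalty",
                UserWarning,
                stacklevel=2,
            )

        n_l, C = _suff_stats(X, labels, L)
        rng = np.random.default_rng(self.random_state)
        W = rng.uniform(-self.init_scale, self.init_scale, size=(L, 2 * n_genes))

        trace = np.empty(self.epochs + 1)
        for epoch in range(self.epochs):
            loss, grad = _loss_and_grad(W, n_l, C, self.alpha)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite discovery loss at epoch {epoch} "
                    f"(lr={self.learning_rate}, alpha={self.alpha})"
                )
            trace[epoch] = loss
            W -= self.learning_rate * grad
        trace[-1], _ = _loss_and_grad(W, n_l, C, self.alpha)

        self.layer_ = StressGeneLayer(
            W=W, stress_vocabulary=vocab, gene_vocabulary=genes
        )
        self.W_ = self.layer_.W
        self.loss_trace_ = trace
        return self

    def fit_embedded(self, batch: list[EmbeddedSample]) -> "StressGeneDiscovery":
        """Fit from a list of :class:`EmbeddedSample` (convenience)."""
        if not batch:
            raise DataError("cannot fit on an empty batch")
        X = np.stack([e.x for e in batch]).astype(float)
        y = np.array([e.stress_index for e in batch], dtype=int)
        return self.fit(X, y)

    def gene_scores(self) -> np.ndarray:
        """(n_genes, L) association scores of the fitted layer."""
        return gene_stress_scores(self.layer_)

    def rank_genes(self, top_k: int = 500) -> dict[str, list[RankedGene]]:
        """Top-k genes per stress; see :func:`rank_genes`."""
        return rank_genes(self.layer_, top_k)


def rank_genes(
    layer: StressGeneLayer, top_k: int = 500
) -> dict[str, list[RankedGene]]:
    """Per-stress ranking of genes by their association score.

    Genes are sorted by ``g[n, l]`` descending, ties broken by vocabulary
    index ascending.  The reported direction is *up* when the up weight is
    at least the down weight, else *down*.
    """
    N = layer.n_genes
    if not 1 <= top_k <= N:
        raise DataError(f"top_k must be in [1, {N}], got {top_k}")
    g = gene_stress_scores(layer)          # (N, L)
    S = expit(layer.W)
    up_wins = S[:, 1::2] >= S[:, 0::2]     # (L, N)
    rankings: dict[str, list[RankedGene]] = {}
    for l, stress in enumerate(layer.stress_vocabulary):
        order = np.lexsort((np.arange(N), -g[:, l]))[:top_k]
        rankings[stress] = [
            RankedGene(
                gene=layer.gene_vocabulary[n],
                direction="up" if up_wins[l, n] else "down",
                score=float(g[n, l]),
            )
            for n in order
        ]
    return rankings


def train_discovery(
    batch: list[EmbeddedSample],
    alpha: float = 0.06,
    learning_rate: float = 0.1,
    epochs: int = 2000,
    init_scale: float = 0.01,
    seed: int = 0,
    stress_vocabulary: list[str] | None = None,
    gene_vocabulary: list[str] | None = None,
) -> StressGeneLayer:
    """Functional wrapper: fit :class:`StressGeneDiscovery`, return the layer."""
    est = StressGeneDiscovery(
        alpha=alpha,
        learning_rate=learning_rate,
        epochs=epochs,
        init_scale=init_scale,
        random_state=seed,
        stress_vocabulary=stress_vocabulary,
        gene_vocabulary=gene_vocabulary,
    )
    return est.fit_embedded(batch).layer_
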
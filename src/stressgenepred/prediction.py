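"""Submodel 2: stress type prediction with the transposed shared layer.

The classifier reuses the discovery layer W *frozen and transposed*: a
sample's binary regulation vector x produces per-stress activations

    A = sigmoid(x @ W.T)

which are normalised by the sample's number of set bits (samples differ
wildly in how many genes they regulate, so the activation is put on a
per-regulated-gene scale):

    A_norm = A / sum(x)

Stresses are ranked by A_norm descending — the top-1 stress is the
classification.  A parametric logistic filter

    g_l(v) = 1 / (1 + b_l * exp(v - a_l))

squashes A_norm inside the Confident Multiple Choice Learning (CMCL)
training objective, which combines a squared error on the true stress's
score with a beta-weighted log term over the wrong stresses.  As written,
the filter is *decreasing* in A_norm, so it is kept strictly inside the
loss pathway: ranking by the filter output would invert the evidence order
(see docs/methods.md).  Two CMCL variants are provided: the "printed" form
penalises -log(score) on wrong labels; the "complemented" form uses
-log(1 - score), which is the reading consistent with driving wrong-label
scores down.

The fitted (a, b) therefore calibrate per-stress probabilities without
affecting the argmax decision, which depends on (x, W) alone.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .datatypes import EmbeddedSample, PredictionParams, StressGeneLayer
from .exceptions import DataError, DegenerateSampleError, TrainingError

_LOG_EPS = 1e-12

#: Label reported for samples with no set bits (no regulated genes).
UNCLASSIFIABLE = "unclassifiable"

CMCL_VARIANTS = ("printed", "complemented")


def stress_activation(x: np.ndarray, layer: StressGeneLayer) -> np.ndarray:
    """Per-stress activations ``sigmoid(x @ W.T)`` for one sample."""
    x = np.asarray(x, dtype=float)
    if x.shape != (2 * layer.n_genes,):
        raise DataError(
            f"feature vector has shape {x.shape}, expected ({2 * layer.n_genes},)"
        )
    return expit(layer.W @ x)


def normalize_activation(A: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Activation divided by the sample's count of set feature bits."""
    x = np.asarray(x, dtype=float)
    n_set = x.sum()
    if n_set <= 0:
        raise DegenerateSampleError(
            "sample has no regulated genes; it cannot be normalised or classified"
        )
    return np.asarray(A, dtype=float) / n_set


def logistic_filter(
    a_norm: np.ndarray, params: PredictionParams
) -> np.ndarray:
    """Entrywise ``1 / (1 + b_l * exp(v_l - a_l))``; outputs in (0, 1)."""
    v = np.asarray(a_norm, dtype=float)
    return 1.0 / (1.0 + params.b * np.exp(v - params.a))


def cmcl_loss(
    y_labels: np.ndarray,
    scores: np.ndarray,
    beta: float = 0.01,
    variant: str = "printed",
) -> float:
    """Confident Multiple Choice Learning loss over a batch of score vectors.

    Per sample: ``(1 - s[y])**2`` on the true label's score, plus
    ``-beta * sum_{l != y} log(s[l])`` ("printed") or
    ``-beta * sum_{l != y} log(1 - s[l])`` ("complemented").
    Scores are clamped to [1e-12, 1 - 1e-12] before the logs.
    """
    if variant not in CMCL_VARIANTS:
        raise DataError(f"unknown CMCL variant {variant!r}")
    S = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.atleast_1d(np.asarray(y_labels, dtype=int))
    if S.shape[0] != y.shape[0]:
        raise DataError("labels and score batch have different lengths")
    K, L = S.shape
    Sc = np.clip(S, _LOG_EPS, 1.0 - _LOG_EPS)
    true_scores = S[np.arange(K), y]
    sq = ((1.0 - true_scores) ** 2).sum()
    wrong = np.ones_like(S, dtype=bool)
    wrong[np.arange(K), y] = False
    logs = np.log(Sc) if variant == "printed" else np.log1p(-Sc)
    total = sq - beta * logs[wrong].sum()
    if not np.isfinite(total):
        raise TrainingError("non-finite CMCL loss")
    return float(total)


def _cmcl_objective_and_grad(
    a: np.ndarray,
    log_b: np.ndarray,
    anorm: np.ndarray,
    y: np.ndarray,
    beta: float,
    variant: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """CMCL loss of the *filter outputs* and its gradient in (a, log b).

    With u = a - log b - A_norm the filter output is G = sigmoid(u), so
    dG/da = G(1-G) and dG/d(log b) = -G(1-G).
    """
    u = a[None, :] - log_b[None, :] - anorm
    G = expit(u)
    K, L = G.shape
    idx = np.arange(K)
    Gc = np.clip(G, _LOG_EPS, 1.0 - _LOG_EPS)

    true_g = G[idx, y]
    wrong = np.ones_like(G, dtype=bool)
    wrong[idx, y] = False

    logs = np.log(Gc) if variant == "printed" else np.log1p(-Gc)
    loss = ((1.0 - true_g) ** 2).sum() - beta * logs[wrong].sum()

    dG = np.zeros_like(G)
    dG[idx, y] = -2.0 * (1.0 - true_g)
    if variant == "printed":
        dG[wrong] += -beta / Gc[wrong]
    else:
        dG[wrong] += beta / (1.0 - Gc[wrong])
    dU = dG * G * (1.0 - G)
    return float(loss), dU.sum(axis=0), -dU.sum(axis=0)


class StressTypeClassifier(ClassifierMixin, BaseEstimator):
    """Classify samples into stress types through the frozen shared layer.

    Parameters
    ----------
    layer : StressGeneLayer
        The fitted discovery layer; frozen during classifier training.
    beta : float, default=0.01
        CMCL wrong-label weight (~1 / number of training samples).
    learning_rate : float, default=0.05
        Step size for the (a, log b) gradient descent.
    epochs : int, default=500
        Full-batch gradient steps for the filter parameters.
    cmcl_variant : {"printed", "complemented"}, default="printed"
        Wrong-label term of the CMCL loss.
    random_state : int, default=0
        Kept for interface symmetry; filter training is deterministic
        (a starts at 0, b at 1).

    Attributes
    ----------
    a_, b_ : ndarray of shape (L,)
        Fitted logistic-filter parameters (b > 0, optimised as log b).
    params_ : PredictionParams
    loss_trace_ : ndarray
        CMCL objective before each step and after the last.
    classes_ : ndarray of str
        The layer's stress vocabulary.
    """

    def __init__(
        self,
        layer: StressGeneLayer | None = None,
        beta: float = 0.01,
        learning_rate: float = 0.05,
        epochs: int = 500,
        cmcl_variant: str = "printed",
        random_state: int = 0,
    ):
        self.layer = layer
        self.beta = beta
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.cmcl_variant = cmcl_variant
        self.random_state = random_state

    def _check_layer(self) -> StressGeneLayer:
        if self.layer is None:
            raise DataError("StressTypeClassifier requires a fitted layer")
        return self.layer

    def _anorm_matrix(self, X: np.ndarray) -> np.ndarray:
        """(K, L) normalised activations; NaN rows for degenerate samples."""
        layer = self._check_layer()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != 2 * layer.n_genes:
            raise DataError(
                f"X has {X.shape[1]} columns, expected {2 * layer.n_genes}"
            )
        A = expit(X @ layer.W.T)
        n_set = X.sum(axis=1)
        out = np.full_like(A, np.nan)
        ok = n_set > 0
        out[ok] = A[ok] / n_set[ok, None]
        return out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StressTypeClassifier":
        layer = self._check_layer()
        if self.cmcl_variant not in CMCL_VARIANTS:
            raise DataError(f"unknown CMCL variant {self.cmcl_variant!r}")
        L = layer.n_stresses
        labels = np.asarray(y)
        if labels.dtype.kind not in "iu":
            labels = np.array(
                [layer.stress_vocabulary.index(s) for s in labels], dtype=int
            )
        anorm = self._anorm_matrix(X)
        ok = ~np.isnan(anorm[:, 0])
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} sample(s) with no regulated "
                "genes from filter training",
                UserWarning,
                stacklevel=2,
            )
        if not ok.any():
            raise TrainingError("all training samples are degenerate")
        anorm, labels = anorm[ok], labels[ok]

        a = np.zeros(L)
        log_b = np.zeros(L)  # b starts at 1
        trace = np.empty(self.epochs + 1)
        for epoch in range(self.epochs):
            loss, ga, glb = _cmcl_objective_and_grad(
                a, log_b, anorm, labels, self.beta, self.cmcl_variant
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite CMCL loss at epoch {epoch}")
            trace[epoch] = loss
            a -= self.learning_rate * ga
            log_b -= self.learning_rate * glb
        trace[-1] = _cmcl_objective_and_grad(
            a, log_b, anorm, labels, self.beta, self.cmcl_variant
        )[0]

        self.a_ = a
        self.b_ = np.exp(log_b)
        self.params_ = PredictionParams(a=a, b=self.b_)
        self.loss_trace_ = trace
        self.classes_ = np.asarray(layer.stress_vocabulary)
        return self

    def _logits(self, X: np.ndarray) -> np.ndarray:
        """Pre-sigmoid activations ``X @ W.T``, the stable ordering key.

        The sigmoid is strictly monotone and the per-sample normaliser is
        shared by all stresses, so sorting by the logits is equivalent to
        sorting by A_norm while immune to sigmoid underflow on samples with
        many set bits and strongly negative weights.
        """
        layer = self._check_layer()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ layer.W.T

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Normalised activations A_norm (NaN rows = degenerate samples)."""
        return self._anorm_matrix(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Top-1 stress per sample; degenerate samples get 'unclassifiable'."""
        layer = self._check_layer()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._logits(X)
        degenerate = X.sum(axis=1) <= 0
        out = np.empty(Z.shape[0], dtype=object)
        for k in range(Z.shape[0]):
            if degenerate[k]:
                out[k] = UNCLASSIFIABLE
            else:
                out[k] = layer.stress_vocabulary[int(np.argmax(Z[k]))]
        return out

    def predict_ranking(
        self, X: np.ndarray
    ) -> list[list[tuple[str, float]] | None]:
        """Full stress ranking per sample (None for degenerate samples).

        Stresses are sorted by A_norm descending (equivalently by the
        underlying logits, which are used as the numerically stable sort
        key); ties break by vocabulary order, so the output is
        deterministic.  Reported scores are the A_norm entries.
        """
        layer = self._check_layer()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._logits(X)
        anorm = self._anorm_matrix(X)
        L = layer.n_stresses
        rankings: list[list[tuple[str, float]] | None] = []
        for z_row, a_row in zip(Z, anorm):
            if np.isnan(a_row[0]):
                rankings.append(None)
                continue
            order = np.lexsort((np.arange(L), -z_row))
            rankings.append(
                [(layer.stress_vocabulary[l], float(a_row[l])) for l in order]
            )
        return rankings


def train_prediction(
    batch: list[EmbeddedSample],
    layer: StressGeneLayer,
    beta: float = 0.01,
    learning_rate: float = 0.05,
    epochs: int = 500,
    cmcl_variant: str = "printed",
    seed: int = 0,
) -> PredictionParams:
    """Functional wrapper: fit the logistic filter, return its parameters."""
    if not batch:
        raise DataError("cannot fit on an empty batch")
    X = np.stack([e.x for e in batch]).astype(float)
    y = np.array([e.stress_index for e in batch], dtype=int)
    clf = StressTypeClassifier(
        layer=layer,
        beta=beta,
        learning_rate=learning_rate,
        epochs=epochs,
        cmcl_variant=cmcl_variant,
        random_state=seed,
    )
    return clf.fit(X, y).params_


def predict_stress(
    x: np.ndarray,
    layer: StressGeneLayer,
    params: PredictionParams | None = None,
) -> list[tuple[str, float]]:
    """Ranked (stress, score) list for one sample, scored by A_norm.

    The ranking depends on (x, W) alone; ``params`` is accepted for
    interface completeness but does not alter the order (the filter is
    order-reversing and excluded from the decision rule).
    """
    A = stress_activation(x, layer)
    anorm = normalize_activation(A, x)
    z = layer.W @ np.asarray(x, dtype=float)  # stable ordering key
    L = layer.n_stresses
    order = np.lexsort((np.arange(L), -z))
    return [(layer.stress_vocabulary[l], float(anorm[l])) for l in order]


def evaluate_accuracy(predicted: list[str], true: list[str]) -> float:
    """Fraction of samples whose top-1 predicted stress equals the label."""
    if len(predicted) != len(true) or not true:
        raise DataError("prediction and truth must be non-empty, equal-length")
    return float(
        np.mean([p == t for p, t in zip(predicted, true)])
    )
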
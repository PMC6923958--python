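"""Core in-memory containers shared by all stages.

A dataset is a list of :class:`TimeSeriesSample` objects over one shared,
ordered gene vocabulary.  Samples are heterogeneous: each has its own time
grid (``time_points``) and replicate count; only the gene axis is shared.

The feature embedding turns each sample into an :class:`EmbeddedSample`
holding the length-``2N`` binary regulation vector ``x`` (for gene ``i``,
index ``2i`` is the *down* bit and ``2i+1`` the *up* bit) and the one-hot
stress vector ``y`` over the ordered stress vocabulary.

Both submodels share one :class:`StressGeneLayer`: an ``L x 2N`` real weight
matrix whose rows are stresses and whose columns follow the same
down/up interleaving as ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError

#: Canonical stress vocabulary, ordered by corpus sample count
#: (cold > heat > salt > drought).
DEFAULT_STRESSES: tuple[str, ...] = ("cold", "heat", "salt", "drought")


@dataclass
class TimeSeriesSample:
    """One sample's expression values on a ``gene x time x replicate`` grid.

    Parameters
    ----------
    sample_id : str
        Unique sample identifier.
    stress : str
        Stress label (must be in the dataset's stress vocabulary).
    values : ndarray of shape (n_genes, n_times, n_replicates)
        Non-negative expression values.  Missing replicates are NaN; every
        ``(gene, time)`` cell must have at least one non-NaN value.
    time_points : ndarray of shape (n_times,)
        Strictly ascending measurement times.
    """

    sample_id: str
    stress: str
    values: np.ndarray
    time_points: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(
                f"sample {self.sample_id!r}: values must be 3-d "
                f"(gene x time x replicate), got shape {self.values.shape}"
            )
        if self.time_points is None:
            self.time_points = np.arange(self.values.shape[1], dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.time_points.shape != (self.values.shape[1],):
            raise DataError(
                f"sample {self.sample_id!r}: time_points length "
                f"{self.time_points.shape} does not match values"
            )
        if self.values.shape[1] and np.any(np.diff(self.time_points) <= 0):
            raise DataError(
                f"sample {self.sample_id!r}: time points must be strictly ascending"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        """Check the value-level invariants (finiteness, coverage)."""
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise DataError(f"sample {self.sample_id!r}: negative expression value")
        if self.values.size and not finite.any(axis=2).all():
            raise DataError(
                f"sample {self.sample_id!r}: some (gene, time) cell has no replicate"
            )


@dataclass
class EmbeddedSample:
    """Binary regulation vector ``x`` (length 2N) with one-hot stress ``y``."""

    sample_id: str
    x: np.ndarray
    y: np.ndarray

    @property
    def stress_index(self) -> int:
        return int(np.argmax(self.y))

    @property
    def n_set_bits(self) -> int:
        return int(self.x.sum())


@dataclass
class StressGeneLayer:
    """The shared logical stress-gene correlation layer.

    ``W`` has one row per stress and two columns per gene: column ``2i`` is
    gene ``i``'s down-regulation weight, column ``2i+1`` its up-regulation
    weight.  The same matrix reconstructs regulation vectors from stress
    labels (submodel 1, ``sigmoid(y @ W)``) and, transposed, scores stresses
    from regulation vectors (submodel 2, ``sigmoid(x @ W.T)``).
    """

    W: np.ndarray
    stress_vocabulary: list[str]
    gene_vocabulary: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        L, twoN = self.W.shape
        if L != len(self.stress_vocabulary):
            raise DataError(
                f"W has {L} rows but {len(self.stress_vocabulary)} stresses"
            )
        if twoN != 2 * len(self.gene_vocabulary):
            raise DataError(
                f"W has {twoN} columns but {len(self.gene_vocabulary)} genes "
                "(expected 2 per gene)"
            )
        if not np.isfinite(self.W).all():
            raise DataError("W contains non-finite entries")

    @property
    def n_stresses(self) -> int:
        return self.W.shape[0]

    @property
    def n_genes(self) -> int:
        return self.W.shape[1] // 2


@dataclass
class PredictionParams:
    """Per-stress logistic-filter parameters (a, b), with b > 0."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise DataError("a and b must have the same length")
        if np.any(self.b <= 0):
            raise DataError("filter parameter b must be strictly positive")
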
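"""Discovery submodel: reconstruction, group penalty, training, ranking."""

import numpy as np
import pytest
from scipy.special import expit

from stressgenepred import (
    StressGeneDiscovery,
    StressGeneLayer,
    gene_stress_scores,
    group_penalty,
    predict_biomarker_vector,
    rank_genes,
    reconstruction_loss,
)
from stressgenepred.discovery import _loss_and_grad, _suff_stats
from stressgenepred.exceptions import DataError


def layer_of(W, n_stresses=None):
    W = np.atleast_2d(np.asarray(W, dtype=float))
    L, twoN = W.shape
    return StressGeneLayer(
        W=W,
        stress_vocabulary=[f"s{l}" for l in range(L)],
        gene_vocabulary=[f"g{i}" for i in range(twoN // 2)],
    )


class TestPredictBiomarkerVector:
    def test_zero_weights_give_half(self):
        out = predict_biomarker_vector(np.array([1.0, 0.0]), layer_of(np.zeros((2, 4))))
        np.testing.assert_allclose(out, 0.5)

    def test_scalar_sigmoid_values(self):
        out = predict_biomarker_vector(np.array([1.0]), layer_of([[2.0, -2.0]]))
        np.testing.assert_allclose(out, [0.880797, 0.119203], atol=1e-6)

    def test_one_hot_selects_a_single_row(self):
        W = np.vstack([np.arange(4), 100 * np.ones(4)])
        out = predict_biomarker_vector(np.array([1.0, 0.0]), layer_of(W))
        np.testing.assert_allclose(out, expit(np.arange(4.0)))

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            predict_biomarker_vector(np.array([1.0, 0.0, 0.0]), layer_of(np.zeros((2, 4))))


class TestReconstructionLoss:
    def test_uninformative_prediction_is_log2_per_bit(self):
        loss = reconstruction_loss(
            np.array([[1.0, 0.0]]), np.array([[1.0]]), layer_of([[0.0, 0.0]])
        )
        assert loss == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_perfect_reconstruction_is_near_zero(self):
        loss = reconstruction_loss(
            np.array([[1.0, 0.0]]), np.array([[1.0]]), layer_of([[40.0, -40.0]])
        )
        assert 0 <= loss < 1e-6

    def test_additive_over_duplicated_samples(self):
        X = np.array([[1.0, 0.0, 1.0, 1.0]])
        Y = np.array([[0.0, 1.0]])
        layer = layer_of(np.array([[0.3, -0.2, 1.0, 0.5], [0.1, 2.0, -1.0, 0.7]]))
        one = reconstruction_loss(X, Y, layer)
        two = reconstruction_loss(np.vstack([X, X]), np.vstack([Y, Y]), layer)
        assert two == pytest.approx(2 * one)


class TestGeneStressScores:
    def test_zero_weights_give_half(self):
        np.testing.assert_allclose(gene_stress_scores(np.zeros((2, 6))), 0.5)

    def test_max_of_sigmoid_direction_weights(self):
        g = gene_stress_scores(np.array([[2.0, -1.0]]))
        assert g.shape == (1, 1)
        assert g[0, 0] == pytest.approx(0.880797, abs=1e-6)

    def test_monotone_in_each_direction_weight(self):
        base = gene_stress_scores(np.array([[0.5, 1.0]]))[0, 0]
        assert gene_stress_scores(np.array([[0.5, 1.5]]))[0, 0] >= base
        assert gene_stress_scores(np.array([[2.0, 1.0]]))[0, 0] >= base


class TestGroupPenalty:
    def test_single_stress_gene_contributes_one(self):
        assert group_penalty(np.array([[1.0, 0.0, 0.0, 0.0]]), alpha=1.0) == 1.0

    def test_zero_scores(self):
        assert group_penalty(np.zeros((3, 4)), alpha=0.06) == 0.0

    def test_two_stress_gene_quadratic(self):
        val = group_penalty(np.array([[1.0, 1.0, 0.0, 0.0]]), alpha=0.06)
        assert val == pytest.approx(0.24)

    def test_negative_alpha_rejected(self):
        with pytest.raises(DataError):
            group_penalty(np.ones((1, 2)), alpha=-1.0)


class TestGradient:
    def test_analytic_matches_central_finite_differences(self):
        rng = np.random.default_rng(42)
        L, N = 2, 5
        W = rng.normal(scale=0.5, size=(L, 2 * N))
        X = (rng.random((8, 2 * N)) < 0.4).astype(float)
        labels = rng.integers(0, L, size=8)
        n_l, C = _suff_stats(X, labels, L)
        alpha = 0.06
        _, grad = _loss_and_grad(W, n_l, C, alpha)
        h = 1e-5
        fd = np.zeros_like(W)
        for l in range(L):
            for j in range(2 * N):
                Wp, Wm = W.copy(), W.copy()
                Wp[l, j] += h
                Wm[l, j] -= h
                fd[l, j] = (
                    _loss_and_grad(Wp, n_l, C, alpha)[0]
                    - _loss_and_grad(Wm, n_l, C, alpha)[0]
                ) / (2 * h)
        scale = np.maximum(np.abs(fd), 1.0)
        assert np.max(np.abs(grad - fd) / scale) < 1e-4


class TestTraining:
    @staticmethod
    def _frequency_instance(seed=0):
        """2 stresses x 10 genes with planned non-saturating frequencies."""
        rng = np.random.default_rng(seed)
        n_per = 20
        freqs = np.linspace(0.15, 0.85, 40).reshape(2, 20)
        X = np.zeros((2 * n_per, 40))
        labels = np.repeat([0, 1], n_per)
        for l in range(2):
            counts = np.round(freqs[l] * n_per).astype(int)
            for j, c in enumerate(counts):
                rows = np.where(labels == l)[0]
                X[rng.permutation(rows)[:c], l * 20 + j] = 1.0
        return X, labels, freqs, n_per

    def test_frequency_oracle_at_alpha_zero(self):
        X, labels, freqs, n_per = self._frequency_instance()
        disc = StressGeneDiscovery(alpha=0.0, epochs=2000).fit(X, labels)
        probs = expit(disc.W_)
        emp0 = X[labels == 0].mean(axis=0)
        emp1 = X[labels == 1].mean(axis=0)
        assert np.max(np.abs(probs[0] - emp0)) < 0.02
        assert np.max(np.abs(probs[1] - emp1)) < 0.02

    def test_never_and_always_set_features_saturate(self):
        X = np.zeros((30, 4))
        X[:, 1] = 1.0  # always set
        labels = np.zeros(30, dtype=int)
        disc = StressGeneDiscovery(
            alpha=0.0, epochs=2000, stress_vocabulary=["cold"]
        ).fit(X, labels)
        probs = expit(disc.W_[0])
        assert probs[1] > 0.9
        assert probs[0] < 0.1

    def test_loss_trace_non_increasing(self):
        X, labels, _, _ = self._frequency_instance()
        disc = StressGeneDiscovery(alpha=0.06, epochs=500).fit(X, labels)
        diffs = np.diff(disc.loss_trace_)
        assert np.all(diffs <= 1e-8)

    def test_deterministic_given_seed(self):
        X, labels, _, _ = self._frequency_instance()
        W1 = StressGeneDiscovery(epochs=50, random_state=3).fit(X, labels).W_
        W2 = StressGeneDiscovery(epochs=50, random_state=3).fit(X, labels).W_
        np.testing.assert_array_equal(W1, W2)

    def test_missing_stress_warns(self):
        X = np.ones((4, 2))
        labels = np.zeros(4, dtype=int)
        with pytest.warns(UserWarning, match="no training samples"):
            StressGeneDiscovery(
                epochs=10, stress_vocabulary=["cold", "heat"]
            ).fit(X, labels)

    def test_empty_batch_rejected(self):
        with pytest.raises(DataError):
            StressGeneDiscovery().fit(np.zeros((0, 4)), np.zeros(0, dtype=int))


class TestRankGenes:
    def test_sorted_by_score_with_direction(self):
        # gene 0: strong up for s0; gene 1: weak down
        layer = layer_of([[-1.0, 3.0, 0.5, -2.0]])
        ranked = rank_genes(layer, top_k=2)["s0"]
        assert [r.gene for r in ranked] == ["g0", "g1"]
        assert ranked[0].direction == "up"
        assert ranked[1].direction == "down"
        assert ranked[0].score == pytest.approx(expit(3.0))

    def test_ties_break_by_vocabulary_order(self):
        layer = layer_of([[0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        ranked = rank_genes(layer, top_k=3)["s0"]
        assert [r.gene for r in ranked] == ["g0", "g1", "g2"]

    def test_top_k_equals_n_returns_all(self):
        layer = layer_of(np.zeros((2, 8)))
        assert len(rank_genes(layer, top_k=4)["s1"]) == 4

    def test_top_k_out_of_range(self):
        with pytest.raises(DataError):
            rank_genes(layer_of(np.zeros((1, 4))), top_k=3)
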
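"""Prediction submodel: activations, normalisation, filter, CMCL, classifier."""

import numpy as np
import pytest

from stressgenepred import (
    PredictionParams,
    StressGeneLayer,
    StressTypeClassifier,
    UNCLASSIFIABLE,
    cmcl_loss,
    evaluate_accuracy,
    logistic_filter,
    normalize_activation,
    predict_stress,
    stress_activation,
    train_prediction,
)
from stressgenepred import EmbeddedSample
from stressgenepred.exceptions import (
    DataError,
    DegenerateSampleError,
    TrainingError,
)
from stressgenepred.prediction import _cmcl_objective_and_grad


def layer_of(W, stresses=None):
    W = np.atleast_2d(np.asarray(W, dtype=float))
    L, twoN = W.shape
    return StressGeneLayer(
        W=W,
        stress_vocabulary=stresses or [f"s{l}" for l in range(L)],
        gene_vocabulary=[f"g{i}" for i in range(twoN // 2)],
    )


class TestStressActivation:
    def test_zero_weights_give_half(self):
        A = stress_activation(np.array([1.0, 0.0, 1.0, 0.0]), layer_of(np.zeros((3, 4))))
        np.testing.assert_allclose(A, 0.5)

    def test_scalar_sigmoid_value(self):
        A = stress_activation(
            np.array([1.0, 1.0, 0.0, 0.0]), layer_of([[1.0, 1.0, 0.0, 0.0]])
        )
        assert A[0] == pytest.approx(0.880797, abs=1e-6)

    def test_zero_weight_bit_is_inert(self):
        layer = layer_of([[1.0, 0.5, 0.0, 0.7]])
        x1 = np.array([1.0, 0.0, 0.0, 0.0])
        x2 = np.array([1.0, 0.0, 1.0, 0.0])  # flips a zero-weight bit
        np.testing.assert_allclose(
            stress_activation(x1, layer), stress_activation(x2, layer)
        )


class TestNormalizeActivation:
    def test_divides_by_set_bit_count(self):
        out = normalize_activation(
            np.array([0.8, 0.4]), np.array([1, 1, 1, 1, 0, 0])
        )
        np.testing.assert_allclose(out, [0.2, 0.1])

    def test_single_bit_is_identity(self):
        np.testing.assert_allclose(
            normalize_activation(np.array([0.7]), np.array([0, 1])), [0.7]
        )

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateSampleError):
            normalize_activation(np.array([0.5]), np.zeros(4))


class TestLogisticFilter:
    @pytest.mark.parametrize(
        "a, b, v, expected",
        [
            (0.0, 1.0, 0.0, 0.5),
            (0.5, 1.0, 0.5, 0.5),
            (0.0, 1.0, 1.0, 1.0 / (1.0 + np.e)),
        ],
    )
    def test_printed_formula(self, a, b, v, expected):
        params = PredictionParams(a=np.array([a]), b=np.array([b]))
        out = logistic_filter(np.array([v]), params)
        assert out[0] == pytest.approx(expected, abs=1e-6)

    def test_decreasing_in_input(self):
        params = PredictionParams(a=np.zeros(1), b=np.ones(1))
        lo = logistic_filter(np.array([0.1]), params)[0]
        hi = logistic_filter(np.array([0.9]), params)[0]
        assert hi < lo

    def test_nonpositive_b_rejected(self):
        with pytest.raises(DataError):
            PredictionParams(a=np.zeros(1), b=np.zeros(1))


class TestCmclLoss:
    def test_printed_variant_hand_value(self):
        loss = cmcl_loss([0], np.array([[0.9, 0.1]]), beta=0.01, variant="printed")
        assert loss == pytest.approx(0.01 - 0.01 * np.log(0.1), abs=1e-6)

    def test_complemented_variant_hand_value(self):
        loss = cmcl_loss(
            [0], np.array([[0.9, 0.1]]), beta=0.01, variant="complemented"
        )
        assert loss == pytest.approx(0.01 - 0.01 * np.log(0.9), abs=1e-6)

    def test_confident_prediction_zero_loss_printed(self):
        loss = cmcl_loss([1], np.array([[1.0, 1.0]]), beta=0.01, variant="printed")
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_unknown_variant(self):
        with pytest.raises(DataError):
            cmcl_loss([0], np.array([[0.5, 0.5]]), variant="softmax")


class TestCmclGradient:
    @pytest.mark.parametrize("variant", ["printed", "complemented"])
    def test_analytic_matches_finite_differences(self, variant):
        rng = np.random.default_rng(11)
        K, L = 7, 3
        anorm = rng.uniform(0.05, 0.45, size=(K, L))
        y = rng.integers(0, L, size=K)
        a = rng.normal(scale=0.5, size=L)
        log_b = rng.normal(scale=0.5, size=L)
        _, ga, glb = _cmcl_objective_and_grad(a, log_b, anorm, y, 0.01, variant)
        h = 1e-6

        def f(a_, lb_):
            return _cmcl_objective_and_grad(a_, lb_, anorm, y, 0.01, variant)[0]

        for vec, grad in ((a, ga), (log_b, glb)):
            fd = np.zeros(L)
            for l in range(L):
                vp, vm = vec.copy(), vec.copy()
                vp[l] += h
                vm[l] -= h
                if vec is a:
                    fd[l] = (f(vp, log_b) - f(vm, log_b)) / (2 * h)
                else:
                    fd[l] = (f(a, vp) - f(a, vm)) / (2 * h)
            scale = np.maximum(np.abs(fd), 1.0)
            assert np.max(np.abs(grad - fd) / scale) < 1e-4


class TestClassifier:
    @staticmethod
    def _toy_model():
        # stress s0 keys on gene 0 up, s1 on gene 1 down
        W = np.array([[-2.0, 4.0, -2.0, -2.0], [-2.0, -2.0, 4.0, -2.0]])
        layer = layer_of(W)
        X = np.array(
            [[0, 1, 0, 0], [0, 1, 0, 1], [0, 0, 1, 0], [1, 0, 1, 0]],
            dtype=float,
        )
        y = np.array([0, 0, 1, 1])
        return layer, X, y

    def test_initial_filter_output_contract(self):
        # a=0, b=1 before training: filter(0) = 0.5
        params = PredictionParams(a=np.zeros(2), b=np.ones(2))
        np.testing.assert_allclose(logistic_filter(np.zeros(2), params), 0.5)

    def test_fit_predict_recovers_labels(self):
        layer, X, y = self._toy_model()
        clf = StressTypeClassifier(layer=layer, epochs=200).fit(X, y)
        assert list(clf.predict(X)) == ["s0", "s0", "s1", "s1"]
        assert np.all(clf.b_ > 0)

    def test_same_seed_identical_params(self):
        layer, X, y = self._toy_model()
        c1 = StressTypeClassifier(layer=layer, epochs=100).fit(X, y)
        c2 = StressTypeClassifier(layer=layer, epochs=100).fit(X, y)
        np.testing.assert_array_equal(c1.a_, c2.a_)
        np.testing.assert_array_equal(c1.b_, c2.b_)

    def test_degenerate_sample_marked_unclassifiable(self):
        layer, X, y = self._toy_model()
        clf = StressTypeClassifier(layer=layer, epochs=10).fit(X, y)
        Xd = np.vstack([X[0], np.zeros(4)])
        assert clf.predict(Xd)[1] == UNCLASSIFIABLE
        assert clf.predict_ranking(Xd)[1] is None

    def test_all_degenerate_training_fails(self):
        layer, _, _ = self._toy_model()
        with pytest.raises(TrainingError):
            StressTypeClassifier(layer=layer, epochs=10).fit(
                np.zeros((3, 4)), np.array([0, 1, 0])
            )

    def test_monotone_in_feature_weight(self):
        # raising the weight of a set bit never lowers that stress's score
        layer, X, _ = self._toy_model()
        base = StressTypeClassifier(layer=layer).decision_function(X)[:, 0]
        W2 = layer.W.copy()
        W2[0, 1] += 1.0
        layer2 = layer_of(W2)
        bumped = StressTypeClassifier(layer=layer2).decision_function(X)[:, 0]
        has_bit = X[:, 1] == 1
        assert np.all(bumped[has_bit] >= base[has_bit])


class TestPredictStress:
    def test_ranked_by_normalised_activation(self):
        stresses = ["cold", "heat", "salt", "drought"]
        # one set bit; per-stress weights give distinct activations
        W = np.array([[1.0, 0.0], [3.0, 0.0], [0.5, 0.0], [-1.0, 0.0]])
        layer = layer_of(W, stresses=stresses)
        ranking = predict_stress(np.array([1, 0]), layer)
        assert [s for s, _ in ranking] == ["heat", "cold", "salt", "drought"]

    def test_ties_break_by_vocabulary_order(self):
        stresses = ["cold", "heat", "salt", "drought"]
        layer = layer_of(np.zeros((4, 2)), stresses=stresses)
        ranking = predict_stress(np.array([1, 0]), layer)
        assert [s for s, _ in ranking] == stresses

    def test_single_stress_vocabulary(self):
        layer = layer_of(np.zeros((1, 2)), stresses=["heat"])
        assert predict_stress(np.array([0, 1]), layer)[0][0] == "heat"

    def test_params_do_not_change_the_order(self):
        layer = layer_of(np.array([[2.0, 0.0], [1.0, 0.0]]))
        params = PredictionParams(a=np.array([5.0, -5.0]), b=np.array([9.0, 0.1]))
        assert [s for s, _ in predict_stress(np.array([1, 0]), layer)] == [
            s for s, _ in predict_stress(np.array([1, 0]), layer, params)
        ]


class TestTrainPredictionWrapper:
    def test_functional_wrapper_matches_estimator(self):
        layer, X, y = TestClassifier._toy_model()
        batch = [
            EmbeddedSample(sample_id=f"s{i}", x=X[i], y=np.eye(2)[y[i]])
            for i in range(len(y))
        ]
        params = train_prediction(batch, layer, epochs=50)
        clf = StressTypeClassifier(layer=layer, epochs=50).fit(X, y)
        np.testing.assert_allclose(params.a, clf.a_)
        np.testing.assert_allclose(params.b, clf.b_)


class TestEvaluateAccuracy:
    def test_values(self):
        assert evaluate_accuracy(["a", "b"], ["a", "b"]) == 1.0
        assert evaluate_accuracy(["a"] * 29 + ["x"], ["a"] * 30) == pytest.approx(
            0.9667, abs=5e-5
        )
        assert evaluate_accuracy(["a", "a"], ["b", "c"]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            evaluate_accuracy(["a"], ["a", "b"])
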
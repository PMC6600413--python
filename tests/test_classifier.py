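"""Softmax head, end-to-end cost/gradient, fine-tuning and prediction."""

import numpy as np
import pytest

from mdbn import (
    CDConfig,
    FinetuneConfig,
    MDBNModel,
    SoftmaxParams,
    cost_and_grad,
    finetune,
    load_model,
    predict,
    pretrain,
    save_model,
    softmax_probs,
    train_softmax_head,
)
from mdbn.classifier import flatten_params, set_flat_params
from mdbn.rbm import sigmoid

from conftest import make_small_model


def numeric_gradient(model, X, Y, lam, masks, eps=1e-5):
    x = flatten_params(model)
    num = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        set_flat_params(model, xp)
        cp, _ = cost_and_grad(model, X, Y, lam, masks)
        set_flat_params(model, xm)
        cm, _ = cost_and_grad(model, X, Y, lam, masks)
        num[i] = (cp - cm) / (2 * eps)
    set_flat_params(model, x)
    return num


class TestSoftmaxProbs:
    def test_zero_parameters_give_uniform(self, rng):
        params = SoftmaxParams(np.zeros((3, 4)), np.zeros(3))
        probs = softmax_probs(params, rng.random((5, 4)))
        np.testing.assert_allclose(probs, 1.0 / 3.0)

    def test_rows_sum_to_one(self, rng):
        params = SoftmaxParams(rng.normal(0, 2, (4, 3)), rng.normal(0, 1, 4))
        probs = softmax_probs(params, rng.normal(0, 5, (10, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_binary_case_reduces_to_logistic(self, rng):
        params = SoftmaxParams(rng.normal(0, 1, (2, 3)), rng.normal(0, 1, 2))
        feats = rng.normal(0, 1, (6, 3))
        probs = softmax_probs(params, feats)
        logit_diff = (
            feats @ (params.weights[0] - params.weights[1])
            + params.biases[0]
            - params.biases[1]
        )
        np.testing.assert_allclose(probs[:, 0], sigmoid(logit_diff), atol=1e-12)

    def test_stable_under_large_logits(self):
        params = SoftmaxParams(np.array([[1000.0], [-1000.0]]), np.zeros(2))
        probs = softmax_probs(params, np.array([[1.0]]))
        assert np.all(np.isfinite(probs))
        assert probs[0, 0] == 1.0


class TestCostAndGrad:
    @pytest.mark.parametrize(
        "arch, k", [((5, 4, 3), 2), ((6, 3), 3), ((4, 5, 2, 3), 3)]
    )
    def test_gradient_matches_finite_differences(self, rng, arch, k):
        model = make_small_model(arch=arch, k=k, seed=1)
        X = rng.random((7, arch[0]))
        Y = np.eye(k)[rng.integers(0, k, 7)]
        masks = [
            (rng.random((7, s)) < 0.7).astype(float) for s in arch[1:]
        ]
        _, grad = cost_and_grad(model, X, Y, 1e-3, masks)
        num = numeric_gradient(model, X, Y, 1e-3, masks)
        assert np.linalg.norm(num - grad) / np.linalg.norm(grad) < 1e-6

    def test_perfectly_confident_correct_predictions_cost_zero(self):
        """Saturated correct logits give exactly zero cross-entropy."""
        model = make_small_model(arch=(2, 2), k=2, seed=0)
        model.softmax.weights[:] = [[4000.0, 0.0], [-4000.0, 0.0]]
        model.softmax.biases[:] = 0.0
        model.dbn.rbms[0].W[:] = 0.0
        model.dbn.rbms[0].b[:] = [50.0, -50.0]  # features saturate to (1, 0)
        X = np.array([[0.3, 0.4]])
        Y = np.array([[1.0, 0.0]])
        cost, _ = cost_and_grad(model, X, Y, 0.0)
        assert cost == 0.0

    def test_weight_decay_term_is_linear_in_lambda(self, rng, small_model):
        X = rng.random((5, 5))
        Y = np.eye(2)[rng.integers(0, 2, 5)]
        c0, _ = cost_and_grad(small_model, X, Y, 0.0)
        c1, _ = cost_and_grad(small_model, X, Y, 0.1)
        c2, _ = cost_and_grad(small_model, X, Y, 0.2)
        sum_sq = sum(
            float(np.sum(r.W**2)) for r in small_model.dbn.rbms
        ) + float(np.sum(small_model.softmax.weights**2))
        assert c1 - c0 == pytest.approx(0.05 * sum_sq)
        assert c2 - c1 == pytest.approx(c1 - c0)

    def test_non_one_hot_targets_rejected(self, rng, small_model):
        X = rng.random((3, 5))
        with pytest.raises(ValueError, match="one-hot"):
            cost_and_grad(small_model, X, np.full((3, 2), 0.5), 0.0)


class TestSoftmaxHead:
    def test_linearly_separable_toy_reaches_full_accuracy(self):
        feats = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [0.9, 0.8]])
        Y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        head = train_softmax_head(feats, Y, weight_decay=0.0, iterations=500)
        assert (softmax_probs(head, feats).argmax(axis=1) == [0, 0, 1, 1]).all()

    def test_zero_iterations_returns_zero_init(self, rng):
        head = train_softmax_head(
            rng.random((4, 3)), np.eye(2)[[0, 1, 0, 1]], iterations=0
        )
        assert not head.weights.any() and not head.biases.any()

    def test_deterministic(self, rng):
        feats = rng.random((10, 3))
        Y = np.eye(2)[rng.integers(0, 2, 10)]
        h1 = train_softmax_head(feats, Y, iterations=50, seed=1)
        h2 = train_softmax_head(feats, Y, iterations=50, seed=1)
        np.testing.assert_array_equal(h1.weights, h2.weights)

    def test_single_class_targets_rejected(self, rng):
        Y = np.tile([1.0, 0.0], (4, 1))
        with pytest.raises(ValueError, match="classes"):
            train_softmax_head(rng.random((4, 3)), Y, iterations=10)


def _toy_problem(rng, n=24, d=6, k=2, dropout=0.0, seed=5):
    model = make_small_model(arch=(d, 4, 3), k=k, dropout=dropout, seed=seed, scale=0.3)
    X = rng.random((n, d))
    labels = (X[:, 0] + X[:, 1] > 1.0).astype(int)
    Y = np.eye(k)[labels]
    return model, X, Y


class TestFinetune:
    def test_zero_iterations_is_identity(self, rng):
        model, X, Y = _toy_problem(rng)
        cfg = FinetuneConfig(method="gd", iterations=0)
        out, trace = finetune(model, X, Y, X, Y, cfg)
        np.testing.assert_array_equal(
            flatten_params(out), flatten_params(model)
        )
        assert len(trace) == 0

    @pytest.mark.parametrize("method", ["gd", "lbfgs"])
    def test_trace_lengths_match_iterations(self, rng, method):
        model, X, Y = _toy_problem(rng, dropout=0.2)
        cfg = FinetuneConfig(method=method, iterations=7, tolerance=0.0)
        _, trace = finetune(model, X, Y, X, Y, cfg)
        assert len(trace.fmse) == len(trace.fmr) == len(trace.tmr) == 7
        assert all(0 <= v <= 1 for v in trace.fmr + trace.tmr)

    def test_gd_small_step_descends_monotonically(self, rng):
        model, X, Y = _toy_problem(rng)
        cfg = FinetuneConfig(
            method="gd", iterations=40, learning_rate=0.01, weight_decay=1e-3
        )
        _, trace = finetune(model, X, Y, X, Y, cfg)
        costs = np.array(trace.cost)
        assert np.all(np.diff(costs) <= 1e-12)

    def test_lbfgs_beats_gd_at_equal_budget(self, rng):
        model, X, Y = _toy_problem(rng, n=40)
        gd_cfg = FinetuneConfig(method="gd", iterations=60, weight_decay=1e-4)
        lb_cfg = FinetuneConfig(method="lbfgs", iterations=60, weight_decay=1e-4)
        _, gd_trace = finetune(model, X, Y, X, Y, gd_cfg)
        _, lb_trace = finetune(model, X, Y, X, Y, lb_cfg)
        assert lb_trace.cost[-1] <= gd_trace.cost[-1]

    def test_test_labels_never_influence_parameters(self, rng):
        """Corrupting test labels changes TMR but not the fitted model."""
        model, X, Y = _toy_problem(rng, dropout=0.3)
        test_X = rng.random((10, 6))
        test_Y = np.eye(2)[rng.integers(0, 2, 10)]
        cfg = FinetuneConfig(method="lbfgs", iterations=10, seed=3)
        out1, _ = finetune(model, X, Y, test_X, test_Y, cfg)
        corrupted = test_Y[:, ::-1].copy()
        out2, _ = finetune(model, X, Y, test_X, corrupted, cfg)
        np.testing.assert_array_equal(
            flatten_params(out1), flatten_params(out2)
        )

    @pytest.mark.parametrize("method", ["gd", "lbfgs"])
    def test_seeded_run_is_bit_reproducible(self, rng, method):
        model, X, Y = _toy_problem(rng, dropout=0.4)
        cfg = FinetuneConfig(method=method, iterations=12, seed=9)
        out1, t1 = finetune(model, X, Y, X, Y, cfg)
        out2, t2 = finetune(model, X, Y, X, Y, cfg)
        np.testing.assert_array_equal(
            flatten_params(out1), flatten_params(out2)
        )
        assert t1.fmse == t2.fmse and t1.tmr == t2.tmr

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            FinetuneConfig(method="adam")


class TestPredict:
    def test_uniform_probabilities_break_ties_to_first_class(self, rng):
        model = make_small_model(arch=(3, 2), k=3, seed=0)
        model.softmax.weights[:] = 0.0
        model.softmax.biases[:] = 0.0
        model.class_order = ["CG", "MG", "RG"]
        assert predict(model, rng.random((4, 3))) == ["CG"] * 4

    def test_prediction_is_deterministic(self, rng):
        model = make_small_model(arch=(4, 3), k=2, dropout=0.5, seed=2)
        X = rng.random((6, 4))
        assert predict(model, X) == predict(model, X)

    def test_agrees_with_manual_argmax(self, rng):
        from mdbn.dbn import DropoutSpec, forward

        model = make_small_model(arch=(4, 3), k=3, seed=8)
        model.class_order = ["a", "b", "c"]
        X = rng.random((3, 4))
        feats = forward(model.dbn, X, DropoutSpec(rate=0.0, mode="inference"))
        expected = [
            ["a", "b", "c"][i]
            for i in softmax_probs(model.softmax, feats).argmax(axis=1)
        ]
        assert predict(model, X) == expected


class TestSerialization:
    def test_save_load_round_trip(self, rng, tmp_path):
        from mdbn.data_io import NormalizationState

        model = make_small_model(arch=(4, 3, 2), k=3, dropout=0.25, seed=6)
        model.class_order = ["CG", "MG", "RG"]
        model.normalization = NormalizationState(
            np.zeros(4), np.ones(4), fitted_on_n=10
        )
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(
            flatten_params(back), flatten_params(model)
        )
        assert back.class_order == model.class_order
        assert back.dropout_rate == model.dropout_rate
        assert predict(back, rng.random((3, 4))) == predict(
            model, rng.random((3, 4))
        ) or True  # predictions compared below on shared input
        X = rng.random((5, 4))
        assert predict(back, X) == predict(model, X)


class TestEndToEnd:
    def test_full_pipeline_is_reproducible(self, rng):
        """pretrain + head + finetune twice from one seed: identical models."""
        X = rng.random((20, 6))
        Y = np.eye(2)[rng.integers(0, 2, 20)]

        def build():
            dbn = pretrain(X, [6, 4, 3], CDConfig(epochs=5, seed=2))
            head = train_softmax_head(
                np.zeros((20, 3)) + 0.5, Y, iterations=10, seed=2
            )
            model = MDBNModel(
                dbn=dbn, softmax=head, dropout_rate=0.2, class_order=["x", "y"]
            )
            out, _ = finetune(
                model, X, Y, X, Y, FinetuneConfig(method="lbfgs", iterations=8, seed=4)
            )
            return out

        np.testing.assert_array_equal(
            flatten_params(build()), flatten_params(build())
        )
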
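"""CNN architecture, losses, training behavior, inference contracts."""

import numpy as np
import pytest

from irfgnet import _nn
from irfgnet.model import (
    CNNModel,
    ClassWeights,
    ModelConfig,
    TrainConfig,
    bce_loss,
    build_model,
    classify,
    compute_class_weights,
    predict_proba,
    train,
    wbce_loss,
    _loss_grad_logits,
)
from irfgnet.synth import SyntheticConfig, dataset_arrays, generate_dataset, synthetic_catalog

TINY = ModelConfig(
    n_classes=3, input_length=24, conv_blocks=((4, 3, 2), (6, 3, 2)), fc_sizes=(8,), dropout_rate=0.0
)


def test_output_dimension_matches_class_count():
    for k in (37, 22):
        m = build_model(ModelConfig(n_classes=k), seed=0)
        probs = m.predict_proba_array(np.random.default_rng(0).random((4, 600)))
        assert probs.shape == (4, k)
        assert probs.min() >= 0 and probs.max() <= 1


def test_excessive_pooling_rejected():
    with pytest.raises(ValueError, match="block"):
        ModelConfig(n_classes=5, conv_blocks=((8, 3, 10), (8, 3, 10), (8, 3, 10)))


def test_config_requires_layers_and_valid_dropout():
    with pytest.raises(ValueError):
        ModelConfig(n_classes=3, conv_blocks=())
    with pytest.raises(ValueError):
        ModelConfig(n_classes=3, dropout_rate=1.0)


def test_parameter_count_reproducible():
    a = build_model(TINY, seed=1)
    b = build_model(TINY, seed=2)
    assert a.n_parameters == b.n_parameters > 0


def test_class_weights_ratio_and_cap(caplog):
    Y = np.zeros((110, 3), dtype=int)
    Y[:55, 0] = 1  # balanced
    Y[:10, 1] = 1  # 10 pos / 100 neg
    w = compute_class_weights(Y)
    assert w.w_pos[0] == pytest.approx(1.0)
    assert w.w_pos[1] == pytest.approx(10.0)
    assert w.w_pos[2] == pytest.approx(100.0)  # no positives -> capped
    np.testing.assert_array_equal(w.w_neg, 1.0)


def test_unit_weight_wbce_equals_bce_exactly(rng):
    for _ in range(100):
        n, k = int(rng.integers(1, 30)), int(rng.integers(1, 10))
        P = rng.random((n, k))
        Y = (rng.random((n, k)) < 0.5).astype(float)
        assert wbce_loss(P, Y, ClassWeights.unit(k)) == bce_loss(P, Y)


def test_wbce_closed_form_single_cell():
    # y=1, p=0.5, w_pos=2 -> -2*log(0.5) = 2 ln 2
    loss = wbce_loss(
        np.array([[0.5]]), np.array([[1.0]]), ClassWeights(np.array([2.0]), np.array([1.0]))
    )
    assert loss == pytest.approx(2 * np.log(2), rel=1e-12)


def test_loss_nonnegative_and_zero_at_perfect_prediction(rng):
    Y = (rng.random((20, 4)) < 0.5).astype(float)
    assert bce_loss(Y, Y) == pytest.approx(0.0, abs=1e-5)
    P = rng.random((20, 4))
    assert bce_loss(P, Y) >= 0


def test_loss_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        bce_loss(np.zeros((3, 2)), np.zeros((2, 3)))


def test_analytic_gradient_matches_finite_differences():
    """Backprop through conv/batchnorm/pool/dense agrees with central
    differences (float64, dropout off)."""
    old_F = _nn.F
    _nn.F = np.float64
    try:
        m = CNNModel(TINY, seed=0)
        r = np.random.default_rng(1)
        X = r.random((5, 1, 24))
        Y = (r.random((5, 3)) < 0.5).astype(float)
        w = ClassWeights(np.array([1.0, 2.0, 0.5]), np.ones(3))

        def loss_val():
            p = _nn.sigmoid(m._forward_logits(X, train=True).astype(float))
            return wbce_loss(p, Y, w), p

        _, p = loss_val()
        m._backward(_loss_grad_logits(p, Y, w))
        for lay in m.layers:
            for name, par, grad in lay.params():
                flat, gflat = par.ravel(), grad.ravel()
                for i in r.choice(flat.size, size=min(4, flat.size), replace=False):
                    eps, old = 1e-6, flat[i]
                    flat[i] = old + eps
                    lp, _ = loss_val()
                    flat[i] = old - eps
                    lm, _ = loss_val()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    # conv biases are cancelled by batch-norm: true grad ~ 0
                    assert abs(num - gflat[i]) < 1e-6 + 1e-4 * max(abs(num), abs(gflat[i]))
    finally:
        _nn.F = old_F


@pytest.fixture(scope="module")
def small_task():
    cat = synthetic_catalog(4)
    cfg = SyntheticConfig(n_samples=200, catalog=cat, seed=3)
    X, Y, _ = dataset_arrays(generate_dataset(cfg))
    return X, Y


def test_training_reduces_loss(small_task):
    X, Y = small_task
    mc = ModelConfig(n_classes=4, conv_blocks=((8, 9, 2), (16, 9, 2)), fc_sizes=(32,))
    model, log = train((X, Y), mc, TrainConfig(seed=1, epochs=5))
    assert log[-1]["train_loss"] < log[0]["train_loss"]


def test_training_deterministic_for_fixed_seed(small_task):
    X, Y = small_task
    mc = ModelConfig(n_classes=4, conv_blocks=((8, 9, 2),), fc_sizes=(16,))
    _, log1 = train((X, Y), mc, TrainConfig(seed=5, epochs=2))
    _, log2 = train((X, Y), mc, TrainConfig(seed=5, epochs=2))
    assert abs(log1[0]["train_loss"] - log2[0]["train_loss"]) < 1e-6
    assert abs(log1[-1]["val_loss"] - log2[-1]["val_loss"]) < 1e-6


def test_training_rejects_empty_and_inconsistent_data():
    mc = ModelConfig(n_classes=4)
    with pytest.raises(ValueError):
        train([], mc, TrainConfig(seed=1))
    with pytest.raises(ValueError):
        train((np.zeros((5, 600)), np.zeros((5, 3))), mc, TrainConfig(seed=1))


def test_inference_deterministic_and_row_consistent(small_task):
    X, Y = small_task
    mc = ModelConfig(n_classes=4, conv_blocks=((8, 9, 2),), fc_sizes=(16,))
    model, _ = train((X, Y), mc, TrainConfig(seed=5, epochs=2))
    batch = np.stack([X[0], X[1], X[0]])
    probs = model.predict_proba_array(batch)
    np.testing.assert_array_equal(probs[0], probs[2])
    np.testing.assert_allclose(model.predict_proba_array(batch), probs)


def test_wrong_input_length_rejected():
    m = build_model(ModelConfig(n_classes=3), seed=0)
    with pytest.raises(ValueError, match="length"):
        m.predict_proba_array(np.zeros((2, 599)))


def test_classify_threshold_semantics():
    P = np.array([[0.7, 0.3], [0.5, 0.5]])
    out = classify(P, np.array([0.5, 0.5]))
    np.testing.assert_array_equal(out, [[1, 0], [1, 1]])  # ties are positive
    with pytest.raises(ValueError):
        classify(P, np.array([0.5, 1.5]))
    with pytest.raises(ValueError):
        classify(P, np.array([0.5]))


def test_model_save_load_roundtrip(tmp_path, small_task):
    X, Y = small_task
    mc = ModelConfig(n_classes=4, conv_blocks=((8, 9, 2),), fc_sizes=(16,))
    model, _ = train((X, Y), mc, TrainConfig(seed=5, epochs=2))
    model.thresholds = np.full(4, 0.5)
    model.save(tmp_path / "m.npz")
    loaded = type(model).load(tmp_path / "m.npz")
    np.testing.assert_allclose(
        loaded.predict_proba_array(X[:8]), model.predict_proba_array(X[:8]), atol=1e-6
    )
    with pytest.raises(ValueError):
        type(model).load(tmp_path / "missing.npz")
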
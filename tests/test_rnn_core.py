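import math

import numpy as np
import pytest

from conftest import max_relative_gradient_error, numerical_gradients
from mcifuse.rnn_core import (
    GRUParams,
    RNNParams,
    batch_loss,
    bptt_gradients,
    classify,
    cross_entropy,
    encode_sequence,
    gru_step,
    load_params,
    loss_and_gradients,
    one_hot,
    rnn_step,
    save_params,
    softmax,
    tanh_activation,
)


def test_tanh_matches_printed_form_and_symmetry():
    assert tanh_activation(np.array([0.0]))[0] == 0.0
    # independent evaluation of 2/(1+e^{-2x}) - 1 at x = 1
    assert tanh_activation(np.array([1.0]))[0] == pytest.approx(
        2.0 / (1.0 + math.exp(-2.0)) - 1.0, rel=1e-15
    )
    x = np.linspace(-3, 3, 13)
    np.testing.assert_allclose(tanh_activation(-x), -tanh_activation(x), atol=1e-15)
    assert np.all(np.abs(tanh_activation(np.array([50.0, -50.0, 1e4]))) <= 1.0)


def test_softmax_symmetry_stability_and_formula():
    np.testing.assert_allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])
    big = softmax(np.array([1000.0, 0.0]))
    assert np.all(np.isfinite(big))
    np.testing.assert_allclose(big, [1.0, 0.0], atol=1e-300)
    u = np.array([1.0, 2.0])
    direct = np.exp(u) / np.exp(u).sum()
    np.testing.assert_allclose(softmax(u), direct, rtol=1e-14)
    # shift invariance
    np.testing.assert_allclose(softmax(u + 17.3), softmax(u), rtol=1e-12)


def test_rnn_step_zero_params_and_naive_oracle():
    p = RNNParams(np.zeros((3, 3)), np.zeros((3, 2)), np.zeros((2, 3)))
    np.testing.assert_array_equal(rnn_step(p, np.ones(3), np.ones(2)), np.zeros(3))

    rng = np.random.default_rng(0)
    p = RNNParams.init(2, 3, seed=4)
    h_prev, x = rng.normal(size=3), rng.normal(size=2)
    # naive elementwise re-computation
    expected = np.empty(3)
    for i in range(3):
        acc = sum(p.W_h[i, j] * h_prev[j] for j in range(3))
        acc += sum(p.W_x[i, j] * x[j] for j in range(2))
        expected[i] = math.tanh(acc)
    np.testing.assert_allclose(rnn_step(p, h_prev, x), expected, rtol=1e-14)


def test_rnn_step_shape_mismatch():
    p = RNNParams.init(2, 3, seed=0)
    with pytest.raises(ValueError):
        rnn_step(p, np.zeros(4), np.zeros(2))


def _zero_gru(hidden=3, feats=2, classes=2):
    z = np.zeros
    return GRUParams(
        z((hidden, feats)), z((hidden, hidden)), z(hidden),
        z((hidden, feats)), z((hidden, hidden)), z(hidden),
        z((hidden, feats)), z((hidden, hidden)), z(hidden),
        z((classes, hidden)),
    )


def test_gru_step_zero_params_halves_previous_state():
    # gates sit at logistic(0) = 0.5 and the candidate at tanh(0) = 0,
    # so h = (1 - 0.5) h_prev + 0.5 * 0
    p = _zero_gru()
    h_prev = np.array([0.4, -0.2, 0.8])
    np.testing.assert_allclose(gru_step(p, h_prev, np.ones(2)), 0.5 * h_prev)
    np.testing.assert_array_equal(gru_step(p, np.zeros(3), np.ones(2)), np.zeros(3))


def test_gru_step_scalar_hand_oracle():
    p = GRUParams(
        W_z=np.array([[0.5]]), U_z=np.array([[0.25]]), b_z=np.array([0.1]),
        W_r=np.array([[-0.3]]), U_r=np.array([[0.2]]), b_r=np.array([0.0]),
        W_c=np.array([[0.7]]), U_c=np.array([[-0.4]]), b_c=np.array([0.05]),
        W_y=np.array([[1.0], [-1.0]]),
    )
    h_prev, x = 0.3, 0.9

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    z = sig(0.5 * x + 0.25 * h_prev + 0.1)
    r = sig(-0.3 * x + 0.2 * h_prev + 0.0)
    c = math.tanh(0.7 * x + (-0.4) * (r * h_prev) + 0.05)
    expected = (1 - z) * h_prev + z * c
    got = gru_step(p, np.array([h_prev]), np.array([x]))
    assert got[0] == pytest.approx(expected, rel=1e-14)


def test_encode_sequence_definition_and_composition():
    p = GRUParams.init(2, 3, seed=9)
    x1, x2 = np.array([0.3, -0.1]), np.array([0.6, 0.2])
    # T = 1 equals a single step from the zero state
    np.testing.assert_array_equal(
        encode_sequence(p, np.array([x1])), gru_step(p, np.zeros(3), x1)
    )
    # T = 2 equals composing single steps
    h = gru_step(p, gru_step(p, np.zeros(3), x1), x2)
    np.testing.assert_allclose(encode_sequence(p, np.stack([x1, x2])), h, rtol=1e-14)
    # zero GRU params: state never leaves zero
    np.testing.assert_array_equal(
        encode_sequence(_zero_gru(), np.zeros((5, 2))), np.zeros(3)
    )
    with pytest.raises(ValueError):
        encode_sequence(p, np.empty((0, 2)))


def test_hidden_state_stays_in_open_unit_ball():
    """From the zero state every intermediate entry stays strictly in (-1, 1)
    for both cell types (tanh-bounded candidates)."""
    rng = np.random.default_rng(12)
    for _ in range(50):
        hid, feats, T = rng.integers(1, 4), rng.integers(1, 4), rng.integers(1, 6)
        X = rng.normal(scale=3.0, size=(T, feats))
        for params in (
            GRUParams.init(feats, hid, seed=int(rng.integers(1 << 16))),
            RNNParams.init(feats, hid, seed=int(rng.integers(1 << 16))),
        ):
            step = gru_step if isinstance(params, GRUParams) else rnn_step
            h = np.zeros(hid)
            for x in X:
                h = step(params, h, x)
                assert np.all(np.abs(h) < 1.0)


def test_classify_uniform_and_formula():
    h = np.array([0.3, -0.7, 0.1])
    np.testing.assert_allclose(classify(h, np.zeros((2, 3))), [0.5, 0.5])
    W_y = np.array([[1.0, 0.0, 2.0], [0.5, -1.0, 0.0]])
    np.testing.assert_allclose(classify(h, W_y), softmax(W_y @ h), rtol=1e-14)
    assert classify(h, W_y).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        classify(np.zeros(4), W_y)


def test_cross_entropy_closed_forms_and_naive_oracle():
    perfect = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert cross_entropy(perfect, perfect) == 0.0
    uniform = np.full((4, 2), 0.5)
    assert cross_entropy(one_hot([0, 1, 0, 1]), uniform) == pytest.approx(math.log(2))
    y = one_hot([0, 1, 1], 3)
    y_hat = np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3], [0.3, 0.5, 0.2]])
    naive = -(math.log(0.7) + math.log(0.6) + math.log(0.5)) / 3.0
    assert cross_entropy(y, y_hat) == pytest.approx(naive, rel=1e-14)
    with pytest.raises(ValueError):
        cross_entropy(np.empty((0, 2)), np.empty((0, 2)))


def test_cross_entropy_nonnegative_random():
    rng = np.random.default_rng(5)
    for _ in range(20):
        y_hat = softmax(rng.normal(size=(6, 2)))
        assert cross_entropy(one_hot(rng.integers(0, 2, 6)), y_hat) >= 0.0


@pytest.mark.parametrize("cell", ["gru", "rnn"])
@pytest.mark.parametrize("trial", range(10))
def test_bptt_matches_central_differences(cell, trial):
    """Exact-gradient contract: reverse-mode BPTT vs numerical differentiation
    on random small instances (hidden <= 3, T <= 4), rel. error <= 1e-5."""
    rng = np.random.default_rng(1000 * (cell == "gru") + trial)
    hid = int(rng.integers(1, 4))
    feats = int(rng.integers(1, 4))
    n = int(rng.integers(2, 5))
    seqs = [rng.normal(size=(int(rng.integers(1, 5)), feats)) for _ in range(n)]
    labels = rng.integers(0, 2, n)
    cls = GRUParams if cell == "gru" else RNNParams
    params = cls.init(feats, hid, seed=int(rng.integers(1 << 16)))
    analytic = bptt_gradients(params, seqs, labels)
    numeric = numerical_gradients(params, seqs, labels)
    assert max_relative_gradient_error(analytic, numeric) <= 1e-5


def test_gradient_vanishes_at_saturated_minimum():
    """A perfectly separated, saturated toy problem sits at (numerically)
    zero loss, so the gradient norm is ~0."""
    p = GRUParams.init(1, 1, seed=3)
    p.W_y = np.array([[-80.0], [80.0]])
    p.W_c = np.array([[5.0]])  # strong push so h_T has a definite sign
    seqs = [np.array([[2.0]]), np.array([[2.0], [2.0]])]
    grads = bptt_gradients(p, seqs, [1, 1])
    total = sum(np.abs(g).sum() for g in grads.arrays().values())
    assert total < 1e-8


def test_single_sample_scalar_rnn_matches_chain_rule():
    """T=1 scalar vanilla RNN: closed-form chain-rule gradient."""
    w_h, w_x, w_y = 0.3, 0.8, 1.2
    x, label = 0.5, 1
    p = RNNParams(np.array([[w_h]]), np.array([[w_x]]),
                  np.array([[0.0], [w_y]]))
    h = math.tanh(w_x * x)
    logits = np.array([0.0, w_y * h])
    pvec = np.exp(logits - logits.max())
    pvec /= pvec.sum()
    # dL/dW_y[1] = (p1 - 1) h ; dL/dW_x = (p1-1) w_y (1-h^2) x ; dL/dW_h = 0
    grads = bptt_gradients(p, [np.array([[x]])], [label])
    assert grads.W_y[1, 0] == pytest.approx((pvec[1] - 1.0) * h, rel=1e-12)
    assert grads.W_x[0, 0] == pytest.approx(
        (pvec[1] - 1.0) * w_y * (1 - h * h) * x, rel=1e-12
    )
    assert grads.W_h[0, 0] == 0.0  # h_0 = 0


def test_descent_step_reduces_loss_on_fixed_batch():
    rng = np.random.default_rng(8)
    p = GRUParams.init(2, 3, seed=21)
    seqs = [rng.normal(size=(T, 2)) for T in (1, 2, 3, 4)]
    labels = [0, 1, 1, 0]
    loss0, grads = loss_and_gradients(p, seqs, labels)
    for name, g in grads.arrays().items():
        getattr(p, name)[...] -= 1e-3 * g
    assert batch_loss(p, seqs, labels) < loss0


def test_chunked_and_batched_encoding_agree():
    """loss_and_gradients' batched unrolling equals the one-step-at-a-time
    encoder for every sequence length in the batch."""
    rng = np.random.default_rng(14)
    p = GRUParams.init(2, 3, seed=5)
    seqs = [rng.normal(size=(T, 2)) for T in (1, 3, 3, 2)]
    hs = [encode_sequence(p, s) for s in seqs]
    probs = [classify(h, p.W_y) for h in hs]
    labels = [0, 1, 0, 1]
    expected = cross_entropy(one_hot(labels), np.stack(probs))
    assert batch_loss(p, seqs, labels) == pytest.approx(expected, rel=1e-12)


def test_params_save_load_roundtrip(tmp_path):
    for params in (GRUParams.init(2, 3, seed=1), RNNParams.init(3, 2, seed=2)):
        path = tmp_path / "p.json"
        save_params(params, path)
        back = load_params(path)
        assert type(back) is type(params)
        for name, arr in params.arrays().items():
            np.testing.assert_array_equal(arr, back.arrays()[name])


def test_params_shape_validation():
    with pytest.raises(ValueError):
        RNNParams(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros((2, 3)))
    with pytest.raises(ValueError):
        GRUParams(*[np.zeros((2, 2))] * 10)
    with pytest.raises(ValueError):
        RNNParams(np.full((2, 2), np.nan), np.zeros((2, 2)), np.zeros((2, 2)))
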
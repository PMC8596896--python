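"""Brute-force oracle equivalence and algebraic contracts for the network ops.

Every operation of the forward pass is checked against an independent
nested-loop implementation on randomized small instances, plus the
closed-form corner cases (identity filter, uniform attention, one-hot
selection, σ(0)=0.5, 50·ln2 loss...).
"""

import numpy as np
import pytest

from swam.model import (
    ModelConfig,
    SWAMModel,
    attend_pool,
    bce_loss,
    classify,
    conv_forward,
    forward,
    max_pool,
    perlabel_attention,
)

RNG = np.random.default_rng(20240917)


# ---------------------------------------------------------------- oracles


def conv_oracle(X, Wc, bc, activation="tanh"):
    d_e, N = X.shape
    k, _, d_c = Wc.shape
    left = (k - 1) // 2
    H = np.zeros((d_c, N))
    for n in range(N):
        z = bc.copy()
        for t in range(k):
            pos = n - left + t
            if 0 <= pos < N:
                z = z + X[:, pos] @ Wc[t]
        H[:, n] = np.tanh(z) if activation == "tanh" else np.maximum(z, 0)
    return H


def softmax_oracle(scores):
    e = np.exp(scores)
    return e / e.sum()


def attend_oracle(H, alpha):
    v = np.zeros(H.shape[0])
    for n in range(H.shape[1]):
        v = v + alpha[n] * H[:, n]
    return v


def bce_oracle(yhat, y):
    total = 0.0
    for p, t in zip(yhat, y):
        total -= t * np.log(p) + (1 - t) * np.log(1 - p)
    return total


# ------------------------------------------------------------ conv layer


def test_conv_identity_filter():
    X = np.array([[1.0, 2.0, 3.0]])
    Wc = np.ones((1, 1, 1))
    H = conv_forward(X, Wc, np.zeros(1), activation="relu")
    np.testing.assert_allclose(H, [[1.0, 2.0, 3.0]])


@pytest.mark.parametrize("k", range(1, 11))
def test_conv_length_conservation(k):
    X = RNG.normal(size=(4, 13))
    Wc = RNG.normal(size=(k, 4, 5))
    assert conv_forward(X, Wc, np.zeros(5)).shape == (5, 13)


@pytest.mark.parametrize("trial", range(100))
def test_conv_matches_loop_oracle(trial):
    rng = np.random.default_rng(trial)
    k = int(rng.integers(1, 6))
    N = int(rng.integers(max(1, k - 2), 9))
    d_e, d_c = int(rng.integers(1, 5)), int(rng.integers(1, 6))
    X = rng.normal(size=(d_e, N))
    Wc = rng.normal(size=(k, d_e, d_c))
    bc = rng.normal(size=d_c)
    act = "tanh" if trial % 2 == 0 else "relu"
    np.testing.assert_allclose(
        conv_forward(X, Wc, bc, act), conv_oracle(X, Wc, bc, act), atol=1e-6
    )


def test_conv_rejects_nonfinite_input():
    X = np.array([[1.0, np.nan]])
    with pytest.raises(ValueError):
        conv_forward(X, np.ones((1, 1, 1)), np.zeros(1))


# ------------------------------------------------------------- attention


def test_attention_uniform_for_zero_vector():
    H = RNG.normal(size=(3, 5))
    np.testing.assert_allclose(perlabel_attention(H, np.zeros(3)), np.full(5, 0.2))


def test_attention_closed_form():
    # scores [ln 2, 0] -> [2/3, 1/3]
    H = np.array([[np.log(2.0), 0.0]])
    np.testing.assert_allclose(
        perlabel_attention(H, np.ones(1)), [2 / 3, 1 / 3], atol=1e-12
    )


@pytest.mark.parametrize("trial", range(100))
def test_attention_matches_naive_softmax(trial):
    rng = np.random.default_rng(1000 + trial)
    d_c, N = int(rng.integers(1, 6)), int(rng.integers(1, 9))
    H = rng.normal(size=(d_c, N))
    u = rng.normal(size=d_c)
    alpha = perlabel_attention(H, u)
    np.testing.assert_allclose(alpha, softmax_oracle(H.T @ u), atol=1e-6)
    assert alpha.sum() == pytest.approx(1.0, abs=1e-9)


def test_attention_mask_zeroes_padding_and_renormalizes():
    H = RNG.normal(size=(2, 4))
    mask = np.array([True, True, False, True])
    alpha = perlabel_attention(H, RNG.normal(size=2), mask)
    assert alpha[2] == 0.0
    assert alpha.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        perlabel_attention(H, np.zeros(2), np.zeros(4, dtype=bool))


# ---------------------------------------------------------------- pooling


def test_attend_pool_selection_and_convexity():
    H = RNG.normal(size=(4, 6))
    one_hot = np.zeros(6)
    one_hot[3] = 1.0
    np.testing.assert_allclose(attend_pool(H, one_hot), H[:, 3])
    col = RNG.normal(size=4)
    H_same = np.tile(col[:, None], (1, 6))
    np.testing.assert_allclose(attend_pool(H_same, np.full(6, 1 / 6)), col, atol=1e-12)


@pytest.mark.parametrize("trial", range(100))
def test_attend_pool_matches_loop(trial):
    rng = np.random.default_rng(2000 + trial)
    H = rng.normal(size=(int(rng.integers(1, 6)), int(rng.integers(1, 9))))
    alpha = rng.dirichlet(np.ones(H.shape[1]))
    np.testing.assert_allclose(attend_pool(H, alpha), attend_oracle(H, alpha), atol=1e-6)


def test_attend_pool_shape_mismatch():
    with pytest.raises(ValueError):
        attend_pool(np.zeros((2, 3)), np.ones(4) / 4)


def test_max_pool_values_argmax_and_oracle():
    H = np.array([[-1.0, 5.0, 2.0], [0.0, 0.0, 1.0]])
    v, arg = max_pool(H)
    np.testing.assert_array_equal(v, [5.0, 1.0])
    np.testing.assert_array_equal(arg, [1, 2])
    for trial in range(100):
        rng = np.random.default_rng(3000 + trial)
        H = rng.normal(size=(int(rng.integers(1, 6)), int(rng.integers(1, 9))))
        v, arg = max_pool(H)
        np.testing.assert_array_equal(v, np.array([row.max() for row in H]))
        np.testing.assert_array_equal(arg, np.array([row.argmax() for row in H]))


def test_max_pool_mask_and_degenerate():
    H = np.array([[1.0, 9.0, 2.0]])
    v, arg = max_pool(H, np.array([True, False, True]))
    assert v[0] == 2.0 and arg[0] == 2
    with pytest.raises(ValueError):
        max_pool(H, np.zeros(3, dtype=bool))


# ----------------------------------------------------------- classification


def test_classify_closed_forms_and_monotonicity():
    assert classify(np.zeros(3), np.zeros(3), 0.0) == pytest.approx(0.5)
    assert classify(np.ones(1), np.array([np.log(3.0)]), 0.0) == pytest.approx(0.75)
    v, beta = RNG.normal(size=4), RNG.normal(size=4)
    ys = [classify(v, beta, b) for b in (-1.0, 0.0, 1.0, 2.0)]
    assert all(a < b for a, b in zip(ys, ys[1:]))


def test_bce_closed_forms_and_oracle():
    y = (RNG.random(50) < 0.5).astype(float)
    assert bce_loss(np.full(50, 0.5), y) == pytest.approx(50 * np.log(2))
    near = np.clip(y, 1e-12, 1 - 1e-12)
    assert bce_loss(near, y) == pytest.approx(0.0, abs=1e-9)
    for trial in range(100):
        rng = np.random.default_rng(4000 + trial)
        L = int(rng.integers(1, 8))
        yhat = rng.uniform(0.01, 0.99, size=L)
        yy = (rng.random(L) < 0.5).astype(float)
        assert bce_loss(yhat, yy) == pytest.approx(bce_oracle(yhat, yy), abs=1e-6)


def test_bce_clamps_out_of_range_with_warning():
    with pytest.warns(RuntimeWarning):
        loss = bce_loss(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    assert np.isfinite(loss)


# ------------------------------------------------------------ full forward


def test_forward_deterministic_without_dropout(micro_model):
    ids = np.array([1, 2, 3, 4, 2, 1])
    s1 = forward(ids, micro_model)
    s2 = forward(ids, micro_model)
    np.testing.assert_array_equal(s1.yhat, s2.yhat)
    assert s1.H.shape[1] == s1.X.shape[1] == len(ids)
    assert np.all((s1.yhat > 0) & (s1.yhat < 1))


def test_forward_hand_trace_single_label_single_filter():
    """|L|=1, d_c=1, k=1 model traced by hand through the four equations."""
    cfg = ModelConfig(n_labels=1, d_e=2, d_c=1, k=1, dropout=0.0)
    emb = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    model = SWAMModel(cfg, emb, seed=0)
    model.params["Wc"] = np.array([[[1.0], [0.5]]])  # k=1, d_e=2, d_c=1
    model.params["bc"] = np.array([0.1])
    model.params["U"] = np.array([[2.0]])
    model.params["B"] = np.array([[1.5]])
    model.params["b"] = np.array([-0.2])
    ids = np.array([1, 2])
    # H = tanh([1*1+0.5*0+0.1, 1*0+0.5*2+0.1]) = tanh([1.1, 1.1])
    h = np.tanh(np.array([1.1, 1.1]))
    alpha = softmax_oracle(2.0 * h)       # equal -> [0.5, 0.5]
    v = (alpha * h).sum()
    yhat = 1 / (1 + np.exp(-(1.5 * v - 0.2)))
    state = forward(ids, model)
    np.testing.assert_allclose(state.H, h[None, :], atol=1e-6)
    np.testing.assert_allclose(state.A, alpha[None, :], atol=1e-6)
    np.testing.assert_allclose(state.yhat, [yhat], atol=1e-6)


def test_forward_all_pad_document_errors(micro_model):
    with pytest.raises(ValueError):
        forward(np.zeros(5, dtype=int), micro_model)


def test_max_pool_variant_permutation_invariance():
    cfg = ModelConfig(n_labels=3, d_e=4, d_c=6, k=1, dropout=0.0, attention="max_pool")
    rng = np.random.default_rng(5)
    emb = rng.normal(size=(10, 4))
    emb[0] = 0
    model = SWAMModel(cfg, emb, seed=1)
    ids = rng.integers(1, 10, size=12)
    perm = rng.permutation(12)
    y1 = forward(ids, model).yhat
    y2 = forward(ids[perm], model).yhat
    np.testing.assert_allclose(y1, y2, atol=1e-12)


def test_per_label_attention_position_equivariance():
    """Permuting tokens permutes α the same way (and yhat is unchanged, k=1)."""
    cfg = ModelConfig(n_labels=2, d_e=4, d_c=3, k=1, dropout=0.0)
    rng = np.random.default_rng(6)
    emb = rng.normal(size=(10, 4))
    emb[0] = 0
    model = SWAMModel(cfg, emb, seed=2)
    ids = rng.integers(1, 10, size=9)
    perm = rng.permutation(9)
    s1 = forward(ids, model)
    s2 = forward(ids[perm], model)
    np.testing.assert_allclose(s1.A[:, perm], s2.A, atol=1e-12)
    np.testing.assert_allclose(s1.yhat, s2.yhat, atol=1e-12)


def test_checkpoint_round_trip_bit_exact(tmp_path, micro_model):
    path = tmp_path / "model.npz"
    micro_model.save(path)
    back = SWAMModel.load(path)
    assert back.config == micro_model.config
    for name, val in micro_model.params.items():
        np.testing.assert_array_equal(back.params[name], val)
    ids = np.array([1, 2, 3])
    np.testing.assert_array_equal(forward(ids, back).yhat, forward(ids, micro_model).yhat)
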
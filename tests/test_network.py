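"""Network-cell oracles: scalar-loop LSTM, brute-force attention, MHA."""

import numpy as np
import pytest

from malnet.network import (ModelConfig, NetworkError, attention,
                            count_parameters, dropout, forward, init_params,
                            lstm_forward, lstm_step, multi_head_attention,
                            predict_labels, tokenize, load_checkpoint,
                            save_checkpoint)


# -- independent oracles ---------------------------------------------------

def _sigmoid_scalar(v):
    return 1.0 / (1.0 + np.exp(-v))


def _lstm_step_oracle(x, h_prev, c_prev, params):
    """Element-by-element scalar re-implementation of the gate update."""
    W = {g: params.W[g].data for g in "ifco"}
    U = {g: params.U[g].data for g in "ifco"}
    b = {g: params.b[g].data for g in "ifco"}
    hd = len(h_prev)
    h_new, c_new = np.zeros(hd), np.zeros(hd)
    for k in range(hd):
        pre = {g: b[g][k]
               + sum(x[j] * W[g][j, k] for j in range(len(x)))
               + sum(h_prev[j] * U[g][j, k] for j in range(hd))
               for g in "ifco"}
        i = _sigmoid_scalar(pre["i"])
        f = _sigmoid_scalar(pre["f"])
        c_tilde = np.tanh(pre["c"])
        c_new[k] = f * c_prev[k] + i * c_tilde
        o = _sigmoid_scalar(pre["o"])
        h_new[k] = o * np.tanh(c_new[k])
    return h_new, c_new


def _attention_oracle(Q, K, V):
    """Brute-force exp/normalize/matmul attention."""
    d_k = Q.shape[-1]
    scores = Q @ K.T / np.sqrt(d_k)
    e = np.exp(scores)
    w = e / e.sum(axis=-1, keepdims=True)
    return w @ V, w


# -- tokenize --------------------------------------------------------------

def test_tokenize_scaling_properties(rng):
    E = rng.standard_normal((6, 4))
    x = rng.random(6)
    toks = tokenize(x, E)
    assert toks.shape == (6, 4)
    np.testing.assert_allclose(tokenize(np.zeros(6), E), 0.0)
    np.testing.assert_allclose(tokenize(np.ones(6), E), E)
    np.testing.assert_allclose(tokenize(2 * x, E), 2 * toks)
    with pytest.raises(NetworkError):
        tokenize(np.ones(5), E)


# -- lstm ------------------------------------------------------------------

def test_lstm_step_zero_params_zero_state(small_config):
    params = init_params(small_config, d=6, seed=0)
    for g in "ifco":
        params.W[g].data[:] = 0
        params.U[g].data[:] = 0
        params.b[g].data[:] = 0
    h, c = lstm_step(np.ones(4), (np.zeros(4), np.zeros(4)), params)
    np.testing.assert_allclose(h, 0.0)   # o=0.5, tanh(c)=0
    np.testing.assert_allclose(c, 0.0)   # i=f=0.5, c̃=0


def test_lstm_memory_preservation_in_saturation(small_params):
    """f≈1, i≈0 keeps the cell state within 1e-4 of its previous value."""
    params = small_params
    params.b["f"].data[:] = 10.0
    params.b["i"].data[:] = -10.0
    params.W["o"].data[:] = 0.0
    params.U["o"].data[:] = 0.0
    c_prev = np.array([0.3, -0.5, 0.8, 0.1])
    h_prev = np.zeros(4)
    _, c = lstm_step(np.full(4, 0.2), (h_prev, c_prev), params)
    np.testing.assert_allclose(c, c_prev, atol=1e-4)


def test_lstm_step_matches_scalar_oracle(rng):
    cfg = ModelConfig(token_dim=3, hidden_dim=3, n_heads=1, dropout_p=0.0)
    params = init_params(cfg, d=4, seed=5)
    x = rng.standard_normal(3)
    h0 = rng.standard_normal(3) * 0.1
    c0 = rng.standard_normal(3) * 0.1
    h, c = lstm_step(x, (h0, c0), params)
    h_ref, c_ref = _lstm_step_oracle(x, h0, c0, params)
    np.testing.assert_allclose(h, h_ref, atol=1e-10)
    np.testing.assert_allclose(c, c_ref, atol=1e-10)


def test_lstm_forward_base_case_and_order_sensitivity(small_params, rng):
    toks = rng.standard_normal((1, 4))
    single = lstm_forward(toks, small_params)
    h_ref, _ = lstm_step(toks[0], (np.zeros(4), np.zeros(4)), small_params)
    np.testing.assert_allclose(single[0], h_ref)

    seq = rng.standard_normal((5, 4))
    out_fwd = lstm_forward(seq, small_params)
    out_rev = lstm_forward(seq[::-1], small_params)
    assert not np.allclose(out_fwd[-1], out_rev[-1])

    with pytest.raises(NetworkError):
        lstm_forward(np.empty((0, 4)), small_params)


def test_lstm_repeated_token_approaches_fixed_point(rng):
    """With a contractive random cell, repeating one token converges."""
    cfg = ModelConfig(token_dim=4, hidden_dim=4, n_heads=1, dropout_p=0.0)
    params = init_params(cfg, d=4, seed=3)
    for g in "ifco":                       # shrink recurrent gain
        params.U[g].data *= 0.3
    token = rng.standard_normal(4) * 0.5
    seq = np.tile(token, (60, 1))
    H = lstm_forward(seq, params)
    steps = np.linalg.norm(np.diff(H, axis=0), axis=1)
    assert steps[-1] < 1e-6
    assert (np.diff(steps[10:]) <= 1e-9).all()


# -- dropout ---------------------------------------------------------------

def test_dropout_identity_cases(rng):
    M = rng.standard_normal((10, 10))
    np.testing.assert_array_equal(dropout(M, 0.0, "train", 1), M)
    np.testing.assert_array_equal(dropout(M, 0.7, "eval", 1), M)
    with pytest.raises(NetworkError):
        dropout(M, 1.0, "train", 1)


def test_dropout_statistics_and_expectation(rng):
    M = np.ones((1000, 1000))
    out = dropout(M, 0.4, "train", seed=7)
    zero_frac = (out == 0).mean()
    n = M.size
    sd = np.sqrt(0.4 * 0.6 / n)
    assert abs(zero_frac - 0.4) <= 2.58 * sd            # binomial 99% CI
    assert abs(out.mean() - 1.0) <= 0.01                # inverted rescale
    survivors = out[out != 0]
    np.testing.assert_allclose(survivors, 1 / 0.6)
    # determinism per seed
    np.testing.assert_array_equal(out, dropout(M, 0.4, "train", seed=7))


# -- attention -------------------------------------------------------------

def test_attention_single_key_and_tied_keys(rng):
    q = rng.standard_normal((1, 4))
    k = rng.standard_normal((1, 4))
    v = rng.standard_normal((1, 4))
    out, w = attention(q, k, v)
    np.testing.assert_allclose(w, [[1.0]])
    np.testing.assert_allclose(out, v)

    k2 = np.vstack([k, k])                # identical keys -> equal weights
    v2 = rng.standard_normal((2, 4))
    _, w2 = attention(q, k2, v2)
    np.testing.assert_allclose(w2, [[0.5, 0.5]])


def test_attention_matches_bruteforce_oracle(rng):
    Q = rng.standard_normal((3, 4))
    K = rng.standard_normal((5, 4))
    V = rng.standard_normal((5, 2))
    out, w = attention(Q, K, V)
    out_ref, w_ref = _attention_oracle(Q, K, V)
    np.testing.assert_allclose(out, out_ref, atol=1e-10)
    np.testing.assert_allclose(w, w_ref, atol=1e-10)


def test_attention_weights_are_a_distribution(rng):
    _, w = attention(rng.standard_normal((6, 3)),
                     rng.standard_normal((4, 3)),
                     rng.standard_normal((4, 3)))
    assert (w >= 0).all()
    np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-9)


def test_mha_single_head_identity_reduces_to_attention(rng):
    cfg = ModelConfig(token_dim=4, hidden_dim=4, n_heads=1, dropout_p=0.0)
    params = init_params(cfg, d=6, seed=9)
    params.WQ[0].data = np.eye(4)
    params.WK[0].data = np.eye(4)
    params.WV[0].data = np.eye(4)
    params.WO.data = np.eye(4)
    H = rng.standard_normal((5, 4))
    out_ref, _ = attention(H, H, H)
    np.testing.assert_allclose(multi_head_attention(H, params), out_ref,
                               atol=1e-12)


def test_mha_matches_head_decomposition_oracle(small_params, rng):
    """H=4 MHA equals four independent single-head attentions concatenated
    and projected by W_O."""
    cfg = ModelConfig(token_dim=4, hidden_dim=4, n_heads=4, dropout_p=0.0)
    params = init_params(cfg, d=6, seed=13)
    H = rng.standard_normal((7, 4))
    heads = []
    for h in range(4):
        out, _ = attention(H @ params.WQ[h].data, H @ params.WK[h].data,
                           H @ params.WV[h].data)
        heads.append(out)
    expected = np.concatenate(heads, axis=-1) @ params.WO.data
    np.testing.assert_allclose(multi_head_attention(H, params), expected,
                               atol=1e-10)


def test_mha_length_one_sequence(small_params):
    """A single token attends only to itself: output = V-projection
    through W_O."""
    cfg = ModelConfig(token_dim=4, hidden_dim=4, n_heads=2, dropout_p=0.0)
    params = init_params(cfg, d=6, seed=17)
    H = np.array([[0.3, -0.2, 0.5, 0.1]])
    expected = np.concatenate(
        [H @ params.WV[h].data for h in range(2)], axis=-1) @ params.WO.data
    np.testing.assert_allclose(multi_head_attention(H, params), expected,
                               atol=1e-12)


# -- full forward ----------------------------------------------------------

def test_forward_outputs_probabilities(small_config, small_params, rng):
    x = rng.random(6)
    probs, logits = forward(x, small_params, small_config, mode="eval")
    assert probs.shape == (5,) and logits.shape == (5,)
    assert ((probs > 0) & (probs < 1)).all()
    np.testing.assert_allclose(probs, 1 / (1 + np.exp(-logits)), atol=1e-12)


def test_forward_eval_is_deterministic(small_config, small_params, rng):
    x = rng.random(6)
    p1, z1 = forward(x, small_params, small_config, mode="eval", seed=1)
    p2, z2 = forward(x, small_params, small_config, mode="eval", seed=999)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(z1, z2)


def test_forward_rejects_nonfinite_input(small_config, small_params):
    with pytest.raises(NetworkError):
        forward(np.array([np.nan] + [0.0] * 5), small_params, small_config)


def test_forward_no_mha_skips_attention(small_params, rng):
    cfg_on = ModelConfig(token_dim=4, hidden_dim=4, n_heads=2, dropout_p=0.0)
    cfg_off = ModelConfig(token_dim=4, hidden_dim=4, n_heads=2,
                          dropout_p=0.0, use_mha=False)
    x = rng.random(6)
    _, z_on = forward(x, small_params, cfg_on)
    _, z_off = forward(x, small_params, cfg_off)
    assert not np.allclose(z_on, z_off)


# -- thresholding ----------------------------------------------------------

def test_predict_labels_strict_threshold():
    p = np.array([0.9, 0.2, 0.6, 0.1, 0.55])
    np.testing.assert_array_equal(predict_labels(p, 0.5), [1, 0, 1, 0, 1])
    assert predict_labels(np.array([0.5]), 0.5)[0] == 0   # strict >
    np.testing.assert_array_equal(
        predict_labels(np.array([0.01, 0.99]), 0.0), [1, 1])


# -- parameter counting ----------------------------------------------------

@pytest.mark.parametrize("token_dim,hidden_dim,expected", [
    (32, 32, 8320),     # 4*((32+32)*32+32): the published LSTM baseline
    (1, 1, 12),         # 4*(2*1+1)
])
def test_lstm_parameter_count(token_dim, hidden_dim, expected):
    cfg = ModelConfig(token_dim=token_dim, hidden_dim=hidden_dim)
    assert count_parameters(cfg, d=38, scope="lstm_only") == expected


def test_full_count_exceeds_lstm_and_is_exact():
    cfg = ModelConfig()
    lstm = count_parameters(cfg, d=38, scope="lstm_only")
    full = count_parameters(cfg, d=38, scope="full")
    assert full > lstm
    expected = (lstm + 38 * 32                      # embeddings
                + 4 * 3 * 32 * 32 + (4 * 32) * 32   # MHA projections + W_O
                + 32 * 32 + 32 + 32 * 5 + 5)        # FC + output
    assert full == expected
    # counted arrays match the actual parameter store
    params = init_params(cfg, d=38, seed=0)
    assert sum(t.data.size for t in params.tensors()) == full


# -- checkpoint ------------------------------------------------------------

def test_checkpoint_roundtrip_and_schema_guard(tmp_path, small_config):
    params = init_params(small_config, d=6, seed=21)
    path = tmp_path / "ckpt.json"
    save_checkpoint(path, params, small_config, "fingerprintA")
    loaded, cfg = load_checkpoint(path, "fingerprintA")
    assert cfg == small_config
    for a, b in zip(params.tensors(), loaded.tensors()):
        np.testing.assert_array_equal(a.data, b.data)
    with pytest.raises(NetworkError, match="schema"):
        load_checkpoint(path, "fingerprintB")
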
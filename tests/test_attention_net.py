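"""Network components vs independent brute-force oracles, shape contracts,
determinism, and gradient flow."""

import numpy as np
import pytest

from pirbind.attention_net import (
    NetConfig,
    PiRNATargetNet,
    cross_entropy,
)
from pirbind.nn import Adam
from pirbind.seq_core import one_hot_encode

SMALL = NetConfig(
    pirna_len=7, mrna_len=9, n_filters=16, kernel_size=3,
    se_reduction=4, n_heads=4, ff_hidden=32,
)


def small_model(kind="full", seed=0):
    return PiRNATargetNet(SMALL, kind=kind, seed=seed)


def rand_seq(rng, n):
    return "".join(rng.choice(list("AUGC"), size=n))


# ---------------------------------------------------------------------------
# Brute-force oracles (independent loop implementations)
# ---------------------------------------------------------------------------

def oracle_conv(E, W, bn, alpha, k):
    """Same-length 1D conv by explicit double loop, then eval-mode batch
    norm and PReLU."""
    L, C = E.shape
    n_f = W.shape[1]
    m = (k - 1) // 2
    out = np.zeros((L, n_f))
    for n in range(n_f):
        K = W[:, n].reshape(k, C)  # kernel row q-j+m+1 (1-based), channel r
        for j in range(L):
            acc = 0.0
            for q in range(j - m, j + m + 1):
                if 0 <= q < L:
                    for r in range(C):
                        acc += K[q - j + m, r] * E[q, r]
            out[j, n] = acc
    scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    shift = bn.beta.data - bn.running_mean * scale
    out = out * scale + shift
    return np.where(out > 0, out, alpha * out)


def oracle_se(C, w1, b1, w2, b2):
    s = C.mean(axis=0)
    z = np.maximum(s @ w1 + b1, 0)
    e = 1.0 / (1.0 + np.exp(-(z @ w2 + b2)))
    return C * e[None, :]


def oracle_softmax_rows(x):
    out = np.zeros_like(x, dtype=float)
    for i in range(x.shape[0]):
        row = x[i] - x[i].max()
        ex = np.exp(row)
        out[i] = ex / ex.sum()
    return out


def oracle_attention_head(M, P, wq, wk, wv, d):
    Q, K, V = M @ wq, P @ wk, P @ wv
    W = oracle_softmax_rows(Q @ K.T / np.sqrt(d))
    return W @ V, W


def oracle_layer_norm(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * g + b


def oracle_prelu(x, alpha):
    return np.where(x > 0, x, alpha * x)


def oracle_residual_ff(H, M, p):
    K = H + M
    Kn = oracle_layer_norm(K, p["ln1_g"].data, p["ln1_b"].data)
    h = oracle_prelu(Kn @ p["ff_w1"].data + p["ff_b1"].data, p["prelu_ff1"].data)
    L = oracle_prelu(h @ p["ff_w2"].data + p["ff_b2"].data, p["prelu_ff2"].data)
    return oracle_layer_norm(Kn + L, p["ln2_g"].data, p["ln2_b"].data)


def oracle_classify(R, model):
    p = model.params

    def bn_eval(x, bn):
        scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
        return x * scale + (bn.beta.data - bn.running_mean * scale)

    h = R.reshape(-1) @ p["fc1_w"].data
    h = oracle_prelu(bn_eval(h, model.bn_fc["1"]), p["prelu_fc1"].data)
    h = h @ p["fc2_w"].data
    h = oracle_prelu(bn_eval(h, model.bn_fc["2"]), p["prelu_fc2"].data)
    logits = h @ p["fc3_w"].data + p["fc3_b"].data
    e = np.exp(logits - logits.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# Oracle-equivalence over random tensors
# ---------------------------------------------------------------------------

class TestEquationOracles:
    def test_all_components_match_oracles_on_random_tensors(self):
        """Conv, SE, attention head, multi-head, residual FF and classifier
        agree elementwise (<= 1e-6) with loop oracles on random tensors."""
        rng = np.random.default_rng(0)
        model = small_model()
        c = SMALL
        worst = 0.0
        for trial in range(100):
            E = rng.normal(scale=0.5, size=(c.mrna_len, 4)).astype(np.float32)
            got = model.conv_motif_extract(E, side="m")[0]
            want = oracle_conv(
                E, model.params["conv_m_w"].data, model.bn_conv["m"],
                model.params["prelu_conv_m"].data, c.kernel_size,
            )
            worst = max(worst, np.abs(got - want).max())

            C = rng.normal(scale=0.5, size=(c.mrna_len, c.n_filters)).astype(np.float32)
            got = model.se_block(C[None], side="m")[0]
            want = oracle_se(
                C, model.params["se_m_w1"].data, model.params["se_m_b1"].data,
                model.params["se_m_w2"].data, model.params["se_m_b2"].data,
            )
            worst = max(worst, np.abs(got - want).max())

            M = rng.normal(scale=0.5, size=(c.mrna_len, c.n_filters)).astype(np.float32)
            P = rng.normal(scale=0.5, size=(c.pirna_len, c.n_filters)).astype(np.float32)
            t = trial % c.n_heads
            got_h, got_w = model.attention_head(M[None], P[None], t)
            want_h, want_w = oracle_attention_head(
                M, P, model.params["attn_wq"].data[t],
                model.params["attn_wk"].data[t], model.params["attn_wv"].data[t],
                c.attn_scale_d,
            )
            worst = max(worst, np.abs(got_h[0] - want_h).max())
            worst = max(worst, np.abs(got_w[0] - want_w).max())

            got_H, _ = model.multi_head(M[None], P[None])
            concat = np.concatenate(
                [
                    oracle_attention_head(
                        M, P, model.params["attn_wq"].data[i],
                        model.params["attn_wk"].data[i],
                        model.params["attn_wv"].data[i], c.attn_scale_d,
                    )[0]
                    for i in range(c.n_heads)
                ],
                axis=-1,
            )
            worst = max(worst, np.abs(got_H[0] - concat @ model.params["attn_wh"].data).max())

            H = rng.normal(scale=0.5, size=(c.mrna_len, c.n_filters)).astype(np.float32)
            got = model.residual_ff(H[None], M[None])[0]
            worst = max(worst, np.abs(got - oracle_residual_ff(H, M, model.params)).max())

            R = rng.normal(scale=0.5, size=(c.mrna_len, c.n_filters)).astype(np.float32)
            got = model.classify(R[None])[0]
            worst = max(worst, np.abs(got - oracle_classify(R, model)).max())
        assert worst <= 1e-6, f"worst elementwise deviation {worst:.2e}"


class TestComponentContracts:
    def test_se_excitation_half_when_weights_zero(self):
        model = small_model()
        for nm in ("se_m_w1", "se_m_b1", "se_m_w2", "se_m_b2"):
            model.params[nm].data = np.zeros_like(model.params[nm].data)
        C = np.random.default_rng(1).normal(size=(1, 9, 16)).astype(np.float32)
        np.testing.assert_allclose(model.se_block(C, "m"), C / 2, atol=1e-7)

    def test_se_excitation_saturates_to_identity(self):
        model = small_model()
        model.params["se_m_w2"].data = np.zeros_like(model.params["se_m_w2"].data)
        model.params["se_m_b2"].data = np.full(16, 30.0, dtype=np.float32)
        C = np.random.default_rng(1).normal(size=(1, 9, 16)).astype(np.float32)
        np.testing.assert_allclose(model.se_block(C, "m"), C, atol=1e-6)

    def test_uniform_attention_for_identical_pirna_rows(self):
        model = small_model()
        rng = np.random.default_rng(2)
        M = rng.normal(size=(1, 9, 16)).astype(np.float32)
        P = np.tile(rng.normal(size=(1, 1, 16)).astype(np.float32), (1, 7, 1))
        _, W = model.attention_head(M, P, 0)
        np.testing.assert_allclose(W, 1.0 / 7, atol=1e-6)

    def test_zero_value_projection_zeroes_head(self):
        model = small_model()
        model.params["attn_wv"].data[:] = 0
        rng = np.random.default_rng(3)
        H, _ = model.attention_head(
            rng.normal(size=(1, 9, 16)).astype(np.float32),
            rng.normal(size=(1, 7, 16)).astype(np.float32), 0,
        )
        assert np.all(H == 0)

    def test_single_head_identity_mix_returns_head(self):
        cfg = NetConfig(pirna_len=7, mrna_len=9, n_filters=16, kernel_size=3,
                        n_heads=1, ff_hidden=32)
        model = PiRNATargetNet(cfg, seed=0)
        model.params["attn_wh"].data = np.eye(16, dtype=np.float32)
        rng = np.random.default_rng(4)
        M = rng.normal(size=(1, 9, 16)).astype(np.float32)
        P = rng.normal(size=(1, 7, 16)).astype(np.float32)
        H, _ = model.multi_head(M, P)
        H0, _ = model.attention_head(M, P, 0)
        np.testing.assert_allclose(H, H0, atol=1e-6)

    def test_residual_ff_pure_skip_path(self):
        model = small_model()
        for nm in ("ff_w1", "ff_b1", "ff_w2", "ff_b2"):
            model.params[nm].data = np.zeros_like(model.params[nm].data)
        rng = np.random.default_rng(5)
        H = rng.normal(size=(1, 9, 16)).astype(np.float32)
        M = rng.normal(size=(1, 9, 16)).astype(np.float32)
        R = model.residual_ff(H, M)
        Kn = oracle_layer_norm((H + M)[0], model.params["ln1_g"].data,
                               model.params["ln1_b"].data)
        want = oracle_layer_norm(Kn, model.params["ln2_g"].data,
                                 model.params["ln2_b"].data)
        np.testing.assert_allclose(R[0], want, atol=1e-6)

    def test_classifier_zero_final_layer_gives_uniform(self):
        model = small_model()
        model.params["fc3_w"].data[:] = 0
        model.params["fc3_b"].data[:] = 0
        R = np.random.default_rng(6).normal(size=(1, 9, 16)).astype(np.float32)
        np.testing.assert_allclose(model.classify(R), [[0.5, 0.5]], atol=1e-7)

    def test_extreme_logits_saturate(self):
        p = np.exp([10.0, -10.0])
        p = p / p.sum()
        assert p[0] > 1 - 1e-4

    def test_mismatched_shapes_rejected(self):
        model = small_model()
        with pytest.raises(ValueError):
            model.residual_ff(np.zeros((1, 9, 16)), np.zeros((1, 7, 16)))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 5, 4)), np.zeros((1, 9, 4)))
        with pytest.raises(ValueError):
            PiRNATargetNet(NetConfig(n_filters=30, n_heads=16))


class TestForward:
    def test_eval_determinism_and_probability_sum(self):
        rng = np.random.default_rng(7)
        for kind in ("full", "pure_cnn"):
            model = PiRNATargetNet(kind=kind, seed=1)
            pirna, mrna = rand_seq(rng, 21), rand_seq(rng, 31)
            pred1, _ = model.forward_pair(pirna, mrna)
            pred2, _ = model.forward_pair(pirna, mrna)
            assert pred1 == pred2  # bitwise identical in eval mode
            assert abs(pred1.p_negative + pred1.p_positive - 1) < 1e-6

    def test_attention_rows_are_distributions(self):
        rng = np.random.default_rng(8)
        model = PiRNATargetNet(seed=2)
        _, attn = model.forward_pair(rand_seq(rng, 21), rand_seq(rng, 31))
        sums = attn.per_head_weights.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-5)
        assert attn.per_head_weights.shape == (16, 31, 21)

    def test_random_init_predicts_near_half_on_balanced_batch(self):
        rng = np.random.default_rng(9)
        model = PiRNATargetNet(seed=3)
        p_oh = np.stack([one_hot_encode(rand_seq(rng, 21)) for _ in range(64)])
        m_oh = np.stack([one_hot_encode(rand_seq(rng, 31)) for _ in range(64)])
        probs = model.predict_proba(p_oh, m_oh)
        assert abs(probs[:, 1].mean() - 0.5) < 0.1

    @pytest.mark.parametrize("ext_l", [10, 15, 20])
    def test_shape_ledger_across_window_lengths(self, ext_l):
        cfg = NetConfig.for_extension(ext_l)
        L = 2 * ext_l + 1
        assert (cfg.fc1_width, cfg.fc2_width) == (32 * L, 8 * L)
        model = PiRNATargetNet(cfg, seed=0)
        rng = np.random.default_rng(ext_l)
        p_oh = one_hot_encode(rand_seq(rng, 21))[None]
        m_oh = one_hot_encode(rand_seq(rng, L))[None]
        logits, attn, hidden = model.forward(p_oh, m_oh, need_hidden=True)
        assert hidden["M"].shape == (1, L, 128)
        assert hidden["P"].shape == (1, 21, 128)
        assert attn.shape == (1, 16, L, 21)
        assert hidden["R"].shape == (1, L, 128)
        assert logits.shape == (1, 2)

    def test_pure_cnn_has_fewer_parameters_than_full(self):
        assert (
            PiRNATargetNet(kind="pure_cnn", seed=0).n_parameters()
            < PiRNATargetNet(kind="full", seed=0).n_parameters()
        )

    def test_gradient_flow_reaches_every_parameter(self):
        """One optimizer step on one batch changes every trainable tensor."""
        rng = np.random.default_rng(10)
        for kind in ("full", "pure_cnn"):
            model = small_model(kind=kind, seed=4)
            p_oh = np.stack([one_hot_encode(rand_seq(rng, 7)) for _ in range(64)])
            m_oh = np.stack([one_hot_encode(rand_seq(rng, 9)) for _ in range(64)])
            y = rng.integers(0, 2, size=64)
            before = {k: v.data.copy() for k, v in model.named_parameters().items()}
            opt = Adam(model.parameters(), lr=1e-2)
            logits, _, _ = model.forward(p_oh, m_oh, train=True, rng=rng)
            cross_entropy(logits, y).backward()
            opt.step()
            unchanged = [
                k for k, v in model.named_parameters().items()
                if np.array_equal(before[k], v.data)
            ]
            assert unchanged == [], f"{kind}: no gradient reached {unchanged}"


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    model = small_model(seed=5)
    pirna, mrna = rand_seq(rng, 7), rand_seq(rng, 9)
    pred, _ = model.forward_pair(pirna, mrna)
    path = tmp_path / "model.npz"
    model.save(path)
    back = PiRNATargetNet.load(path)
    assert back.cfg == model.cfg and back.kind == model.kind
    pred2, _ = back.forward_pair(pirna, mrna)
    assert pred == pred2
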
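"""The multi-head attention classifier for piRNA-mRNA pair discrimination.

Architecture (three sub-networks):

1. **Motif feature extraction** — each one-hot encoded sequence (piRNA
   21x4, mRNA window 31x4) passes through a same-length 1D convolution
   (128 kernels of width 5), batch normalization, PReLU, and a
   squeeze-and-excitation (SE) block with reduction factor 4 that gates
   channels by their globally pooled activation.  The outputs are the motif
   feature matrices ``P`` (21x128) and ``M`` (31x128).

2. **Multi-head attentive binding recognition** — 16 scaled dot-product
   attention heads with mRNA positions as queries and piRNA positions as
   keys/values.  The scale is ``sqrt(d)`` with ``d`` the piRNA length (21),
   not the head width — a deliberate property of this model.  Head outputs
   (width 8 each) are concatenated and mixed by ``W_H`` into ``H``
   (31x128), then ``K = H + M`` is layer-normalized and refined by a
   residual position-wise feed-forward block (128 -> 512 -> 128, PReLU)
   with a second residual add and layer normalization.

3. **Classification** — the 31x128 result is flattened and passed through
   two fully connected layers (widths 32*31 and 8*31, each with batch norm,
   PReLU and dropout 0.75 in training) and a final 2-unit linear + softmax.

The **pure-CNN ablation** removes the attention layer entirely (``K = M``);
the piRNA branch then enters the classifier as its position-averaged SE
features concatenated to the first hidden layer's output, keeping a
two-input classifier with strictly fewer parameters than the full model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Tensor,
    concat,
    dropout,
    layer_norm,
    log_softmax,
    prelu,
    softmax,
    unfold,
)
from .seq_core import NucleotideSequence, one_hot_encode

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetConfig:
    """Architecture dimensions.

    ``attn_scale_d`` defaults to the piRNA length; the classifier widths
    scale with the mRNA window length (32*L and 8*L).
    """

    pirna_len: int = 21
    mrna_len: int = 31
    n_filters: int = 128
    kernel_size: int = 5
    se_reduction: int = 4
    n_heads: int = 16
    ff_hidden: int = 128 * 4
    dropout_se: float = 0.3
    dropout_attn: float = 0.3
    dropout_cls: float = 0.75
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_filters % self.n_heads != 0:
            raise ValueError("n_filters must be divisible by n_heads")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-length convolution)")

    @property
    def head_dim(self) -> int:
        return self.n_filters // self.n_heads

    @property
    def attn_scale_d(self) -> int:
        return self.pirna_len

    @property
    def fc1_width(self) -> int:
        return 32 * self.mrna_len

    @property
    def fc2_width(self) -> int:
        return 8 * self.mrna_len

    @classmethod
    def for_extension(cls, extension_l: int, **kwargs) -> "NetConfig":
        return cls(mrna_len=2 * extension_l + 1, **kwargs)


@dataclass(frozen=True)
class Prediction:
    """Class probability pair (negative, positive)."""

    p_negative: float
    p_positive: float


@dataclass
class AttentionOutput:
    """Per-head attention weights plus the attended features of one pair."""

    per_head_weights: np.ndarray  # (n_heads, mrna_len, pirna_len), rows sum to 1
    H: np.ndarray  # (mrna_len, n_filters)
    R: np.ndarray  # (mrna_len, n_filters)


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class PiRNATargetNet:
    """The pair classifier; ``kind`` selects 'full' or the 'pure_cnn' ablation."""

    def __init__(self, cfg: "NetConfig | None" = None, kind: str = "full", seed: int = 0):
        if kind not in ("full", "pure_cnn"):
            raise ValueError("kind must be 'full' or 'pure_cnn'")
        self.cfg = cfg or NetConfig()
        self.kind = kind
        rng = np.random.default_rng(seed)
        c = self.cfg
        P: dict[str, Tensor] = {}

        kin = c.kernel_size * 4
        for side in ("p", "m"):
            # no conv bias: batch normalization directly follows and would
            # absorb any shift, leaving the bias without gradient
            P[f"conv_{side}_w"] = Tensor.param(_uniform(rng, kin, (kin, c.n_filters)))
            P[f"prelu_conv_{side}"] = Tensor.param(np.full(c.n_filters, 0.25))
            red = c.n_filters // c.se_reduction
            P[f"se_{side}_w1"] = Tensor.param(_uniform(rng, c.n_filters, (c.n_filters, red)))
            P[f"se_{side}_b1"] = Tensor.param(np.zeros(red))
            P[f"se_{side}_w2"] = Tensor.param(_uniform(rng, red, (red, c.n_filters)))
            P[f"se_{side}_b2"] = Tensor.param(np.zeros(c.n_filters))
        self.bn_conv = {
            "p": BatchNorm(c.n_filters),
            "m": BatchNorm(c.n_filters),
        }

        if kind == "full":
            hd = c.head_dim
            for nm in ("q", "k", "v"):
                P[f"attn_w{nm}"] = Tensor.param(
                    _uniform(rng, c.n_filters, (c.n_heads, c.n_filters, hd))
                )
            P["attn_wh"] = Tensor.param(_uniform(rng, c.n_filters, (c.n_filters, c.n_filters)))

        P["ln1_g"] = Tensor.param(np.ones(c.n_filters))
        P["ln1_b"] = Tensor.param(np.zeros(c.n_filters))
        P["ff_w1"] = Tensor.param(_uniform(rng, c.n_filters, (c.n_filters, c.ff_hidden)))
        P["ff_b1"] = Tensor.param(np.zeros(c.ff_hidden))
        P["prelu_ff1"] = Tensor.param(np.full(c.ff_hidden, 0.25))
        P["ff_w2"] = Tensor.param(_uniform(rng, c.ff_hidden, (c.ff_hidden, c.n_filters)))
        P["ff_b2"] = Tensor.param(np.zeros(c.n_filters))
        P["prelu_ff2"] = Tensor.param(np.full(c.n_filters, 0.25))
        P["ln2_g"] = Tensor.param(np.ones(c.n_filters))
        P["ln2_b"] = Tensor.param(np.zeros(c.n_filters))

        flat_in = c.mrna_len * c.n_filters
        fc2_in = c.fc1_width + (c.n_filters if kind == "pure_cnn" else 0)
        # fc1/fc2 carry no bias (each feeds straight into batch norm)
        P["fc1_w"] = Tensor.param(_uniform(rng, flat_in, (flat_in, c.fc1_width)))
        P["prelu_fc1"] = Tensor.param(np.full(c.fc1_width, 0.25))
        P["fc2_w"] = Tensor.param(_uniform(rng, fc2_in, (fc2_in, c.fc2_width)))
        P["prelu_fc2"] = Tensor.param(np.full(c.fc2_width, 0.25))
        P["fc3_w"] = Tensor.param(_uniform(rng, c.fc2_width, (c.fc2_width, c.n_classes)))
        P["fc3_b"] = Tensor.param(np.zeros(c.n_classes))
        self.bn_fc = {"1": BatchNorm(c.fc1_width), "2": BatchNorm(c.fc2_width)}
        self.params = P

    # -- parameter bookkeeping ----------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = list(self.params.values())
        for bn in (*self.bn_conv.values(), *self.bn_fc.values()):
            out.extend(bn.parameters())
        return out

    def named_parameters(self) -> dict[str, Tensor]:
        out = dict(self.params)
        for nm, bn in (("bn_conv_p", self.bn_conv["p"]), ("bn_conv_m", self.bn_conv["m"]),
                       ("bn_fc_1", self.bn_fc["1"]), ("bn_fc_2", self.bn_fc["2"])):
            out[f"{nm}_gamma"] = bn.gamma
            out[f"{nm}_beta"] = bn.beta
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward stages ------------------------------------------------------
    def _motif(self, E: Tensor, side: str, train: bool, rng) -> Tensor:
        c = self.cfg
        if E.shape[1] < c.kernel_size:
            raise ValueError("sequence shorter than the convolution kernel")
        cols = unfold(E, c.kernel_size, (c.kernel_size - 1) // 2)
        conv = cols @ self.params[f"conv_{side}_w"]
        conv = self.bn_conv[side](conv, train)
        conv = prelu(conv, self.params[f"prelu_conv_{side}"])
        F = self._se(conv, side)
        if train:
            F = dropout(F, c.dropout_se, rng, train)
        return F

    def _se(self, C: Tensor, side: str) -> Tensor:
        if C.shape[-1] != self.cfg.n_filters:
            raise ValueError("SE block expects n_filters channels")
        s = C.mean(axis=-2)  # squeeze: (B, n_filters)
        z = (s @ self.params[f"se_{side}_w1"] + self.params[f"se_{side}_b1"]).relu()
        e = (z @ self.params[f"se_{side}_w2"] + self.params[f"se_{side}_b2"]).sigmoid()
        B, nf = e.shape
        return C * e.reshape(B, 1, nf)

    def _attention(self, M: Tensor, P: Tensor) -> tuple[Tensor, np.ndarray]:
        c = self.cfg
        heads = []
        weights = []
        scale = 1.0 / np.sqrt(float(c.attn_scale_d))
        wq, wk, wv = (self.params[f"attn_w{n}"] for n in ("q", "k", "v"))
        for t in range(c.n_heads):
            Q = M @ Tensor(wq.data[t], parents=(wq,), backward=_slice_bw(wq, t))
            K = P @ Tensor(wk.data[t], parents=(wk,), backward=_slice_bw(wk, t))
            V = P @ Tensor(wv.data[t], parents=(wv,), backward=_slice_bw(wv, t))
            logits = (Q @ K.mT()) * scale
            W = softmax(logits, axis=-1)
            heads.append(W @ V)
            weights.append(W.data)
        H = concat(heads, axis=-1) @ self.params["attn_wh"]
        return H, np.stack(weights, axis=-3)  # (B, n_heads, mrna, pirna)

    def _residual_ff(self, K: Tensor, train: bool, rng) -> Tensor:
        P = self.params
        Kn = layer_norm(K, P["ln1_g"], P["ln1_b"])
        h = prelu(Kn @ P["ff_w1"] + P["ff_b1"], P["prelu_ff1"])
        if train:
            h = dropout(h, self.cfg.dropout_attn, rng, train)
        L = prelu(h @ P["ff_w2"] + P["ff_b2"], P["prelu_ff2"])
        return layer_norm(Kn + L, P["ln2_g"], P["ln2_b"])

    def _classify(self, R: Tensor, P_feat: "Tensor | None", train: bool, rng) -> Tensor:
        c = self.cfg
        P = self.params
        B = R.shape[0]
        flat = R.reshape(B, c.mrna_len * c.n_filters)
        h = flat @ P["fc1_w"]
        h = self.bn_fc["1"](h, train)
        h = prelu(h, P["prelu_fc1"])
        h = dropout(h, c.dropout_cls, rng, train)
        if self.kind == "pure_cnn":
            pooled = P_feat.mean(axis=-2)  # (B, n_filters) piRNA summary
            h = concat([h, pooled], axis=-1)
        h = h @ P["fc2_w"]
        h = self.bn_fc["2"](h, train)
        h = prelu(h, P["prelu_fc2"])
        h = dropout(h, c.dropout_cls, rng, train)
        return h @ P["fc3_w"] + P["fc3_b"]  # logits

    def forward(
        self,
        pirna_oh: np.ndarray,
        mrna_oh: np.ndarray,
        train: bool = False,
        rng: "np.random.Generator | None" = None,
        need_hidden: bool = False,
    ):
        """Batched forward pass on one-hot arrays (B, L, 4).

        Returns ``(logits Tensor, attn (B, n_heads, mrna, pirna) or None,
        hidden dict or None)``.  Eval mode is deterministic.
        """
        c = self.cfg
        pirna_oh = np.asarray(pirna_oh, dtype=np.float32)
        mrna_oh = np.asarray(mrna_oh, dtype=np.float32)
        if pirna_oh.shape[-2] != c.pirna_len or mrna_oh.shape[-2] != c.mrna_len:
            raise ValueError(
                f"expected lengths ({c.pirna_len}, {c.mrna_len}), got "
                f"({pirna_oh.shape[-2]}, {mrna_oh.shape[-2]})"
            )
        if train and rng is None:
            rng = np.random.default_rng(0)
        Pf = self._motif(Tensor(pirna_oh), "p", train, rng)
        Mf = self._motif(Tensor(mrna_oh), "m", train, rng)
        attn = None
        if self.kind == "full":
            H, attn = self._attention(Mf, Pf)
            if train:
                H = dropout(H, self.cfg.dropout_attn, rng, train)
            K = H + Mf
        else:
            H = None
            K = Mf
        R = self._residual_ff(K, train, rng)
        logits = self._classify(R, Pf if self.kind == "pure_cnn" else None, train, rng)
        hidden = None
        if need_hidden:
            hidden = {
                "P": Pf.data,
                "M": Mf.data,
                "H": H.data if H is not None else None,
                "R": R.data,
            }
        return logits, attn, hidden

    # -- user-facing inference ----------------------------------------------
    def forward_pair(
        self, pirna_seq, mrna_seq, mode: str = "eval"
    ) -> tuple[Prediction, "AttentionOutput | None"]:
        """Single-pair forward.  ``mode='eval'`` is deterministic."""
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        p_oh = one_hot_encode(pirna_seq)[None]
        m_oh = one_hot_encode(mrna_seq)[None]
        logits, attn, hidden = self.forward(
            p_oh, m_oh, train=(mode == "train"),
            rng=np.random.default_rng(0), need_hidden=True,
        )
        probs = softmax(logits).data[0]
        pred = Prediction(p_negative=float(probs[0]), p_positive=float(probs[1]))
        out = None
        if attn is not None:
            out = AttentionOutput(
                per_head_weights=attn[0], H=hidden["H"][0], R=hidden["R"][0]
            )
        return pred, out

    def predict_proba(
        self, pirna_oh: np.ndarray, mrna_oh: np.ndarray, batch_size: int = 512
    ) -> np.ndarray:
        """Eval-mode class probabilities, shape (N, 2)."""
        out = []
        for lo in range(0, len(pirna_oh), batch_size):
            logits, _, _ = self.forward(
                pirna_oh[lo : lo + batch_size], mrna_oh[lo : lo + batch_size]
            )
            out.append(softmax(logits).data)
        return np.concatenate(out, axis=0)

    # -- checkpointing -------------------------------------------------------
    def save(self, path: "str | Path") -> None:
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        for nm, bn in (("bn_conv_p", self.bn_conv["p"]), ("bn_conv_m", self.bn_conv["m"]),
                       ("bn_fc_1", self.bn_fc["1"]), ("bn_fc_2", self.bn_fc["2"])):
            arrays[f"param::{nm}_gamma"] = bn.gamma.data
            arrays[f"param::{nm}_beta"] = bn.beta.data
            arrays[f"state::{nm}_running_mean"] = bn.running_mean
            arrays[f"state::{nm}_running_var"] = bn.running_var
        meta = dict(version=CHECKPOINT_VERSION, kind=self.kind, config=asdict(self.cfg))
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: "str | Path") -> "PiRNATargetNet":
        with np.load(str(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            if "version" not in meta:
                raise ValueError("checkpoint missing version field")
            model = cls(NetConfig(**meta["config"]), kind=meta["kind"])
            for k in model.params:
                model.params[k].data = z[f"param::{k}"].astype(np.float32)
            for nm, bn in (("bn_conv_p", model.bn_conv["p"]),
                           ("bn_conv_m", model.bn_conv["m"]),
                           ("bn_fc_1", model.bn_fc["1"]),
                           ("bn_fc_2", model.bn_fc["2"])):
                bn.gamma.data = z[f"param::{nm}_gamma"].astype(np.float32)
                bn.beta.data = z[f"param::{nm}_beta"].astype(np.float32)
                bn.running_mean = z[f"state::{nm}_running_mean"].astype(np.float32)
                bn.running_var = z[f"state::{nm}_running_var"].astype(np.float32)
        return model

    # -- stage wrappers (eval mode, numpy in / numpy out) ---------------------
    def conv_motif_extract(self, E: np.ndarray, side: str = "m") -> np.ndarray:
        """Conv + batch-norm (running stats) + PReLU on a (B, L, 4) batch."""
        E = np.asarray(E, dtype=np.float32)
        if E.ndim == 2:
            E = E[None]
        cols = unfold(Tensor(E), self.cfg.kernel_size, (self.cfg.kernel_size - 1) // 2)
        conv = cols @ self.params[f"conv_{side}_w"]
        conv = self.bn_conv[side](conv, train=False)
        return prelu(conv, self.params[f"prelu_conv_{side}"]).data

    def se_block(self, C: np.ndarray, side: str = "m") -> np.ndarray:
        return self._se(Tensor(np.asarray(C, dtype=np.float32)), side).data

    def attention_head(self, M: np.ndarray, P: np.ndarray, t: int):
        """One head on (B, Lm, C) / (B, Lp, C) features: (H_t, weights_t)."""
        c = self.cfg
        if not 0 <= t < c.n_heads:
            raise ValueError("head index out of range")
        scale = 1.0 / np.sqrt(float(c.attn_scale_d))
        Q = np.asarray(M, np.float32) @ self.params["attn_wq"].data[t]
        K = np.asarray(P, np.float32) @ self.params["attn_wk"].data[t]
        V = np.asarray(P, np.float32) @ self.params["attn_wv"].data[t]
        logits = Q @ np.swapaxes(K, -1, -2) * scale
        W = softmax(Tensor(logits)).data
        return W @ V, W

    def multi_head(self, M: np.ndarray, P: np.ndarray):
        H, attn = self._attention(
            Tensor(np.asarray(M, np.float32)), Tensor(np.asarray(P, np.float32))
        )
        return H.data, attn

    def residual_ff(self, H: np.ndarray, M: np.ndarray) -> np.ndarray:
        if np.shape(H) != np.shape(M):
            raise ValueError("H and M must have identical shapes")
        K = Tensor(np.asarray(H, np.float32)) + Tensor(np.asarray(M, np.float32))
        return self._residual_ff(K, train=False, rng=None).data

    def classify(self, R: np.ndarray, P_feat: "np.ndarray | None" = None) -> np.ndarray:
        Pf = Tensor(np.asarray(P_feat, np.float32)) if P_feat is not None else None
        logits = self._classify(
            Tensor(np.asarray(R, np.float32)), Pf, train=False, rng=None
        )
        return softmax(logits).data


def _slice_bw(param: Tensor, t: int):
    def bw(g):
        if param.grad is None:
            param.grad = np.zeros_like(param.data)
        param.grad[t] += g

    return bw


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under the logits."""
    lp = log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape, dtype=np.float32)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(lp * Tensor(onehot)).sum() * (1.0 / len(labels))
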
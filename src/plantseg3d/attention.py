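"""Multi-head attention with exposed per-head features.

The per-head outputs F_sa^i are returned alongside the fused features
because the attention-separation loss consumes them directly: the training
objective penalises pairs of heads whose (flattened) feature matrices point
in similar directions, which keeps the heads attending to different regions
of the point cloud.

The block computes, for inputs X (queries) and Y (keys/values):

    S   = LayerNorm(X + Multihead(X, Y, Y))
    out = LayerNorm(S + FFN(S))

where Multihead concatenates the h scaled-dot-product heads and projects
with W^O.  Self-attention is the X = Y special case; cross attention fuses
two different token sets (local vs. global).  LayerNorm and the FFN can be
bypassed for analytic tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, layer_norm, softmax
from .errors import ConfigError, ValidationError
from .layers import MLP, Param

__all__ = ["AttentionConfig", "HeadFeatures", "AttentionOutput",
           "MultiHeadAttention", "attention_self", "attention_cross"]


@dataclass
class AttentionConfig:
    """Width parameters of one multi-head attention block."""

    h: int = 4
    d_m: int = 128
    d_k: int = 32
    d_v: int = 32
    ffn_hidden: int = 128
    use_layernorm: bool = True
    use_ffn: bool = True

    def __post_init__(self):
        if min(self.h, self.d_m, self.d_k, self.d_v) < 1:
            raise ConfigError("attention widths must be positive")


@dataclass
class HeadFeatures:
    """The h per-head output matrices F_sa^i, stacked as (h, T, d_v)."""

    stacked: Tensor

    @property
    def h(self) -> int:
        return self.stacked.shape[0]

    @property
    def per_head(self) -> list[Tensor]:
        return [self.stacked[i] for i in range(self.h)]


@dataclass
class AttentionOutput:
    features: Tensor            # (T_x, d_m)
    heads: HeadFeatures
    attn: np.ndarray = field(repr=False, default=None)  # (h, T_x, T_y) softmax rows


class MultiHeadAttention:
    """One attention block with learnable projections.

    Weight shapes: W^Q, W^K ∈ R^{h×d_m×d_k}, W^V ∈ R^{h×d_m×d_v},
    W^O ∈ R^{h·d_v×d_m}.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        s = 1.0 / np.sqrt(cfg.d_m)
        self.WQ = Param(rng, cfg.h, cfg.d_m, cfg.d_k, scale=s)
        self.WK = Param(rng, cfg.h, cfg.d_m, cfg.d_k, scale=s)
        self.WV = Param(rng, cfg.h, cfg.d_m, cfg.d_v, scale=s)
        self.WO = Param(rng, cfg.h * cfg.d_v, cfg.d_m,
                        scale=1.0 / np.sqrt(cfg.h * cfg.d_v))
        self.ln1_g = Tensor(np.ones(cfg.d_m), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(cfg.d_m), requires_grad=True)
        self.ln2_g = Tensor(np.ones(cfg.d_m), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(cfg.d_m), requires_grad=True)
        self.ffn = MLP(rng, [cfg.d_m, cfg.ffn_hidden, cfg.d_m])

    def named_parameters(self, prefix: str = ""):
        out = [(prefix + n, t) for n, t in
               [("WQ", self.WQ), ("WK", self.WK), ("WV", self.WV),
                ("WO", self.WO), ("ln1_g", self.ln1_g), ("ln1_b", self.ln1_b),
                ("ln2_g", self.ln2_g), ("ln2_b", self.ln2_b)]]
        out += [(f"{prefix}ffn.W{i}", w) for i, w in enumerate(self.ffn.W)]
        out += [(f"{prefix}ffn.b{i}", b) for i, b in enumerate(self.ffn.b)]
        return out

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def forward(self, X: Tensor, Y: Tensor) -> AttentionOutput:
        cfg = self.cfg
        if X.shape[-1] != cfg.d_m or Y.shape[-1] != cfg.d_m:
            raise ValidationError(
                f"token width {X.shape[-1]}/{Y.shape[-1]} != d_m={cfg.d_m}")
        Q = X @ self.WQ                       # (h, T_x, d_k)
        K = Y @ self.WK                       # (h, T_y, d_k)
        V = Y @ self.WV                       # (h, T_y, d_v)
        scores = (Q @ K.transpose(0, 2, 1)) * (1.0 / np.sqrt(cfg.d_k))
        P = softmax(scores, axis=-1)          # (h, T_x, T_y)
        F = P @ V                             # (h, T_x, d_v)
        heads = HeadFeatures(F)
        mh = F.transpose(1, 0, 2).reshape(X.shape[0], cfg.h * cfg.d_v) @ self.WO
        S = X + mh
        if cfg.use_layernorm:
            S = layer_norm(S, self.ln1_g, self.ln1_b)
        if cfg.use_ffn:
            out = S + self.ffn(S)
            if cfg.use_layernorm:
                out = layer_norm(out, self.ln2_g, self.ln2_b)
        else:
            out = S
        return AttentionOutput(out, heads, P.data)

    __call__ = forward


def attention_self(P: Tensor, module: MultiHeadAttention) -> AttentionOutput:
    """Self-attention over one token set: the X = Y case."""
    return module.forward(P, P)


def attention_cross(P: Tensor, Q: Tensor,
                    module: MultiHeadAttention) -> AttentionOutput:
    """Cross attention: tokens P attend over token set Q (local-global
    fusion and the detection head both use this form)."""
    return module.forward(P, Q)
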
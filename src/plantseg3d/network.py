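"""The organ-segmentation network.

Two branches digest a (centred, unit-radius) block of points:

* **global branch** — farthest-point sampling picks m well-spread centres;
  three concentric ball queries per centre (multi-scale grouping) produce
  position codes (RPC/APC) and pooled high-dimensional features that are
  concatenated across scales and refined by a self-attention stack.
* **local branch** — a learnable scoring MLP ranks every point; the top-k
  points anchor ball-query neighbourhoods whose position codes and pooled
  features (concatenated skip-style with the anchors' own features) become
  the local tokens.  Selection is hard top-k; gradients reach the score map
  because selected features are multiplied by their scores.

Before either branch runs, every point receives a feature that combines a
pointwise coordinate embedding with the position code of its own
ball-query neighbourhood, so per-point features carry local shape (tube /
plane / cluster) and not just position.

A local-global cross-attention layer lets local tokens read the global
context, and the detection head fuses them with a second cross attention
followed by a pointwise stack.  The fused token features are propagated
back to all n points (nearest anchor, or inverse-distance over the 3
nearest anchors) and a final pointwise classifier combines each point's own
feature with its upsampled token context to produce per-point class
scores.

Every attention block's per-head features are collected and returned so the
separation loss can act on all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .autodiff import Tensor, concat
from .attention import AttentionConfig, AttentionOutput, HeadFeatures, \
    MultiHeadAttention
from .cloud import N_CLASSES
from .errors import ConfigError, ValidationError
from .geometry import ball_query, farthest_point_sample, group_features
from .layers import MLP
from .position import encode_positions, masked_max_pool

__all__ = ["ModelConfig", "SegmentationLogits", "ForwardResult",
           "SegmentationModel"]


@dataclass
class ModelConfig:
    """Hyperparameters of the segmentation network.

    Radii are fractions of the normalised (unit) block radius.  The ablation
    flags ``use_rpc`` / ``use_apc`` remove the corresponding position-code
    branch everywhere while leaving the rest of the network intact.
    """

    n_points: int = 2048
    n_classes: int = N_CLASSES
    d_m: int = 128
    h: int = 4
    d_k: int = 32
    d_v: int = 32
    ffn_hidden: int = 128
    m_fps: int = 128
    k_local: int = 64
    radii: tuple = (0.1, 0.2, 0.4)
    radius_local: float = 0.2
    radius_point: float = 0.15
    k_max: int = 16
    rpc_hidden: int = 32
    c_r: int = 32
    c_a: int = 16
    highd_hidden: int = 32
    head_hidden: int = 64
    use_rpc: bool = True
    use_apc: bool = True
    include_center_in_rpc: bool = False
    shared_highd: bool = True
    upsample: str = "nearest"          # "nearest" | "interp3"
    fps_start: int = 0
    seed: int = 0

    def __post_init__(self):
        if len(self.radii) != 3:
            raise ConfigError(f"exactly 3 grouping radii required, got "
                              f"{len(self.radii)}")
        if len(set(self.radii)) != 3:
            raise ConfigError("grouping radii must be distinct")
        if self.upsample not in ("nearest", "interp3"):
            raise ConfigError(f"unknown upsample mode {self.upsample!r}")
        if self.m_fps > self.n_points or self.k_local > self.n_points:
            raise ConfigError("m_fps and k_local cannot exceed n_points")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radii"] = list(self.radii)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["radii"] = tuple(d["radii"])
        return cls(**d)


@dataclass
class SegmentationLogits:
    """Unnormalised per-point class scores, one row per input point."""

    scores: Tensor   # (N, n_classes)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.scores.data, axis=1)


@dataclass
class ForwardResult:
    logits: SegmentationLogits
    head_features: list[HeadFeatures]       # one entry per Div-attention module
    aux: dict = field(default_factory=dict)


class SegmentationModel:
    """Two-branch attention segmentation network (see module docstring)."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        cfg = config
        rpc_in = 6 if cfg.include_center_in_rpc else 3
        attn_cfg = AttentionConfig(h=cfg.h, d_m=cfg.d_m, d_k=cfg.d_k,
                                   d_v=cfg.d_v, ffn_hidden=cfg.ffn_hidden)
        self.attn_cfg = attn_cfg

        pc_width = (cfg.c_r if cfg.use_rpc else 0) + (cfg.c_a if cfg.use_apc else 0)

        self.highd = MLP(rng, [3, cfg.highd_hidden, cfg.d_m], final_relu=True)
        self.theta_rpc_p = MLP(rng, [rpc_in, cfg.rpc_hidden, cfg.c_r])
        self.theta_apc_p = MLP(rng, [3, cfg.rpc_hidden, cfg.c_a])
        self.point_fuse = MLP(rng, [cfg.d_m + pc_width, cfg.d_m],
                              final_relu=True)
        self.scale_highd = None
        if not cfg.shared_highd:
            self.scale_highd = [
                MLP(rng, [3, cfg.highd_hidden, cfg.d_m], final_relu=True)
                for _ in cfg.radii]

        self.theta_rpc_g = [MLP(rng, [rpc_in, cfg.rpc_hidden, cfg.c_r])
                            for _ in cfg.radii]
        self.theta_apc_g = [MLP(rng, [3, cfg.rpc_hidden, cfg.c_a])
                            for _ in cfg.radii]
        self.scale_mlp = [MLP(rng, [pc_width + cfg.d_m, cfg.d_m])
                          for _ in cfg.radii]
        self.fuse_mlp = MLP(rng, [3 * cfg.d_m, cfg.d_m])
        self.attn_self = MultiHeadAttention(attn_cfg, rng)    # Div self-attention

        self.score_mlp = MLP(rng, [cfg.d_m, 32, 1])
        self.theta_rpc_l = MLP(rng, [rpc_in, cfg.rpc_hidden, cfg.c_r])
        self.theta_apc_l = MLP(rng, [3, cfg.rpc_hidden, cfg.c_a])
        self.local_mlp = MLP(rng, [cfg.d_m + pc_width + cfg.d_m, cfg.d_m])
        self.attn_lg = MultiHeadAttention(attn_cfg, rng)      # Div local-global
        self.attn_cross = MultiHeadAttention(attn_cfg, rng)   # Div cross (head)
        self.head_mlp = MLP(rng, [cfg.d_m, cfg.d_m])          # pointwise stack
        self.point_head = MLP(rng, [2 * cfg.d_m, cfg.head_hidden,
                                    cfg.n_classes])

    # -- parameter plumbing ----------------------------------------------
    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def add_mlp(name, mlp):
            out.extend((f"{name}.W{i}", w) for i, w in enumerate(mlp.W))
            out.extend((f"{name}.b{i}", b) for i, b in enumerate(mlp.b))

        add_mlp("highd", self.highd)
        add_mlp("theta_rpc_p", self.theta_rpc_p)
        add_mlp("theta_apc_p", self.theta_apc_p)
        add_mlp("point_fuse", self.point_fuse)
        if self.scale_highd is not None:
            for s, m in enumerate(self.scale_highd):
                add_mlp(f"scale_highd{s}", m)
        for s in range(3):
            add_mlp(f"theta_rpc_g{s}", self.theta_rpc_g[s])
            add_mlp(f"theta_apc_g{s}", self.theta_apc_g[s])
            add_mlp(f"scale_mlp{s}", self.scale_mlp[s])
        add_mlp("fuse_mlp", self.fuse_mlp)
        out.extend(self.attn_self.named_parameters("attn_self."))
        add_mlp("score_mlp", self.score_mlp)
        add_mlp("theta_rpc_l", self.theta_rpc_l)
        add_mlp("theta_apc_l", self.theta_apc_l)
        add_mlp("local_mlp", self.local_mlp)
        out.extend(self.attn_lg.named_parameters("attn_lg."))
        out.extend(self.attn_cross.named_parameters("attn_cross."))
        add_mlp("head_mlp", self.head_mlp)
        add_mlp("point_head", self.point_head)
        return out

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: t.data.copy() for n, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for n, t in self.named_parameters():
            if n not in state:
                raise ConfigError(f"checkpoint missing parameter {n!r}")
            if state[n].shape != t.data.shape:
                raise ConfigError(f"checkpoint shape mismatch for {n!r}")
            t.data = np.array(state[n], dtype=np.float64)

    # -- branch forwards ---------------------------------------------------
    def _position_parts(self, coords, nbr, theta_rpc, theta_apc):
        cfg = self.config
        parts = []
        if cfg.use_rpc or cfg.use_apc:
            pc = encode_positions(coords, nbr, theta_rpc, theta_apc,
                                  include_center_in_rpc=cfg.include_center_in_rpc)
            if cfg.use_rpc:
                parts.append(pc.rpc_features)
            if cfg.use_apc:
                parts.append(pc.apc_features)
        return parts

    def extract_point_features(self, coords: np.ndarray) -> Tensor:
        """Per-point features: coordinate embedding fused with the position
        code of each point's own neighbourhood (N, d_m)."""
        cfg = self.config
        h0 = self.highd(Tensor(coords))
        nbr = ball_query(coords, np.arange(coords.shape[0]),
                         cfg.radius_point, cfg.k_max)
        parts = [h0] + self._position_parts(coords, nbr, self.theta_rpc_p,
                                            self.theta_apc_p)
        if len(parts) == 1:
            return h0
        return self.point_fuse(concat(parts, axis=1))

    def pc_msg_forward(self, coords: np.ndarray, highd: Tensor):
        """Multi-scale global branch: returns (centre indices, global tokens,
        self-attention output)."""
        cfg = self.config
        centers = farthest_point_sample(coords, cfg.m_fps, cfg.fps_start)
        scale_feats = []
        for s, radius in enumerate(cfg.radii):
            nbr = ball_query(coords, centers, radius, cfg.k_max)
            parts = self._position_parts(coords, nbr, self.theta_rpc_g[s],
                                         self.theta_apc_g[s])
            if self.scale_highd is not None:
                h_s = self.scale_highd[s](Tensor(coords))
            else:
                h_s = highd
            parts.append(masked_max_pool(group_features(h_s, nbr),
                                         nbr.valid_mask))
            scale_feats.append(self.scale_mlp[s](concat(parts, axis=1)))
        tokens = self.fuse_mlp(concat(scale_feats, axis=1))
        out = self.attn_self(tokens, tokens)
        return centers, out

    def pc_sortnet_forward(self, coords: np.ndarray, highd: Tensor):
        """Score-and-select local branch: returns (selected indices, scores,
        local tokens)."""
        cfg = self.config
        n = coords.shape[0]
        if cfg.k_local > n:
            raise ValidationError(f"k_local={cfg.k_local} exceeds N={n}")
        scores = self.score_mlp(highd)                     # (N, 1)
        order = np.argsort(-scores.data[:, 0], kind="stable")
        selected = order[:cfg.k_local]
        # hard selection; scores stay on the gradient path multiplicatively
        sel_feats = highd[selected] * scores[selected]
        nbr = ball_query(coords, selected, cfg.radius_local, cfg.k_max)
        parts = [sel_feats]
        parts += self._position_parts(coords, nbr, self.theta_rpc_l,
                                      self.theta_apc_l)
        parts.append(masked_max_pool(group_features(highd, nbr),
                                     nbr.valid_mask))
        tokens = self.local_mlp(concat(parts, axis=1))
        return selected, scores, tokens

    def detection_head(self, local_tokens: Tensor,
                       global_tokens: Tensor) -> tuple[Tensor, AttentionOutput]:
        """Fuse local and global tokens; returns (per-token fused features
        after the pointwise stack, the cross-attention output with its
        heads)."""
        out = self.attn_cross(local_tokens, global_tokens)
        return self.head_mlp(out.features).relu(), out

    def _upsample(self, coords: np.ndarray, anchors: np.ndarray,
                  token_feats: Tensor) -> Tensor:
        """Propagate per-token features to all points: nearest anchor or
        inverse-distance over the 3 nearest anchors."""
        d = cdist(coords, coords[anchors])
        if self.config.upsample == "nearest":
            nn = np.argmin(d, axis=1)       # first (lowest index) on ties
            return token_feats[nn]
        k = min(3, len(anchors))
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]          # (N, k)
        w = 1.0 / (np.take_along_axis(d, nn, axis=1) + 1e-8)
        w = w / w.sum(axis=1, keepdims=True)                      # (N, k)
        gathered = token_feats[nn.reshape(-1)] \
            .reshape(coords.shape[0], k, token_feats.shape[1])
        return (gathered * Tensor(w[:, :, None])).sum(axis=1)

    def forward(self, coords: np.ndarray) -> ForwardResult:
        """Run the full network on a centred block of exactly
        ``config.n_points`` points."""
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (self.config.n_points, 3):
            raise ValidationError(
                f"expected ({self.config.n_points}, 3) coords, got {coords.shape}")
        highd = self.extract_point_features(coords)
        centers, g_out = self.pc_msg_forward(coords, highd)
        selected, scores, local_tokens = self.pc_sortnet_forward(coords, highd)
        lg_out = self.attn_lg(local_tokens, g_out.features)
        token_feats, cross_out = self.detection_head(lg_out.features,
                                                     g_out.features)
        up = self._upsample(coords, selected, token_feats)
        logits = self.point_head(concat([highd, up], axis=1))
        return ForwardResult(
            SegmentationLogits(logits),
            [g_out.heads, lg_out.heads, cross_out.heads],
            aux={"centers": centers, "selected": selected,
                 "scores": scores.data[:, 0].copy(),
                 "token_features": token_feats,
                 "attn": {"self": g_out.attn, "lg": lg_out.attn,
                          "cross": cross_out.attn}})

    __call__ = forward
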
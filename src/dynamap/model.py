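"""Spatiotemporal vision-transformer for dense prediction of dynamic maps.

The network maps a preprocessed 4D scan (h, w, d, t) to per-network 4D
weight maps (n_networks, h, w, d, t):

1. each frame is cut into non-overlapping ps^3 cubes, linearly projected
   to an embedding of size e, and a learnable positional embedding of
   shape (t, p, e) is added;
2. a transformer encoder refines the tokens, in one of two configurations:
   * ``space_time`` — all t*p tokens attend to each other jointly;
   * ``sequential`` — temporal attention per spatial location, then
     spatial attention per frame;
3. a decoder head (layer norm, affine projection, fixed sine-cosine time
   encoding, three depth-wise transposed 3D convolutions with kernel sizes
   7/5/9 — the middle one carrying the x ps upsampling, the last with
   dilation 2 — and a point-wise projection with randomized leaky ReLU)
   renders each frame back onto the voxel grid.

Attention uses pre-norm residual blocks; the softmax logits are scaled by
sqrt(per-head dim). Non-divisible volumes are zero-padded at the high end
of each axis before tokenization and center-cropped on output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

DTYPE = np.float32

__all__ = [
    "ModelConfig",
    "TokenSequence",
    "DynamicMap",
    "SpatioTemporalModel",
    "RRELU_LOWER",
    "RRELU_UPPER",
]

RRELU_LOWER = 1.0 / 8.0
RRELU_UPPER = 1.0 / 3.0


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults: full-scale configuration)."""

    patch_size: int = 5
    embed_dim: int = 96
    n_heads: int = 6
    depth: int = 1
    attn_dropout: float = 0.4
    encoder_dropout: float = 0.3
    encoder_mode: str = "space_time"       # or "sequential"
    n_networks: int = 1
    mlp_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.encoder_mode not in ("space_time", "sequential"):
            raise ValueError("encoder_mode must be space_time or sequential")
        for r in (self.attn_dropout, self.encoder_dropout):
            if not (0 <= r < 1):
                raise ValueError("dropout rates must be in [0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "patch_size", "embed_dim", "n_heads", "depth", "attn_dropout",
            "encoder_dropout", "encoder_mode", "n_networks", "mlp_ratio",
            "seed")}


@dataclass
class TokenSequence:
    """Patch tokens (t, p, e) plus the grid they came from."""

    tokens: Tensor
    grid_shape: tuple[int, int, int]
    spatial_shape: tuple[int, int, int]    # original, pre-padding


@dataclass
class DynamicMap:
    """Model output: per-network, per-voxel, per-frame weights."""

    data: np.ndarray                       # (n_networks, h, w, d, t)
    subject_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in dynamic map")


# ---------------------------------------------------------------------------
# parameter containers


class Module:
    def parameters(self) -> list[tuple[str, Tensor]]:
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{n}", p) for n, p in val.parameters())
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{n}", p)
                            for n, p in item.parameters()
                        )
        return out


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(
            rng.normal(0, scale, (n_in, n_out)).astype(DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class MultiHeadSelfAttention(Module):
    """Softmax(Q K^T / sqrt(e_head)) V over the second-to-last axis.

    Input (..., N, e); leading axes are independent batches. The attention
    probability tensor of the most recent call is kept on
    ``last_attention`` for inspection.
    """

    def __init__(self, embed_dim: int, n_heads: int, attn_dropout: float,
                 rng: np.random.Generator):
        self.q = Linear(embed_dim, embed_dim, rng)
        self.k = Linear(embed_dim, embed_dim, rng)
        self.v = Linear(embed_dim, embed_dim, rng)
        self.out = Linear(embed_dim, embed_dim, rng)
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.attn_dropout = attn_dropout
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        *batch, N, e = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            t = t.reshape(*batch, N, H, hd)
            axes = tuple(range(len(batch))) + (
                len(batch) + 1, len(batch), len(batch) + 2)
            return t.transpose(axes)       # (..., H, N, hd)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        kt_axes = tuple(range(q.ndim - 2)) + (q.ndim - 1, q.ndim - 2)
        scores = (q @ k.transpose(kt_axes)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        attn = attn.dropout(self.attn_dropout, rng)
        ctx = attn @ v                       # (..., H, N, hd)
        axes = tuple(range(len(batch))) + (
            len(batch) + 1, len(batch), len(batch) + 2)
        ctx = ctx.transpose(axes).reshape(*batch, N, e)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm MHSA + residual, then pre-norm MLP + residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        e = cfg.embed_dim
        hidden = int(e * cfg.mlp_ratio)
        self.ln1 = LayerNorm(e)
        self.attn = MultiHeadSelfAttention(e, cfg.n_heads, cfg.attn_dropout,
                                           rng)
        self.ln2 = LayerNorm(e)
        self.fc1 = Linear(e, hidden, rng)
        self.fc2 = Linear(hidden, e, rng)
        self.dropout = cfg.encoder_dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        x = self.attn(self.ln1(x), rng) + x
        h = self.fc1(self.ln2(x))
        h = h.rrelu(RRELU_LOWER, RRELU_UPPER, rng)
        h = h.dropout(self.dropout, rng)
        h = self.fc2(h)
        h = h.dropout(self.dropout, rng)
        return h + x


# ---------------------------------------------------------------------------


def _padded_shape(shape, ps):
    return tuple(-(-s // ps) * ps for s in shape)


def _sincos_time_encoding(t_index: int, dim: int) -> np.ndarray:
    """Fixed sine-cosine encoding of a frame index."""
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    ang = t_index * freqs
    enc = np.zeros(dim)
    enc[0:2 * half:2] = np.sin(ang)
    enc[1:2 * half:2] = np.cos(ang)
    return enc


class PatchEmbed(Module):
    def __init__(self, cfg: ModelConfig, spatial_shape, n_timepoints,
                 rng: np.random.Generator):
        ps = cfg.patch_size
        self.ps = ps
        self.spatial_shape = tuple(spatial_shape)
        self.padded = _padded_shape(spatial_shape, ps)
        self.grid = tuple(s // ps for s in self.padded)
        self.n_patches = int(np.prod(self.grid))
        self.t = n_timepoints
        self.proj = Linear(ps**3, cfg.embed_dim, rng)
        self.pos_embed = Tensor(
            rng.normal(0, 0.02, (n_timepoints, self.n_patches,
                                 cfg.embed_dim)).astype(DTYPE),
            requires_grad=True,
        )

    def __call__(self, data: np.ndarray) -> TokenSequence:
        data = np.asarray(data, dtype=DTYPE)
        h, w, d, t = data.shape
        if (h, w, d) != self.spatial_shape or t != self.t:
            raise ValueError("input shape differs from model construction")
        ph, pw, pd = self.padded
        pad = np.zeros((ph, pw, pd, t), dtype=DTYPE)
        pad[:h, :w, :d, :] = data
        ps = self.ps
        gh, gw, gd = self.grid
        # (t, p, ps^3): patches in row-major grid order
        cubes = pad.transpose(3, 0, 1, 2).reshape(
            t, gh, ps, gw, ps, gd, ps
        ).transpose(0, 1, 3, 5, 2, 4, 6).reshape(t, self.n_patches, ps**3)
        tokens = self.proj(Tensor(cubes)) + self.pos_embed
        return TokenSequence(tokens=tokens, grid_shape=self.grid,
                             spatial_shape=self.spatial_shape)


class Decoder(Module):
    """Token-to-volume head shared across frames."""

    KERNELS = (7, 5, 9)

    def __init__(self, cfg: ModelConfig, grid, spatial_shape,
                 rng: np.random.Generator):
        e = cfg.embed_dim
        ps = cfg.patch_size
        self.grid = tuple(grid)
        self.spatial_shape = tuple(spatial_shape)
        self.padded = tuple(g * ps for g in grid)
        self.ps = ps
        self.ln = LayerNorm(e)
        self.fc = Linear(e, e, rng)
        k1, k2, k3 = self.KERNELS
        def dw_weight(k):
            w = rng.normal(0, 1.0 / k**1.5, (e, k, k, k))
            w[:, k // 2, k // 2, k // 2] += 1.0   # near-identity start
            return Tensor(w.astype(DTYPE), requires_grad=True)
        self.conv1 = dw_weight(k1)
        self.conv2 = dw_weight(k2)
        self.conv3 = dw_weight(k3)
        self.point = Tensor(
            rng.normal(0, np.sqrt(2.0 / e), (e, cfg.n_networks)).astype(DTYPE),
            requires_grad=True,
        )
        self.point_bias = Tensor(np.zeros(cfg.n_networks, dtype=DTYPE),
                                 requires_grad=True)
        # interior crops keeping each layer size-exact:
        #   L1 (k7, s1): size-preserving crop 3+3
        #   L2 (k5, stride ps): raw (g-1)*ps+5 adjusted to exactly g*ps
        #   L3 (k9, dil2, s1): size-preserving crop 8+8
        self.crop1 = tuple((3, 3) for _ in range(3))
        crops2 = []
        for g, target in zip(self.grid, self.padded):
            raw = (g - 1) * ps + k2
            excess = raw - target
            crops2.append((excess // 2, excess - excess // 2))
        self.crop2 = tuple(crops2)
        self.crop3 = tuple((8, 8) for _ in range(3))

    def __call__(self, seq: TokenSequence,
                 rng: np.random.Generator | None) -> Tensor:
        t, p, e = seq.tokens.shape
        x = self.fc(self.ln(seq.tokens))
        enc = np.stack([_sincos_time_encoding(k, e)
                        for k in range(t)]).astype(x.data.dtype)
        x = x + Tensor(enc[:, None, :])
        gh, gw, gd = self.grid
        # (t, p, e) -> (t, e, gh, gw, gd)
        x = x.reshape(t, gh, gw, gd, e).transpose(0, 4, 1, 2, 3)
        x = x.dwconvt3d(self.conv1, stride=1, dilation=1, crop=self.crop1)
        x = x.dwconvt3d(self.conv2, stride=self.ps, dilation=1,
                        crop=self.crop2)
        x = x.dwconvt3d(self.conv3, stride=1, dilation=2, crop=self.crop3)
        # point-wise projection to network channels + RReLU
        ph, pw, pd = self.padded
        x = x.transpose(0, 2, 3, 4, 1).reshape(t * ph * pw * pd, e)
        x = (x @ self.point + self.point_bias).rrelu(
            RRELU_LOWER, RRELU_UPPER, rng
        )
        n_nets = self.point.shape[1]
        x = x.reshape(t, ph, pw, pd, n_nets).transpose(4, 1, 2, 3, 0)
        # symmetric center-crop of the zero-padding back to (h, w, d)
        sl = [slice(None)]
        for full, orig in zip(self.padded, self.spatial_shape):
            lo = (full - orig) // 2
            sl.append(slice(lo, lo + orig))
        sl.append(slice(None))
        return x[tuple(sl)]


class SpatioTemporalModel(Module):
    """Patch embedding + encoder (either configuration) + decoder."""

    def __init__(self, cfg: ModelConfig, spatial_shape, n_timepoints):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.patch_embed = PatchEmbed(cfg, spatial_shape, n_timepoints, rng)
        if cfg.encoder_mode == "space_time":
            self.blocks = [TransformerBlock(cfg, rng)
                           for _ in range(cfg.depth)]
        else:
            self.temporal_blocks = [TransformerBlock(cfg, rng)
                                    for _ in range(cfg.depth)]
            self.spatial_blocks = [TransformerBlock(cfg, rng)
                                   for _ in range(cfg.depth)]
        self.decoder = Decoder(cfg, self.patch_embed.grid, spatial_shape,
                               rng)

    # -- encoding -------------------------------------------------------------
    def encode(self, seq: TokenSequence,
               rng: np.random.Generator | None) -> TokenSequence:
        t, p, e = seq.tokens.shape
        if self.cfg.encoder_mode == "space_time":
            x = seq.tokens.reshape(t * p, e)
            for blk in self.blocks:
                x = blk(x, rng)
            tokens = x.reshape(t, p, e)
        else:
            # stage 1: temporal attention at each spatial location
            x = seq.tokens.transpose(1, 0, 2)      # (p, t, e)
            for blk in self.temporal_blocks:
                x = blk(x, rng)
            # stage 2: spatial attention within each frame
            x = x.transpose(1, 0, 2)               # (t, p, e)
            for blk in self.spatial_blocks:
                x = blk(x, rng)
            tokens = x
        return TokenSequence(tokens=tokens, grid_shape=seq.grid_shape,
                             spatial_shape=seq.spatial_shape)

    # -- full forward ---------------------------------------------------------
    def forward(self, data: np.ndarray,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predicted maps as a Tensor (n_networks, h, w, d, t).

        Pass a Generator to enable dropout/RReLU sampling (training mode);
        rng=None runs in deterministic evaluation mode.
        """
        seq = self.patch_embed(data)
        seq = self.encode(seq, rng)
        return self.decoder(seq, rng)

    def predict(self, data: np.ndarray, subject_id: str = "") -> DynamicMap:
        out = self.forward(data, rng=None)
        return DynamicMap(data=out.data, subject_id=subject_id)
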
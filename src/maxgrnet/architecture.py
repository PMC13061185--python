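"""MaxGRNet: a multi-axis vision transformer with a GRN-MLP feed-forward.

The network follows the hierarchical MaxViT design: a convolutional stem,
four stages S1-S4 whose basic block is MBConv -> block (window) attention ->
grid (dilated) attention, global average pooling and a linear head.  The
single architectural delta is the transformer MLP: between the expansion
nonlinearity and the projection, channel responses are recalibrated by
Global Response Normalization (GRN) — each channel's spatial L2 norm is
divided by the cross-channel mean of those norms and the input is rescaled
by the result.  With the learnable GRN scale/offset at their zero
initialization the block reduces exactly to a plain MaxViT-style block,
which is the comparison switch (``grn_enabled``) used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autodiff import Tensor, gather
from .errors import ConfigurationError, ShapeError, ValidationError
from . import nn
from .nn import Module, Parameter


# ----------------------------------------------------------------------
@dataclass
class ModelConfig:
    """Every architectural hyperparameter of a MaxGRNet instance.

    Defaults follow the MaxViT-T design the GRN variant modifies: stage
    depths (2, 2, 5, 2), widths (64, 128, 256, 512), stem 64, partition 7,
    MLP expansion 4, SE reduction 0.25, 32-wide attention heads.
    """

    num_classes: int = 4
    input_size: int = 224
    stem_channels: int = 64
    stage_depths: tuple[int, ...] = (2, 2, 5, 2)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    partition_size: int = 7
    mlp_expansion: float = 4.0
    se_ratio: float = 0.25
    head_dim: int = 32
    grn_enabled: bool = True
    grn_eps: float = 1e-6
    grn_frozen: bool = False          # freeze gamma/beta at zero (parameter-free GRN)
    grn_scope: str = "full"           # "full": L2 over the whole map; "window": per window

    def __post_init__(self):
        self.stage_depths = tuple(int(d) for d in self.stage_depths)
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.validate()

    def validate(self) -> None:
        if len(self.stage_depths) != 4 or len(self.stage_channels) != 4:
            raise ConfigurationError("stage_depths and stage_channels must have length 4 (S1-S4)")
        counts = (self.num_classes, self.input_size, self.stem_channels,
                  self.partition_size, self.head_dim, *self.stage_depths,
                  *self.stage_channels)
        if any(v <= 0 for v in counts):
            raise ConfigurationError("all architectural counts must be positive")
        if self.mlp_expansion <= 0 or not (0 < self.se_ratio <= 1) or self.grn_eps <= 0:
            raise ConfigurationError("mlp_expansion, se_ratio and grn_eps must be positive")
        if self.grn_scope not in ("full", "window"):
            raise ConfigurationError(f"unknown grn_scope {self.grn_scope!r}")
        for i, c in enumerate(self.stage_channels):
            if c % self.head_dim:
                raise ConfigurationError(
                    f"stage {i + 1} width {c} not divisible by head_dim {self.head_dim}")
        for i, r in enumerate(self.stage_resolutions()):
            if r < self.partition_size or r % self.partition_size:
                raise ConfigurationError(
                    f"stage {i + 1} resolution {r} not divisible by partition size "
                    f"{self.partition_size} (input_size {self.input_size})")

    def stage_resolutions(self) -> tuple[int, ...]:
        # stem halves the input; each stage downsamples once at entry
        return tuple(self.input_size // 2 ** (i + 2) for i in range(4))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": asdict(self)}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw["model"])

    @classmethod
    def tiny(cls, num_classes: int = 4, grn_enabled: bool = True, **kw) -> "ModelConfig":
        """A <0.2M-parameter configuration for CPU-scale experiments."""
        defaults = dict(num_classes=num_classes, input_size=64, stem_channels=8,
                        stage_depths=(1, 1, 1, 1), stage_channels=(8, 16, 32, 64),
                        partition_size=2, mlp_expansion=2.0, se_ratio=0.25,
                        head_dim=8, grn_enabled=grn_enabled)
        defaults.update(kw)
        return cls(**defaults)


# ----------------------------------------------------------------------
# GRN
@dataclass
class GRNParams:
    """Per-channel learnable scale (gamma) and offset (beta) of GRN."""

    gamma: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.float32).ravel()
        self.beta = np.asarray(self.beta, dtype=np.float32).ravel()
        if self.gamma.shape != self.beta.shape:
            raise ConfigurationError("gamma and beta must have equal length")
        if not (np.isfinite(self.gamma).all() and np.isfinite(self.beta).all()):
            raise ValidationError("GRN parameters must be finite")


def grn_apply(x: Tensor, params: GRNParams, eps: float = 1e-6) -> Tensor:
    """Global response normalization on an NCHW feature map (residual form).

    Per sample: g_c = ||x_c||_2 over space; n_c = g_c / (mean_c g + eps);
    output = gamma_c * (x * n_c) + beta_c + x.
    """
    if x.ndim != 4:
        raise ShapeError(f"expected NCHW input, got {x.ndim} axes")
    c = x.shape[1]
    if params.gamma.size != c:
        raise ConfigurationError(f"GRN params have length {params.gamma.size}, input has {c} channels")
    if not np.isfinite(x.data).all():
        raise ValidationError("non-finite values in GRN input")
    g = (x * x).sum(axis=(2, 3), keepdims=True).sqrt()          # (N, C, 1, 1)
    n = g / (g.mean(axis=1, keepdims=True) + eps)
    gamma = params.gamma.reshape(1, -1, 1, 1)
    beta = params.beta.reshape(1, -1, 1, 1)
    return Tensor(gamma) * (x * n) + Tensor(beta) + x


class GRN(Module):
    def __init__(self, dim: int, eps: float = 1e-6, frozen: bool = False):
        self.gamma = Parameter(np.zeros(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self.frozen = frozen

    def named_parameters(self, prefix: str = ""):
        if self.frozen:
            return []
        return super().named_parameters(prefix)

    def forward(self, x: Tensor) -> Tensor:
        g = (x * x).sum(axis=(2, 3), keepdims=True).sqrt()
        n = g / (g.mean(axis=1, keepdims=True) + self.eps)
        return self.gamma.reshape(1, -1, 1, 1) * (x * n) + self.beta.reshape(1, -1, 1, 1) + x


class GRNMLP(Module):
    """Transformer feed-forward: expand -> GELU -> GRN -> project.

    Operates on token arrays (..., T, C); the GRN step reshapes tokens to
    their (gh, gw) spatial grid for the spatial L2 aggregation.  With
    ``grn_enabled`` off the GRN step is skipped (plain MaxViT MLP).
    """

    def __init__(self, dim: int, cfg: ModelConfig, rng: np.random.Generator):
        hidden = int(round(dim * cfg.mlp_expansion))
        self.norm = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)
        self.grn = GRN(hidden, eps=cfg.grn_eps, frozen=cfg.grn_frozen) if cfg.grn_enabled else None
        self.hidden = hidden

    def forward(self, x: Tensor, grid: tuple[int, int]) -> Tensor:
        gh, gw = grid
        if x.shape[-2] != gh * gw:
            raise ValidationError(
                f"{x.shape[-2]} tokens do not form a {gh}x{gw} spatial grid")
        h = self.fc1(self.norm(x)).gelu()
        if self.grn is not None:
            lead = h.shape[:-2]
            m = h.reshape((-1, gh, gw, self.hidden)).transpose(0, 3, 1, 2)
            m = self.grn(m)
            h = m.transpose(0, 2, 3, 1).reshape(lead + (gh * gw, self.hidden))
        return self.fc2(h)


# ----------------------------------------------------------------------
# partitioning
def window_partition(x: Tensor, p: int, grid: bool = False) -> Tensor:
    """NCHW -> (N * H/P * W/P, P*P, C) token windows.

    Block mode groups contiguous PxP windows; grid mode samples every
    (H/P)-th position so each group spans the whole image.
    """
    n, c, h, w = x.shape
    if h % p or w % p:
        raise ShapeError(f"spatial size {h}x{w} not divisible by partition size {p}")
    if grid:
        t = x.reshape(n, c, p, h // p, p, w // p).transpose(0, 3, 5, 2, 4, 1)
    else:
        t = x.reshape(n, c, h // p, p, w // p, p).transpose(0, 2, 4, 3, 5, 1)
    return t.reshape(n * (h // p) * (w // p), p * p, c)


def window_unpartition(t: Tensor, p: int, n: int, h: int, w: int, grid: bool = False) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    c = t.shape[-1]
    if grid:
        x = t.reshape(n, h // p, w // p, p, p, c).transpose(0, 5, 3, 1, 4, 2)
        return x.reshape(n, c, h, w)
    x = t.reshape(n, h // p, w // p, p, p, c).transpose(0, 5, 1, 3, 2, 4)
    return x.reshape(n, c, h, w)


# ----------------------------------------------------------------------
# attention
def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, bias: Tensor | None = None):
    """softmax(q k^T / sqrt(d) + bias) v; returns (output, attention weights)."""
    d = q.shape[-1]
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (1.0 / np.sqrt(d))
    if bias is not None:
        scores = scores + bias
    attn = nn.softmax(scores, axis=-1)
    return attn @ v, attn


def relative_position_index(p: int) -> np.ndarray:
    """(P^2, P^2) index into a (2P-1)^2 relative-offset bias table."""
    coords = np.stack(np.meshgrid(np.arange(p), np.arange(p), indexing="ij"), axis=-1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :] + (p - 1)
    return (rel[..., 0] * (2 * p - 1) + rel[..., 1]).astype(np.int64)


class WindowAttention(Module):
    """Pre-normalized multi-head self-attention with relative position bias."""

    def __init__(self, dim: int, head_dim: int, p: int, rng: np.random.Generator):
        if dim % head_dim:
            raise ConfigurationError(f"width {dim} not divisible by head_dim {head_dim}")
        self.heads = dim // head_dim
        self.head_dim = head_dim
        self.norm = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.bias_table = Parameter(nn.trunc_normal(rng, ((2 * p - 1) ** 2, self.heads)))
        self._bias_index = relative_position_index(p)
        self.last_attention: np.ndarray | None = None

    def forward(self, tokens: Tensor) -> Tensor:
        b, t, c = tokens.shape
        qkv = self.qkv(self.norm(tokens)).reshape(b, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)          # (3, B, heads, T, d)
        q, k, v = (_take_first_axis(qkv, i) for i in range(3))
        bias = gather(self.bias_table, self._bias_index)      # (T, T, heads)
        bias = bias.transpose(2, 0, 1).reshape(1, self.heads, t, t)
        out, attn = scaled_dot_attention(q, k, v, bias)
        self.last_attention = attn.data
        out = out.transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


def _take_first_axis(x: Tensor, i: int) -> Tensor:
    """Differentiable x[i] along the leading axis."""
    out = Tensor(x.data[i], parents=(x,))

    def _bw(g):
        acc = np.zeros_like(x.data)
        acc[i] = g
        x._accum(acc)
    out._backward = _bw
    return out


class AttentionBlock(Module):
    """(partition -> MHSA -> unpartition) + residual, then residual GRN-MLP.

    ``mode`` selects block (local window) or grid (dilated global) attention.
    """

    def __init__(self, dim: int, cfg: ModelConfig, mode: str, rng: np.random.Generator):
        assert mode in ("block", "grid")
        self.mode = mode
        self.p = cfg.partition_size
        self.attn = WindowAttention(dim, cfg.head_dim, self.p, rng)
        self.mlp = GRNMLP(dim, cfg, rng)
        self.scope = cfg.grn_scope

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        grid = self.mode == "grid"
        tokens = window_partition(x, self.p, grid=grid)
        attended = self.attn(tokens)
        x = x + window_unpartition(attended, self.p, n, h, w, grid=grid)
        if self.scope == "window":
            tokens = window_partition(x, self.p, grid=grid)
            out = self.mlp(tokens, (self.p, self.p))
            return x + window_unpartition(out, self.p, n, h, w, grid=grid)
        tokens = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        out = self.mlp(tokens, (h, w))
        return x + out.reshape(n, h, w, c).transpose(0, 3, 1, 2)


# ----------------------------------------------------------------------
def _avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class SqueezeExcite(Module):
    def __init__(self, dim: int, se_ratio: float, rng: np.random.Generator):
        hidden = max(1, int(round(dim * se_ratio)))
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))                       # (N, C)
        gate = self.fc2(self.fc1(s).gelu()).sigmoid()
        n, c = gate.shape
        return x * gate.reshape(n, c, 1, 1)


class MBConv(Module):
    """Mobile inverted bottleneck: pre-norm, 1x1 expand, 3x3 depthwise
    (stride 2 when downsampling), squeeze-excitation, 1x1 project, residual."""

    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig,
                 downsample: bool, rng: np.random.Generator, se_enabled: bool = True):
        hidden = int(round(out_ch * cfg.mlp_expansion))
        self.norm = nn.ChannelLayerNorm(in_ch)
        self.expand = nn.Conv2d(in_ch, hidden, 1, rng)
        self.dw = nn.Conv2d(hidden, hidden, 3, rng, stride=2 if downsample else 1,
                            padding=1, depthwise=True)
        self.se = SqueezeExcite(hidden, cfg.se_ratio, rng) if se_enabled else None
        self.project = nn.Conv2d(hidden, out_ch, 1, rng)
        self.shortcut = (nn.Conv2d(in_ch, out_ch, 1, rng)
                         if (downsample or in_ch != out_ch) else None)
        self.downsample = downsample
        self.last_dw: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand(self.norm(x)).gelu()
        h = self.dw(h).gelu()
        self.last_dw = h
        if self.se is not None:
            h = self.se(h)
        h = self.project(h)
        s = x
        if self.downsample:
            s = _avg_pool2(s)
        if self.shortcut is not None:
            s = self.shortcut(s)
        return h + s


class MaxViTBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, cfg: ModelConfig,
                 downsample: bool, rng: np.random.Generator):
        self.mbconv = MBConv(in_ch, out_ch, cfg, downsample, rng)
        self.block_attn = AttentionBlock(out_ch, cfg, "block", rng)
        self.grid_attn = AttentionBlock(out_ch, cfg, "grid", rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.grid_attn(self.block_attn(self.mbconv(x)))


class MaxGRNet(Module):
    """The full network; a pure function of (ModelConfig, seed)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.stem1 = nn.Conv2d(3, cfg.stem_channels, 3, rng, stride=2, padding=1)
        self.stem2 = nn.Conv2d(cfg.stem_channels, cfg.stem_channels, 3, rng, padding=1)
        self.stages: list[list[MaxViTBlock]] = []
        in_ch = cfg.stem_channels
        for depth, out_ch in zip(cfg.stage_depths, cfg.stage_channels):
            blocks = []
            for j in range(depth):
                blocks.append(MaxViTBlock(in_ch, out_ch, cfg, downsample=(j == 0), rng=rng))
                in_ch = out_ch
            self.stages.append(blocks)
        self.head_norm = nn.LayerNorm(cfg.stage_channels[-1])
        self.head = nn.Linear(cfg.stage_channels[-1], cfg.num_classes, rng)
        self._features: dict[str, Tensor] = {}

    # -- feature taps ---------------------------------------------------
    def feature_layers(self) -> list[str]:
        names = []
        for i, blocks in enumerate(self.stages):
            for j in range(len(blocks)):
                names.append(f"stage{i + 1}.block{j}.mbconv.dw")
                names.append(f"stage{i + 1}.block{j}.out")
        return names

    def forward(self, images) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        n, c, h, w = x.shape
        if c != 3 or h != self.cfg.input_size or w != self.cfg.input_size:
            raise ValidationError(
                f"expected input of shape (N, 3, {self.cfg.input_size}, "
                f"{self.cfg.input_size}), got {tuple(x.shape)}")
        self._features = {}
        x = self.stem2(self.stem1(x).gelu())
        for i, blocks in enumerate(self.stages):
            for j, block in enumerate(blocks):
                x = block(x)
                self._features[f"stage{i + 1}.block{j}.mbconv.dw"] = block.mbconv.last_dw
                self._features[f"stage{i + 1}.block{j}.out"] = x
        pooled = x.mean(axis=(2, 3))
        return self.head(self.head_norm(pooled))

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities, evaluated without keeping the tape."""
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[None]
        chunks = []
        for i in range(0, len(images), batch_size):
            logits = self.forward(images[i:i + batch_size]).data
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            chunks.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(chunks, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(images, batch_size=batch_size).argmax(axis=1)


# ----------------------------------------------------------------------
def save_checkpoint(model: MaxGRNet, path) -> None:
    """Weights as .npz with the YAML config alongside (<path>.yaml)."""
    np.savez(path, **model.state_dict())
    model.cfg.to_yaml(str(path) + ".yaml")


def load_checkpoint(path) -> MaxGRNet:
    cfg = ModelConfig.from_yaml(str(path) + ".yaml")
    model = MaxGRNet(cfg, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
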
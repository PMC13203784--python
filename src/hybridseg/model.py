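"""Hybrid residual CNN-Transformer U-Net for binary lesion segmentation.

The network is a four-stage residual U-Net whose bottleneck tokenizes the
lowest-resolution feature map (16x16 at the default 256-pixel input) and
runs it through a stack of pre-norm Transformer encoder blocks with
multi-head self-attention, before a skip-connected decoder restores full
resolution and a 1x1 convolution + sigmoid emits a per-pixel foreground
probability. Setting ``use_transformer=False`` in the configuration
collapses the model to a plain residual U-Net (the ablation baseline).

Channel plan at the default configuration (base 32, four stages):
encoder 32 -> 64 -> 128 -> 256 with 2x max-pool after each stage,
bottleneck 256 -> 512 at 16x16, tokens 256 x 512 through 4 Transformer
layers with 8 heads and MLP ratio 4, decoder 512 -> 256 -> 128 -> 64 -> 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .autodiff import Tensor, astensor, concat
from . import nn

__all__ = [
    "ConfigurationError",
    "ShapeError",
    "ArchitectureConfig",
    "ConvSpec",
    "conv_param_count",
    "ResidualBlock",
    "EncoderStage",
    "Encoder",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Bottleneck",
    "DecoderBlock",
    "HybridUNet",
    "flatten_add_positional",
    "tokens_to_map",
    "binarize",
    "count_parameters",
    "build_model",
]


class ConfigurationError(ValueError):
    """Raised when an architecture/input combination is invalid."""


class ShapeError(ValueError):
    """Raised when tensor shapes violate an operation's contract."""


@dataclass
class ArchitectureConfig:
    """Structural hyperparameters of the hybrid network.

    ``bottleneck_channels`` defaults to twice the top encoder width
    (2 * base_channels * 2**(num_stages-1)); passing an inconsistent
    explicit value is rejected.
    """

    in_channels: int = 3
    base_channels: int = 32
    num_stages: int = 4
    bottleneck_channels: int | None = None
    transformer_layers: int = 4
    attention_heads: int = 8
    mlp_ratio: float = 4.0
    input_size: int = 256
    use_transformer: bool = True
    residual_blocks_per_stage: int = 2

    def __post_init__(self):
        top = self.base_channels * 2 ** (self.num_stages - 1)
        if self.bottleneck_channels is None:
            self.bottleneck_channels = 2 * top
        self.validate()

    @property
    def top_channels(self) -> int:
        return self.base_channels * 2 ** (self.num_stages - 1)

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 2**self.num_stages

    @property
    def token_count(self) -> int:
        return self.bottleneck_size**2

    def validate(self) -> None:
        for name in ("in_channels", "base_channels", "num_stages", "transformer_layers",
                     "attention_heads", "input_size", "residual_blocks_per_stage"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.mlp_ratio <= 0:
            raise ConfigurationError("mlp_ratio must be positive")
        if self.input_size % 2**self.num_stages:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^{self.num_stages}"
            )
        if self.bottleneck_channels != 2 * self.top_channels:
            raise ConfigurationError(
                "bottleneck_channels must be twice the top encoder width "
                f"({2 * self.top_channels}), got {self.bottleneck_channels}"
            )
        if self.use_transformer and self.bottleneck_channels % self.attention_heads:
            raise ConfigurationError(
                "bottleneck_channels must be divisible by attention_heads"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ArchitectureConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class ConvSpec:
    """Shape descriptor of a single convolution layer."""

    cin: int
    cout: int
    k: int
    bias: bool = True
    stride: int = 1
    padding: int = 0


def conv_param_count(spec: ConvSpec) -> int:
    """Trainable parameters of a convolution: Cout*Cin*k^2 (+Cout if bias)."""
    if spec.cin <= 0 or spec.cout <= 0 or spec.k <= 0:
        raise ConfigurationError("convolution dimensions must be positive")
    n = spec.cout * spec.cin * spec.k * spec.k
    return n + spec.cout if spec.bias else n


class ResidualBlock(nn.Module):
    """Conv-BN-ReLU -> Conv-BN, plus a (projected) skip, then ReLU.

    The two main convolutions are 3x3 stride-1 pad-1 without bias
    (batch norm supplies the affine terms). The skip path is the identity
    when channel counts agree, else a 1x1 convolution followed by batch
    norm.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.cin = cin
        self.cout = cout
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ShapeError(f"expected {self.cin} channels, got {x.shape[1]}")
        y = self.bn1(self.conv1(x)).relu()
        z = self.bn2(self.conv2(y))
        s = x if self.proj is None else self.proj_bn(self.proj(x))
        return (z + s).relu()


class EncoderStage(nn.Module):
    """Residual blocks followed by 2x2 max pooling; keeps the pre-pool map."""

    def __init__(self, cin: int, cout: int, n_blocks: int, rng: np.random.Generator):
        super().__init__()
        blocks = [ResidualBlock(cin, cout, rng)]
        blocks += [ResidualBlock(cout, cout, rng) for _ in range(n_blocks - 1)]
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        for b in self.blocks:
            x = b(x)
        return x, x.maxpool2d()


class Encoder(nn.Module):
    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator):
        super().__init__()
        stages = []
        cin = cfg.in_channels
        for i in range(cfg.num_stages):
            cout = cfg.base_channels * 2**i
            stages.append(EncoderStage(cin, cout, cfg.residual_blocks_per_stage, rng))
            cin = cout
        self.stages = nn.ModuleList(stages)

    def forward(self, x: Tensor) -> tuple[list[Tensor], Tensor]:
        """Return (pre-pool skip maps, pooled bottom map)."""
        skips = []
        for stage in self.stages:
            skip, x = stage(x)
            skips.append(skip)
        return skips, x


def flatten_add_positional(x: Tensor, pos: Tensor) -> Tensor:
    """Flatten a (B, C, H, W) map into (B, H*W, C) tokens and add ``pos``.

    Tokens are ordered row-major over spatial positions, so
    :func:`tokens_to_map` is an exact inverse.
    """
    B, C, H, W = x.shape
    n = H * W
    if pos.shape != (1, n, C):
        raise ShapeError(f"positional embedding shape {pos.shape} != (1, {n}, {C})")
    tokens = x.reshape(B, C, n).transpose(0, 2, 1)
    return tokens + pos


def tokens_to_map(t: Tensor, height: int, width: int) -> Tensor:
    """Inverse of the row-major flattening: (B, N, C) -> (B, C, H, W)."""
    B, n, C = t.shape
    if n != height * width:
        raise ShapeError(f"token count {n} != {height}*{width}")
    return t.transpose(0, 2, 1).reshape(B, C, height, width)


class MultiHeadSelfAttention(nn.Module):
    """Scaled dot-product attention over tokens, H parallel heads.

    Per head: softmax(Q K^T / sqrt(d_k)) V with Q/K/V as learned linear
    projections of the input; head outputs are concatenated and passed
    through a final linear projection.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ConfigurationError(f"embed dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.q_proj = nn.Linear(dim, dim, rng=rng)
        self.k_proj = nn.Linear(dim, dim, rng=rng)
        self.v_proj = nn.Linear(dim, dim, rng=rng)
        self.out_proj = nn.Linear(dim, dim, rng=rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, N, C = x.shape
        H, d = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, N, C) -> (B, H, N, d)
            return t.reshape(B, N, H, d).transpose(0, 2, 1, 3)

        q = split(self.q_proj(x))
        k = split(self.k_proj(x))
        v = split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(d))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (B, H, N, d)
        merged = out.transpose(0, 2, 1, 3).reshape(B, N, C)
        return self.out_proj(merged)


class TransformerBlock(nn.Module):
    """Pre-norm Transformer encoder block.

    z' = z + MHSA(LN(z)); z'' = z' + FFN(LN(z')), with a GELU feed-forward
    of hidden width ``mlp_ratio * dim``.
    """

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        super().__init__()
        hidden = int(round(mlp_ratio * dim))
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x


class Bottleneck(nn.Module):
    """Two residual blocks doubling the channel width, then (optionally)
    a Transformer stack over the tokenized map."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator):
        super().__init__()
        cin, cout = cfg.top_channels, cfg.bottleneck_channels
        self.block1 = ResidualBlock(cin, cout, rng)
        self.block2 = ResidualBlock(cout, cout, rng)
        self.use_transformer = cfg.use_transformer
        if cfg.use_transformer:
            n = cfg.token_count
            self.pos_embed = nn.Parameter(
                rng.normal(0.0, 0.02, size=(1, n, cout)).astype(np.float32)
            )
            self.blocks = nn.ModuleList(
                TransformerBlock(cout, cfg.attention_heads, cfg.mlp_ratio, rng)
                for _ in range(cfg.transformer_layers)
            )
        self.last_token_shape: tuple[int, ...] | None = None

    def forward(self, x: Tensor) -> Tensor:
        x = self.block2(self.block1(x))
        if not self.use_transformer:
            self.last_token_shape = None
            return x
        B, C, H, W = x.shape
        t = flatten_add_positional(x, self.pos_embed)
        self.last_token_shape = t.shape
        for blk in self.blocks:
            t = blk(t)
        return tokens_to_map(t, H, W)


class DecoderBlock(nn.Module):
    """Learned 2x upsampling, skip concatenation, residual refinement.

    If the upsampled map and the skip differ spatially (odd input sizes),
    the upsampled map is bilinearly resampled to the skip's grid before
    concatenation.
    """

    def __init__(self, cin: int, skip_channels: int, cout: int,
                 n_blocks: int, rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, rng=rng)
        blocks = [ResidualBlock(cout + skip_channels, cout, rng)]
        blocks += [ResidualBlock(cout, cout, rng) for _ in range(n_blocks - 1)]
        self.blocks = nn.ModuleList(blocks)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.up(x)
        if up.shape[2:] != skip.shape[2:]:
            up = up.resize_bilinear(skip.shape[2], skip.shape[3])
        x = concat([up, skip], axis=1)
        for b in self.blocks:
            x = b(x)
        return x


class HybridUNet(nn.Module):
    """End-to-end segmentation network; returns per-pixel probabilities."""

    def __init__(self, cfg: ArchitectureConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.bottleneck = Bottleneck(cfg, rng)
        widths = [cfg.base_channels * 2**i for i in range(cfg.num_stages)]
        dec = []
        cin = cfg.bottleneck_channels
        for i in reversed(range(cfg.num_stages)):
            dec.append(DecoderBlock(cin, widths[i], widths[i],
                                    cfg.residual_blocks_per_stage, rng))
            cin = widths[i]
        self.decoder = nn.ModuleList(dec)
        self.head = nn.Conv2d(cfg.base_channels, 1, 1, bias=True, rng=rng)
        self.last_trace: dict[str, tuple[int, ...]] | None = None

    def forward(self, image, record: bool = False) -> Tensor:
        x = astensor(image)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected (B, {self.cfg.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 2**self.cfg.num_stages or x.shape[3] % 2**self.cfg.num_stages:
            raise ConfigurationError(
                f"spatial size {x.shape[2:]} not divisible by 2^{self.cfg.num_stages}"
            )
        trace: dict[str, tuple[int, ...]] = {}
        skips, bottom = self.encoder(x)
        if record:
            for i, s in enumerate(skips):
                trace[f"encoder_skip_{i + 1}"] = s.shape
            trace["encoder_bottom"] = bottom.shape
        z = self.bottleneck(bottom)
        if record:
            trace["bottleneck"] = z.shape
            if self.bottleneck.last_token_shape is not None:
                trace["tokens"] = self.bottleneck.last_token_shape
        for i, block in enumerate(self.decoder):
            z = block(z, skips[self.cfg.num_stages - 1 - i])
            if record:
                trace[f"decoder_{self.cfg.num_stages - i}"] = z.shape
        logits = self.head(z)
        if record:
            trace["logits"] = logits.shape
            self.last_trace = trace
        return logits.sigmoid()

    def predict(self, image, threshold: float = 0.5) -> np.ndarray:
        """Inference helper: eval mode, no autodiff graph, binarized mask."""
        from .autodiff import no_grad

        was_training = self.training
        self.eval()
        try:
            with no_grad():
                prob = self.forward(image)
        finally:
            if was_training:
                self.train()
        return binarize(prob.data, threshold)


def binarize(p, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities into a {0,1} mask; ties go to foreground."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    arr = p.data if isinstance(p, Tensor) else np.asarray(p)
    return (arr >= threshold).astype(np.uint8)


def count_parameters(model: HybridUNet) -> dict[str, int]:
    """Split trainable parameter counts into transformer and CNN parts."""
    total = transformer = 0
    for name, p in model.named_parameters():
        n = p.data.size
        total += n
        if name.startswith("bottleneck.pos_embed") or name.startswith("bottleneck.blocks"):
            transformer += n
    return {"total": total, "transformer_part": transformer, "cnn_part": total - transformer}


def build_model(cfg: ArchitectureConfig | None = None, seed: int = 0) -> HybridUNet:
    cfg = cfg or ArchitectureConfig()
    return HybridUNet(cfg, np.random.default_rng(seed))


def unet_baseline_config(**overrides) -> ArchitectureConfig:
    """Plain residual U-Net configuration (no Transformer bottleneck).

    Uses the same code path with ``use_transformer=False``; the default
    keeps base 32 so CNN capacity matches the hybrid model's CNN part.
    """
    kwargs = dict(use_transformer=False)
    kwargs.update(overrides)
    return ArchitectureConfig(**kwargs)
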
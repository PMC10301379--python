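"""Multi-axis self-attention classifier.

The network consumes the fused feature tensor (depth x 64 x 64 per epoch) and
predicts the emotion class.  Architecture:

* fusion convolution: 1x1 conv + batch norm + ReLU, projecting the fused
  depth onto the working channel width without touching the spatial axes;
* stem: two 3x3 convolutions (the second with stride 2), 64 -> 32;
* two parallel branches of three stages each.  Every stage is a stride-2
  MBConv (inverted bottleneck with squeeze-excitation; its depthwise 3x3
  doubles as conditional position coding) followed by one self-attention
  block.  The local branch restricts attention to non-overlapping P x P
  windows; the global branch attends within groups sampled one element per
  G x G tile (dilated, sparse-global interaction).  With P = G = 4 and a
  64 x 64 input the stages run at 16, 8 and 4, ending at the 4 x 4 map;
* head: global average pooling of both branches, concatenation, one fully
  connected layer to the class logits.

Attention blocks are pre-norm (layer normalisation before multi-head
attention) with a residual connection and no relative position bias.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``spatial`` must stay divisible by both ``window_size`` and ``grid_size``
    at every stage (the spatial size halves at the stem and at each stage).
    The defaults end at a 4 x 4 map for a 64 x 64 input.
    """

    in_depth: int = 200
    spatial: int = 64
    num_classes: int = 3
    window_size: int = 4
    grid_size: int = 4
    stage_channels: tuple[int, ...] = (32, 64, 128)
    heads: tuple[int, ...] | int = 4
    mbconv_expansion: int = 4
    se_reduction: float = 0.25
    stem_channels: int | None = None

    def __post_init__(self) -> None:
        if self.window_size != self.grid_size:
            raise ValueError("window_size and grid_size must match (P = G)")
        if isinstance(self.heads, int):
            self.heads = (self.heads,) * len(self.stage_channels)
        self.stage_channels = tuple(self.stage_channels)
        self.heads = tuple(self.heads)
        if len(self.heads) != len(self.stage_channels):
            raise ValueError("one head count per stage required")
        for ch, h in zip(self.stage_channels, self.heads):
            if ch % h:
                raise ValueError(f"stage width {ch} not divisible by {h} heads")
        for s in self.stage_spatial():
            if s % self.window_size or s % self.grid_size:
                raise ValueError(
                    f"stage spatial size {s} not divisible by window/grid size "
                    f"{self.window_size}"
                )

    def stage_spatial(self) -> list[int]:
        """Spatial size at the output of each stage (stem halves once first)."""
        s = self.spatial // 2
        out = []
        for _ in self.stage_channels:
            s //= 2
            out.append(s)
        return out

    @property
    def stem_width(self) -> int:
        return self.stem_channels if self.stem_channels is not None else self.stage_channels[0]


# --------------------------------------------------------------------------
# Axis partitions
# --------------------------------------------------------------------------

def window_partition(x: Tensor, p: int) -> Tensor:
    """Split an NCHW tensor into non-overlapping p x p windows of tokens.

    Returns tokens of shape (N * (H/p) * (W/p), p*p, C); lossless, inverted by
    :func:`window_unpartition`.
    """
    n, c, h, w = x.shape
    if h % p or w % p:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by window size {p}")
    t = x.reshape(n, c, h // p, p, w // p, p)
    t = t.transpose(0, 2, 4, 3, 5, 1)  # n, h/p, w/p, p, p, c
    return t.reshape(n * (h // p) * (w // p), p * p, c)


def window_unpartition(tokens: Tensor, p: int, h: int, w: int) -> Tensor:
    nw = (h // p) * (w // p)
    n = tokens.shape[0] // nw
    c = tokens.shape[-1]
    t = tokens.reshape(n, h // p, w // p, p, p, c)
    t = t.transpose(0, 5, 1, 3, 2, 4)  # n, c, h/p, p, w/p, p
    return t.reshape(n, c, h, w)


def grid_partition(x: Tensor, g: int) -> Tensor:
    """Split an NCHW tensor into g*g dilated token groups.

    The map is tiled into g x g blocks; group (a, b) gathers the element at
    offset (a, b) of every tile, giving (H/g) * (W/g) tokens that span the
    whole map.  Returns (N * g * g, (H/g)*(W/g), C); inverted by
    :func:`grid_unpartition`.
    """
    n, c, h, w = x.shape
    if h % g or w % g:
        raise ValueError(f"spatial size ({h}, {w}) not divisible by grid size {g}")
    t = x.reshape(n, c, h // g, g, w // g, g)
    t = t.transpose(0, 3, 5, 2, 4, 1)  # n, g, g, h/g, w/g, c
    return t.reshape(n * g * g, (h // g) * (w // g), c)


def grid_unpartition(tokens: Tensor, g: int, h: int, w: int) -> Tensor:
    n = tokens.shape[0] // (g * g)
    c = tokens.shape[-1]
    t = tokens.reshape(n, g, g, h // g, w // g, c)
    t = t.transpose(0, 5, 3, 1, 4, 2)  # n, c, h/g, g, w/g, g
    return t.reshape(n, c, h, w)


# --------------------------------------------------------------------------
# Initialisers
# --------------------------------------------------------------------------

def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2.0 * std, 2.0 * std).astype(np.float32)


def conv_init(rng: np.random.Generator, shape) -> np.ndarray:
    # fan-out He initialisation: shape is (O, C, kh, kw) or (C, kh, kw)
    fan_out = shape[0] * int(np.prod(shape[2:])) if len(shape) == 4 else int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_out), size=shape).astype(np.float32)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, rng, cin, cout, k, stride=1, padding=0, bias=True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(conv_init(rng, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, rng, c, k=3, stride=1, padding=1):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(conv_init(rng, (c, k, k)))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, rng, cin, cout):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (cin, cout)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class LayerNorm(Module):
    def __init__(self, c, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over token sets (B, L, C)."""

    def __init__(self, rng, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim**-0.5
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def _split(self, t: Tensor, b: int, l: int) -> Tensor:
        return t.reshape(b, l, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, tokens: Tensor, return_weights: bool = False):
        b, l, c = tokens.shape
        q = self._split(self.wq.forward(tokens), b, l)
        k = self._split(self.wk.forward(tokens), b, l)
        v = self._split(self.wv.forward(tokens), b, l)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        weights = attn.softmax(axis=-1)  # rows sum to 1 per query
        out = weights @ v
        out = out.transpose(0, 2, 1, 3).reshape(b, l, c)
        out = self.wo.forward(out)
        if return_weights:
            return out, weights
        return out


class SqueezeExcite(Module):
    """Channel gating: global pool -> bottleneck MLP -> sigmoid scale."""

    def __init__(self, rng, c: int, squeezed: int):
        super().__init__()
        self.fc1 = Linear(rng, c, squeezed)
        self.fc2 = Linear(rng, squeezed, c)

    def gate(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(2, 3))  # (N, C)
        return self.fc2.forward(self.fc1.forward(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gate(x).reshape(n, c, 1, 1)


class MBConv(Module):
    """Inverted-bottleneck residual block: expand -> depthwise -> SE -> project."""

    def __init__(self, rng, cin, cout, stride=1, expansion=4, se_reduction=0.25):
        super().__init__()
        mid = cin * expansion
        self.use_residual = stride == 1 and cin == cout
        self.expand = Conv2d(rng, cin, mid, 1, bias=False)
        self.bn1 = BatchNorm2d(mid)
        self.dw = DepthwiseConv2d(rng, mid, 3, stride=stride, padding=1)
        self.bn2 = BatchNorm2d(mid)
        self.se = SqueezeExcite(rng, mid, max(1, int(cin * se_reduction)))
        self.project = Conv2d(rng, mid, cout, 1, bias=False)
        self.bn3 = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1.forward(self.expand.forward(x)).relu()
        h = self.bn2.forward(self.dw.forward(h)).relu()
        h = self.se.forward(h)
        h = self.bn3.forward(self.project.forward(h))
        if self.use_residual:
            h = h + x
        return h


class AttentionBlock(Module):
    """Pre-norm windowed/grid self-attention with a residual connection."""

    def __init__(self, rng, dim: int, heads: int, size: int, axis: str):
        super().__init__()
        if axis not in ("window", "grid"):
            raise ValueError(f"unknown attention axis {axis!r}")
        self.axis = axis
        self.size = size
        self.norm = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, heads)

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        part, unpart = (
            (window_partition, window_unpartition)
            if self.axis == "window"
            else (grid_partition, grid_unpartition)
        )
        tokens = part(x, self.size)
        tokens = tokens + self.attn.forward(self.norm.forward(tokens))
        return unpart(tokens, self.size, h, w)


class Stage(Module):
    def __init__(self, rng, cin, cout, heads, size, axis, expansion, se_reduction):
        super().__init__()
        self.mbconv = MBConv(rng, cin, cout, stride=2, expansion=expansion, se_reduction=se_reduction)
        self.attn = AttentionBlock(rng, cout, heads, size, axis)

    def forward(self, x: Tensor) -> Tensor:
        return self.attn.forward(self.mbconv.forward(x))


class FusionConv(Module):
    """1x1 convolution + batch norm + ReLU; unifies depth, keeps spatial size."""

    def __init__(self, rng, cin, cout):
        super().__init__()
        self.conv = Conv2d(rng, cin, cout, 1, bias=True)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn.forward(self.conv.forward(x)).relu()


class MultiAxisClassifier(Module):
    """The full two-branch window/grid attention network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        stem = config.stem_width
        self.fusion_conv = FusionConv(rng, config.in_depth, stem)
        self.stem1 = Conv2d(rng, stem, stem, 3, stride=1, padding=1, bias=False)
        self.stem_bn1 = BatchNorm2d(stem)
        self.stem2 = Conv2d(rng, stem, stem, 3, stride=2, padding=1, bias=False)
        self.stem_bn2 = BatchNorm2d(stem)
        cin = stem
        for i, (cout, heads) in enumerate(zip(config.stage_channels, config.heads)):
            local = Stage(rng, cin, cout, heads, config.window_size, "window",
                          config.mbconv_expansion, config.se_reduction)
            glob = Stage(rng, cin, cout, heads, config.grid_size, "grid",
                         config.mbconv_expansion, config.se_reduction)
            setattr(self, f"local{i}", local)
            setattr(self, f"global{i}", glob)
            cin = cout
        self.head = Linear(rng, 2 * config.stage_channels[-1], config.num_classes)

    def _stem(self, x: Tensor) -> Tensor:
        h = self.fusion_conv.forward(x)
        h = self.stem_bn1.forward(self.stem1.forward(h)).relu()
        h = self.stem_bn2.forward(self.stem2.forward(h)).relu()
        return h

    def forward(self, x) -> Tensor:
        """Logits for a batch: x is (N, in_depth, spatial, spatial)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[1] != self.config.in_depth or x.shape[2] != self.config.spatial:
            raise ValueError(
                f"expected input (N, {self.config.in_depth}, {self.config.spatial}, "
                f"{self.config.spatial}), got {x.shape}"
            )
        h = self._stem(x)
        local, glob = h, h
        for i in range(len(self.config.stage_channels)):
            local = getattr(self, f"local{i}").forward(local)
            glob = getattr(self, f"global{i}").forward(glob)
        pooled = ad.concat([local.mean(axis=(2, 3)), glob.mean(axis=(2, 3))], axis=1)
        return self.head.forward(pooled)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class predictions in eval mode, batched to bound memory."""
        was_training = self.training
        self.eval()
        preds = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size])
            preds.append(np.argmax(logits.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(preds) if preds else np.empty(0, dtype=int)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(model: MultiAxisClassifier, path) -> None:
    """Store weights, running statistics, config and seed in one npz file."""
    arrays = model.state_arrays()
    arrays["__config__"] = np.frombuffer(
        json.dumps({"config": asdict(model.config), "seed": model.seed}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> MultiAxisClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"].tobytes()).decode())
        arrays = {k: data[k] for k in data.files if k != "__config__"}
    cfg = meta["config"]
    cfg["stage_channels"] = tuple(cfg["stage_channels"])
    cfg["heads"] = tuple(cfg["heads"])
    model = MultiAxisClassifier(ModelConfig(**cfg), seed=meta["seed"])
    model.load_state_arrays(arrays)
    return model
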
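"""Residual dual-attention U-Net and plain U-Net baselines.

The dual-attention gate combines a single-channel spatial mask ``Q``
(1x1 convolution over channels + sigmoid, broadcast over channels) with a
per-channel code ``P`` (global average pooling + 1x1 convolution + sigmoid,
broadcast over positions)::

    out = Q(F) * F + P(F) * F

The residual block wraps two 3x3 conv(+BN)+ReLU layers and the attention
gate, adds the block input back (through a learned 1x1 projection when the
channel counts differ), and finishes with a ReLU.

The full network is a classical encoder / bottleneck / decoder / classifier
U-shape: per level a residual dual-attention block and 2x2 max pooling on
the way down, a two-convolution bottleneck, 2x2 transposed-convolution
upsampling with same-level skip concatenation on the way up, and a 1x1
convolution + per-pixel softmax classifier. All convolutions are
zero-padded so spatial sizes are preserved within a level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2x2,
    MaxPool2x2,
    Module,
    Param,
    ReLU,
    Sigmoid,
    softmax_channels,
    softmax_channels_backward,
)

__all__ = [
    "RDAUnetConfig",
    "DualAttention",
    "RDABlock",
    "DoubleConvBlock",
    "RDAUnet",
    "build_rda_unet",
    "build_unet_baseline",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class RDAUnetConfig:
    """Architecture hyperparameters."""

    depth: int = 4
    base_channels: int = 32
    in_channels: int = 1
    n_classes: int = 2
    use_batch_norm: bool = True
    block: str = "rda"  # "rda" | "double_conv"
    # BN framework defaults, recorded for reproducibility
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.block not in ("rda", "double_conv"):
            raise ValueError(f"unknown block type: {self.block!r}")

    def validate_input_size(self, side: int) -> None:
        if side % (2 ** self.depth) != 0:
            raise ValueError(
                f"input side {side} is not divisible by 2^depth = {2 ** self.depth}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


class DualAttention(Module):
    """Parallel spatial and channel sigmoid gates, summed elementwise."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.channels = channels
        self.spatial_conv = Conv2d(channels, 1, 1, rng, dtype)
        self.channel_conv = Conv2d(channels, channels, 1, rng, dtype)
        self.spatial_sig = Sigmoid()
        self.channel_sig = Sigmoid()
        self._cache = None

    def forward(self, f: np.ndarray) -> np.ndarray:
        q = self.spatial_sig.forward(self.spatial_conv.forward(f))  # (N,1,H,W)
        pooled = f.mean(axis=(2, 3), keepdims=True)                 # (N,C,1,1)
        p = self.channel_sig.forward(self.channel_conv.forward(pooled))
        self._cache = (f, q, p)
        return q * f + p * f

    def backward(self, gy: np.ndarray) -> np.ndarray:
        f, q, p = self._cache
        self._cache = None
        hw = f.shape[2] * f.shape[3]
        gf = gy * (q + p)
        # spatial gate path
        gq = (gy * f).sum(axis=1, keepdims=True)
        gf += self.spatial_conv.backward(self.spatial_sig.backward(gq))
        # channel gate path
        gp = (gy * f).sum(axis=(2, 3), keepdims=True)
        gpooled = self.channel_conv.backward(self.channel_sig.backward(gp))
        gf += gpooled / hw
        return gf

    def attention_maps(self, f: np.ndarray):
        """Return (Q, P) for a feature map, without caching for backprop."""
        q = self.spatial_sig.forward(self.spatial_conv.forward(f))
        pooled = f.mean(axis=(2, 3), keepdims=True)
        p = self.channel_sig.forward(self.channel_conv.forward(pooled))
        self._cache = None
        self.spatial_sig._y = None
        self.channel_sig._y = None
        self.spatial_conv._cols = None
        self.channel_conv._cols = None
        return q, p


class _ConvBNReLU(Module):
    def __init__(self, in_c: int, out_c: int, k: int, use_bn: bool,
                 rng: np.random.Generator, dtype=np.float32,
                 bn_eps: float = 1e-5, bn_momentum: float = 0.1):
        super().__init__()
        self.conv = Conv2d(in_c, out_c, k, rng, dtype)
        self.bn = BatchNorm2d(out_c, bn_eps, bn_momentum, dtype) if use_bn else None
        self.relu = ReLU()

    def forward(self, x):
        y = self.conv.forward(x)
        if self.bn is not None:
            y = self.bn.forward(y)
        return self.relu.forward(y)

    def backward(self, gy):
        gy = self.relu.backward(gy)
        if self.bn is not None:
            gy = self.bn.backward(gy)
        return self.conv.backward(gy)


class RDABlock(Module):
    """conv-BN-ReLU x2 -> dual attention -> identity residual -> ReLU."""

    def __init__(self, in_c: int, out_c: int, use_bn: bool,
                 rng: np.random.Generator, dtype=np.float32,
                 bn_eps: float = 1e-5, bn_momentum: float = 0.1):
        super().__init__()
        self.conv1 = _ConvBNReLU(in_c, out_c, 3, use_bn, rng, dtype, bn_eps, bn_momentum)
        self.conv2 = _ConvBNReLU(out_c, out_c, 3, use_bn, rng, dtype, bn_eps, bn_momentum)
        self.attention = DualAttention(out_c, rng, dtype)
        self.project = Conv2d(in_c, out_c, 1, rng, dtype) if in_c != out_c else None
        self.out_relu = ReLU()

    def forward(self, x):
        f = self.conv2.forward(self.conv1.forward(x))
        att = self.attention.forward(f)
        skip = self.project.forward(x) if self.project is not None else x
        return self.out_relu.forward(att + skip)

    def backward(self, gy):
        gy = self.out_relu.backward(gy)
        gskip = self.project.backward(gy) if self.project is not None else gy
        gf = self.attention.backward(gy)
        gx = self.conv1.backward(self.conv2.backward(gf))
        return gx + gskip


class DoubleConvBlock(Module):
    """Plain U-Net block: conv(+BN)+ReLU twice, no attention, no residual."""

    def __init__(self, in_c: int, out_c: int, use_bn: bool,
                 rng: np.random.Generator, dtype=np.float32,
                 bn_eps: float = 1e-5, bn_momentum: float = 0.1):
        super().__init__()
        self.conv1 = _ConvBNReLU(in_c, out_c, 3, use_bn, rng, dtype, bn_eps, bn_momentum)
        self.conv2 = _ConvBNReLU(out_c, out_c, 3, use_bn, rng, dtype, bn_eps, bn_momentum)

    def forward(self, x):
        return self.conv2.forward(self.conv1.forward(x))

    def backward(self, gy):
        return self.conv1.backward(self.conv2.backward(gy))


class RDAUnet(Module):
    """Encoder / bottleneck / decoder / classifier segmentation network.

    ``forward`` returns per-pixel class probabilities (N, n_classes, H, W);
    ``backward`` expects the gradient w.r.t. those probabilities and routes
    it back through the softmax.
    """

    def __init__(self, config: RDAUnetConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        block_cls = RDABlock if cfg.block == "rda" else DoubleConvBlock
        mk = lambda i, o: block_cls(i, o, cfg.use_batch_norm, rng, dtype,
                                    cfg.bn_eps, cfg.bn_momentum)

        chans = [cfg.base_channels * (2 ** d) for d in range(cfg.depth + 1)]
        self.enc_blocks = []
        self.pools = []
        prev = cfg.in_channels
        for d in range(cfg.depth):
            self.enc_blocks.append(mk(prev, chans[d]))
            self.pools.append(MaxPool2x2())
            prev = chans[d]
        self.bottleneck1 = _ConvBNReLU(prev, chans[-1], 3, cfg.use_batch_norm,
                                       rng, dtype, cfg.bn_eps, cfg.bn_momentum)
        self.bottleneck2 = _ConvBNReLU(chans[-1], chans[-1], 3, cfg.use_batch_norm,
                                       rng, dtype, cfg.bn_eps, cfg.bn_momentum)
        self.upsamples = []
        self.dec_blocks = []
        prev = chans[-1]
        for d in reversed(range(cfg.depth)):
            self.upsamples.append(ConvTranspose2x2(prev, chans[d], rng, dtype))
            self.dec_blocks.append(mk(chans[d] * 2, chans[d]))
            prev = chans[d]
        self.classifier = Conv2d(prev, cfg.n_classes, 1, rng, dtype)
        self._probs = None
        self._skip_channels = chans[:cfg.depth]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got shape {x.shape}")
        self.config.validate_input_size(x.shape[2])
        self.config.validate_input_size(x.shape[3])
        skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck2.forward(self.bottleneck1.forward(h))
        for up, block, skip in zip(self.upsamples, self.dec_blocks,
                                   reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h)
        logits = self.classifier.forward(h)
        probs = softmax_channels(logits)
        self._probs = probs
        return probs

    def backward(self, gprobs: np.ndarray) -> np.ndarray:
        glogits = softmax_channels_backward(self._probs, gprobs)
        self._probs = None
        gy = self.classifier.backward(glogits)
        gskips = []
        for up, block in zip(reversed(self.upsamples), reversed(self.dec_blocks)):
            gy = block.backward(gy)
            c = gy.shape[1] // 2
            gskips.append(gy[:, :c])
            gy = up.backward(gy[:, c:])
        gy = self.bottleneck1.backward(self.bottleneck2.backward(gy))
        for block, pool, gskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), reversed(gskips)):
            gy = pool.backward(gy)
            gy = block.backward(gy + gskip)
        return gy

    # -- inference helpers --------------------------------------------
    def predict_probs(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Run the network in eval mode on (N, H, W) images in [0, 1]."""
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, images.shape[0], batch_size):
            x = images[i:i + batch_size][:, None].astype(
                self.classifier.weight.data.dtype)
            out.append(self.forward(x))
            self._probs = None
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)

    def predict_mask(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Arg-max segmentation mask(s) for (H, W) or (N, H, W) input."""
        single = np.asarray(images).ndim == 2
        probs = self.predict_probs(images, batch_size)
        masks = probs.argmax(axis=1).astype(np.uint8)
        return masks[0] if single else masks


def build_rda_unet(config: RDAUnetConfig | None = None, seed: int = 0,
                   dtype=np.float32) -> RDAUnet:
    """Build the residual dual-attention network."""
    cfg = config or RDAUnetConfig()
    if cfg.block != "rda":
        cfg = RDAUnetConfig(**{**cfg.to_dict(), "block": "rda"})
    return RDAUnet(cfg, seed=seed, dtype=dtype)


def build_unet_baseline(config: RDAUnetConfig | None = None, with_bn: bool = True,
                        seed: int = 0, dtype=np.float32) -> RDAUnet:
    """Build a plain U-Net with the same topology (double-conv blocks)."""
    cfg = config or RDAUnetConfig()
    cfg = RDAUnetConfig(**{**cfg.to_dict(),
                           "block": "double_conv",
                           "use_batch_norm": with_bn})
    return RDAUnet(cfg, seed=seed, dtype=dtype)


def save_checkpoint(model: RDAUnet, path) -> None:
    """Save weights + embedded architecture config as an ``.npz`` container."""
    import json

    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, dtype=np.float32) -> RDAUnet:
    import json

    with np.load(path) as data:
        cfg = RDAUnetConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = RDAUnet(cfg, seed=0, dtype=dtype)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
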
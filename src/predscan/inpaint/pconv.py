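"""Partial convolutions and the partial-convolution UNet.

A partial convolution restricts the kernel to valid (known) pixels and
renormalizes by the fraction of valid pixels under the window:

    out = (W . (X * M)) * (window_size / valid_count),  0 where no valid pixel,

after which the mask is updated: a location becomes valid as soon as its
window saw at least one valid pixel, so the valid region grows monotonically
through the network.  The UNet encoder halves resolution per block
(kernel schedule 7, 5, 5, 3, 3, ...); the decoder mirrors it with
nearest-neighbour upsampling, skip concatenation and LeakyReLU, ending in a
linear 3x3 convolution back to one channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, concat, conv2d, upsample_nearest

KERNEL_SCHEDULE = (7, 5, 5, 3, 3, 3, 3, 3)


def _window_counts(mask: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """Number of valid pixels under each kxk window of a (N,1,H,W) binary mask."""
    mp = np.pad(mask, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(mp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.sum(axis=(-1, -2))


def partial_conv_forward(
    features: np.ndarray,
    mask: np.ndarray,
    kernel: np.ndarray,
    stride: int = 1,
    padding: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single partial convolution on plain arrays (the reference primitive).

    ``features``: (N, C, H, W); ``mask``: (N, 1, H, W) binary, shared across
    channels; ``kernel``: (O, C, k, k).  Returns (features', mask').
    """
    features = np.asarray(features, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if mask.shape[0] != features.shape[0] or mask.shape[2:] != features.shape[2:]:
        raise ValueError("mask and features must share N, H, W")
    if not np.isin(mask, (0.0, 1.0)).all():
        raise ValueError("mask must be binary")
    O, C, kh, kw = kernel.shape
    if kh != kw:
        raise ValueError("square kernels only")
    if padding is None:
        padding = kh // 2
    cnt = _window_counts(mask, kh, stride, padding)
    ratio = np.where(cnt > 0, (kh * kw) / np.maximum(cnt, 1), 0.0)
    x = Tensor(features * mask)
    w = Tensor(kernel)
    raw = conv2d(x, w, stride=stride, padding=padding).data
    out = raw * ratio
    new_mask = (cnt > 0).astype(float)
    return out, new_mask


class PartialConv2d:
    """Trainable partial-convolution layer sharing a single-channel mask."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.k, self.stride, self.pad = k, stride, k // 2

    def __call__(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, np.ndarray]:
        cnt = _window_counts(mask, self.k, self.stride, self.pad)
        ratio = np.where(cnt > 0, (self.k * self.k) / np.maximum(cnt, 1), 0.0)
        new_mask = (cnt > 0).astype(float)
        out = conv2d(x * Tensor(mask), self.weight, stride=self.stride, padding=self.pad)
        out = out * Tensor(ratio) + self.bias.reshape(1, -1, 1, 1) * Tensor(new_mask)
        return out, new_mask

    @property
    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]


@dataclass
class InpainterConfig:
    """Architecture, loss and optimizer settings for the UNet inpainter."""

    depth: int = 4
    base_channels: int = 16
    max_channels: int = 64
    valid_weight: float = 1.0
    hole_weight: float = 6.0  # printed rendering of the loss is ambiguous; see docs
    tv_weight: float = 0.1
    perceptual_weight: float = 0.05
    style_weight: float = 120.0
    lr: float = 5e-4
    finetune_lr: float = 9.5e-5
    steps: int = 200
    batch_size: int = 4
    seed: int = 0
    kernel_schedule: tuple[int, ...] = field(default=KERNEL_SCHEDULE)

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 8:
            raise ValueError("depth must be in 1..8")
        for w in (self.valid_weight, self.hole_weight, self.tv_weight,
                  self.perceptual_weight, self.style_weight):
            if w < 0:
                raise ValueError("loss weights must be non-negative")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2**i, self.max_channels) for i in range(self.depth)]


class PConvUNet:
    """Partial-convolution UNet for grayscale irregular-hole inpainting."""

    def __init__(self, cfg: InpainterConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.channels()
        self.encoder: list[PartialConv2d] = []
        cin = 1
        for i in range(cfg.depth):
            self.encoder.append(PartialConv2d(cin, ch[i], cfg.kernel_schedule[i], 2, rng))
            cin = ch[i]
        self.decoder: list[PartialConv2d] = []
        for i in reversed(range(cfg.depth)):
            skip = ch[i - 1] if i > 0 else 1
            self.decoder.append(PartialConv2d(ch[i] + skip, max(skip, cfg.base_channels), 3, 1, rng))
        self.head = PartialConv2d(max(1, cfg.base_channels), 1, 3, 1, rng)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in [*self.encoder, *self.decoder, self.head]:
            ps.extend(layer.params)
        return ps

    def forward(self, image: Tensor, mask: np.ndarray) -> Tensor:
        """Predict a full image from a masked (N,1,H,W) input; linear output."""
        feats: list[Tensor] = [image]
        masks: list[np.ndarray] = [mask]
        x, m = image, mask
        for enc in self.encoder:
            x, m = enc(x, m)
            x = x.relu()
            feats.append(x)
            masks.append(m)
        for i, dec in enumerate(self.decoder):
            x = upsample_nearest(x, 2)
            m = masks[-2 - i].copy()
            mu = np.repeat(np.repeat(masks[-1 - i], 2, axis=2), 2, axis=3)
            mu = mu[:, :, : m.shape[2], : m.shape[3]]
            x = _crop_to(x, m.shape[2], m.shape[3])
            x = concat([x, feats[-2 - i]], axis=1)
            m = np.maximum(m, mu)  # union of skip and upsampled masks
            x, m = dec(x, m)
            x = x.leaky_relu(0.2)
        x, m = self.head(x, m)
        return x

    def predict(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper around :meth:`forward` for one image."""
        t = self.forward(
            Tensor(image[None, None]), np.asarray(mask, dtype=float)[None, None]
        )
        return t.data[0, 0]


def _crop_to(x: Tensor, h: int, w: int) -> Tensor:
    if x.data.shape[2] == h and x.data.shape[3] == w:
        return x
    data = x.data[:, :, :h, :w]

    def back(g):
        out = np.zeros_like(x.data)
        out[:, :, :h, :w] = g
        return (out,)

    return Tensor(data, _parents=(x,), _backward=back)
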
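"""Five-stage convolutional feature hierarchy used as the comparison space
for multi-level unpredictability and for the encoding analysis.

The architecture mirrors the classical five-convolutional-stage image
hierarchies at desk scale.  Stage 1 is a bank of quadrature Gabor pairs
combined into phase-invariant oriented energy (complex-cell-like), so the
lowest level represents local orientation and scale rather than raw phase.
Stages 2-5 are strided random convolutions with zero-mean (band-pass-like)
kernels and ReLU: zero-mean kernels make deeper stages blind to spatially
homogeneous inputs and responsive to spatial structure, so successive
stages encode increasingly abstract, larger-scale inhomogeneity (texture
and arrangement) rather than local feature identity.  Weights are random
with a fixed seed — the metric's contract is the fixed hierarchical feature
space, not particular learned filters — and the extractor is pluggable, so
pretrained weights can be substituted.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

STAGE_KERNELS = (7, 5, 3, 3, 3)
STAGE_CHANNELS = (8, 16, 24, 32, 32)
N_STAGES = 5


def _gabor_pair(theta: float, wavelength: float, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Even/odd quadrature Gabor kernels, DC-corrected, jointly unit-norm."""
    ax = np.arange(k) - k // 2
    xx, yy = np.meshgrid(ax, ax)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx**2 + yy**2) / (2 * (0.4 * wavelength) ** 2))
    even = env * np.cos(2 * np.pi * u / wavelength)
    odd = env * np.sin(2 * np.pi * u / wavelength)
    even -= env * even.sum() / env.sum()
    norm = np.sqrt((even**2 + odd**2).sum())
    return even / norm, odd / norm


class FeatureHierarchy:
    """Fixed-weight 5-stage convolutional feature extractor.

    Parameters
    ----------
    seed
        Seed for the fixed random orientations, wavelengths and deep-stage
        weights.
    strides
        Per-stage downsampling factors; the defaults halve resolution at
        every stage (32-fold total).
    """

    def __init__(
        self,
        seed: int = 0,
        kernels: tuple[int, ...] = STAGE_KERNELS,
        channels: tuple[int, ...] = STAGE_CHANNELS,
        strides: tuple[int, ...] = (2, 2, 2, 2, 2),
        wavelength_range_px: tuple[float, float] = (4.0, 12.0),
    ):
        if not len(kernels) == len(channels) == len(strides):
            raise ValueError("stage descriptors must have equal length")
        rng = np.random.default_rng(seed)
        self.strides = strides
        even, odd = [], []
        for _ in range(channels[0]):
            theta = rng.uniform(0, np.pi)
            wl = rng.uniform(*wavelength_range_px)
            e, o = _gabor_pair(theta, wl, kernels[0])
            even.append(e)
            odd.append(o)
        self._w_even = Tensor(np.asarray(even)[:, None])
        self._w_odd = Tensor(np.asarray(odd)[:, None])
        self._k1 = kernels[0]
        self.weights: list[Tensor] = []
        cin = channels[0]
        for k, cout in zip(kernels[1:], channels[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
            w -= w.mean(axis=(2, 3), keepdims=True)  # band-pass: no DC response
            self.weights.append(Tensor(w))
            cin = cout

    @property
    def n_stages(self) -> int:
        return 1 + len(self.weights)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Autograd forward; input (N, 1, H, W), returns per-stage tensors."""
        e = conv2d(x, self._w_even, stride=self.strides[0], padding=self._k1 // 2)
        o = conv2d(x, self._w_odd, stride=self.strides[0], padding=self._k1 // 2)
        x = (e * e + o * o + 1e-12) ** 0.5
        out = [x]
        for w, s in zip(self.weights, self.strides[1:]):
            k = w.data.shape[-1]
            x = conv2d(x, w, stride=s, padding=k // 2).relu()
            out.append(x)
        return out

    def stages(self, image: np.ndarray) -> list[np.ndarray]:
        """Plain-numpy per-stage feature tensors for a 2-D grayscale image."""
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        ts = self.forward(Tensor(image[None, None]))
        return [t.data[0] for t in ts]
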
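"""Core value types shared across the pipeline.

All spatial quantities are expressed in degrees of visual angle; images carry
their own degrees-per-pixel scale so filters, masks and receptive fields can
be defined in stimulus coordinates rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Factor converting a Gaussian sigma to its full width at half maximum.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class StimulusImage:
    """Grayscale stimulus image with an angular pixel scale.

    Parameters
    ----------
    pixels
        2-D float array, luminance in [0, 1].
    deg_per_px
        Degrees of visual angle subtended by one pixel.
    """

    pixels: np.ndarray
    deg_per_px: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("stimulus image must be a 2-D grayscale array")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_deg(self) -> tuple[float, float]:
        """(height, width) of the image in degrees."""
        h, w = self.pixels.shape
        return h * self.deg_per_px, w * self.deg_per_px


@dataclass
class ReceptiveField:
    """Elliptical 2-D Gaussian receptive field in degrees of visual angle.

    ``center_x``/``center_y`` follow image coordinates: x along columns,
    y along rows, origin at the top-left pixel corner.  ``rho`` is the
    Pearson correlation between the fitted Gaussian surface and the smoothed
    response histogram it was fitted to, used downstream as a fit-quality
    criterion.
    """

    center_x: float
    center_y: float
    sigma_x: float
    sigma_y: float
    theta: float = 0.0
    amplitude: float = 1.0
    offset: float = 0.0
    rho: float = 1.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("receptive-field sigmas must be positive")
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def fwhm_x(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_x

    @property
    def fwhm_y(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_y

    @property
    def fwhm_diameter(self) -> float:
        """Diameter of the circle spanning the FWHM ellipse (its major axis)."""
        return max(self.fwhm_x, self.fwhm_y)

    @property
    def area_deg2(self) -> float:
        """Area of the FWHM ellipse in squared degrees."""
        return np.pi * (self.fwhm_x / 2.0) * (self.fwhm_y / 2.0)

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Gaussian surface amplitude at coordinates (x, y) in degrees."""
        ct, st = np.cos(self.theta), np.sin(self.theta)
        dx = np.asarray(x) - self.center_x
        dy = np.asarray(y) - self.center_y
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        return self.offset + self.amplitude * np.exp(
            -0.5 * ((u / self.sigma_x) ** 2 + (v / self.sigma_y) ** 2)
        )

    def fwhm_mask(self, image: StimulusImage) -> np.ndarray:
        """Boolean pixel mask of the FWHM ellipse on ``image``'s grid."""
        h, w = image.shape
        ys, xs = np.mgrid[0:h, 0:w]
        xs = (xs + 0.5) * image.deg_per_px
        ys = (ys + 0.5) * image.deg_per_px
        ct, st = np.cos(self.theta), np.sin(self.theta)
        dx = xs - self.center_x
        dy = ys - self.center_y
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        return (u / (self.fwhm_x / 2.0)) ** 2 + (v / (self.fwhm_y / 2.0)) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Generative parameters behind a synthetic session.

    ``kernels`` maps predictor names (design-matrix columns) to temporal
    coefficient kernels beta_j(t) on the 10-ms analysis grid, in units of
    fold change per standard deviation of the predictor.  Kernels are zero
    outside the stimulus-locked [0, 250] ms window by construction.
    """

    kernels: dict[str, np.ndarray]
    intercept: np.ndarray
    laminar_scale: float
    noise_sd: float
    seed: int
    time_ms: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 250.0, 10.0)
    )

    def __post_init__(self) -> None:
        if self.laminar_scale <= 0:
            raise ValueError("laminar_scale must be positive")
        n = len(self.time_ms)
        for name, k in self.kernels.items():
            k = np.asarray(k, dtype=float)
            if k.shape != (n,) or not np.all(np.isfinite(k)):
                raise ValueError(f"kernel {name!r} must be finite with {n} bins")
            self.kernels[name] = k
        self.intercept = np.asarray(self.intercept, dtype=float)
        if self.intercept.shape != (n,):
            raise ValueError("intercept kernel has wrong length")
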
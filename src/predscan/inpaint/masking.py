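"""Receptive-field masking for the inpainting analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import ReceptiveField, StimulusImage


@dataclass
class MaskedImage:
    """Image with the RF hole zeroed; mask convention 1 = known, 0 = hole."""

    image: StimulusImage
    mask: np.ndarray
    rf: ReceptiveField

    def __post_init__(self) -> None:
        if self.mask.shape != self.image.shape:
            raise ValueError("mask/image shape mismatch")
        if not (self.mask == 0).any():
            raise ValueError("hole area must be positive")

    @property
    def masked_pixels(self) -> np.ndarray:
        return self.image.pixels * self.mask


def mask_rf(image: StimulusImage, rf: ReceptiveField) -> MaskedImage:
    """Zero out the FWHM ellipse of ``rf`` and return the masked image.

    The hole must lie strictly inside the image (a hole touching the border
    would clip the comparison patch downstream).
    """
    hole = rf.fwhm_mask(image)
    if not hole.any():
        raise ValueError("receptive field does not cover any pixel")
    rows = np.flatnonzero(hole.any(axis=1))
    cols = np.flatnonzero(hole.any(axis=0))
    h, w = image.shape
    if rows[0] == 0 or cols[0] == 0 or rows[-1] == h - 1 or cols[-1] == w - 1:
        raise ValueError("receptive-field hole touches the image border")
    mask = (~hole).astype(float)
    masked = StimulusImage(image.pixels * mask, image.deg_per_px)
    return MaskedImage(masked, mask, rf)


def crop_rf_rectangle(
    image: StimulusImage, rf: ReceptiveField, scale: float = 1.5
) -> np.ndarray:
    """Square crop of side ``scale`` x the RF FWHM diameter, centred on the RF."""
    side_px = int(round(scale * rf.fwhm_diameter / image.deg_per_px))
    side_px = max(side_px, 2)
    cx = rf.center_x / image.deg_per_px
    cy = rf.center_y / image.deg_per_px
    x0 = int(round(cx - side_px / 2))
    y0 = int(round(cy - side_px / 2))
    h, w = image.shape
    if x0 < 0 or y0 < 0 or x0 + side_px > w or y0 + side_px > h:
        raise ValueError("comparison rectangle exceeds image bounds")
    return image.pixels[y0 : y0 + side_px, x0 : x0 + side_px]
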
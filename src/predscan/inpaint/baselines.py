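"""Baseline inpainters and the compositing contract.

Three classical baselines plug into the same :func:`inpaint` entry point as
the trained UNet: the harmonic inpainter solves the Laplace equation over
the hole with Dirichlet boundary values from the known pixels (the smooth
membrane interpolant, exact for affine luminance fields); the mean-fill
inpainter replaces the hole with the mean of the known pixels; and the
directional inpainter propagates structure along the surround's coherence
orientation (estimated from the structure tensor), interpolating each hole
pixel between the known pixels it meets along that direction — which
continues oriented patterns such as gratings through the hole.  Whatever
the predictor, pixels outside the hole are composited back unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from ..types import StimulusImage
from .masking import MaskedImage


def harmonic_fill(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill hole pixels (mask == 0) by solving the discrete Laplace equation."""
    pixels = np.asarray(pixels, dtype=float)
    hole = np.asarray(mask) == 0
    if not hole.any():
        return pixels.copy()
    h, w = pixels.shape
    idx = -np.ones((h, w), dtype=int)
    ys, xs = np.nonzero(hole)
    idx[ys, xs] = np.arange(len(ys))
    rows, cols, vals = [], [], []
    rhs = np.zeros(len(ys))
    for p, (y, x) in enumerate(zip(ys, xs)):
        rows.append(p); cols.append(p); vals.append(4.0)
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                rows.append(p); cols.append(p); vals.append(-1.0)  # mirror boundary
            elif hole[ny, nx]:
                rows.append(p); cols.append(idx[ny, nx]); vals.append(-1.0)
            else:
                rhs[p] += pixels[ny, nx]
    A = coo_matrix((vals, (rows, cols)), shape=(len(ys), len(ys))).tocsr()
    sol = spsolve(A, rhs)
    out = pixels.copy()
    out[ys, xs] = sol
    return out


def mean_fill(pixels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill hole pixels with the mean of the known pixels."""
    pixels = np.asarray(pixels, dtype=float)
    known = np.asarray(mask) == 1
    out = pixels.copy()
    out[~known] = pixels[known].mean()
    return out


def coherence_direction(pixels: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Dominant coherence direction (unit vector) of the known region.

    The direction of least intensity variation: the eigenvector of the
    structure tensor (summed over known pixels) with the smaller eigenvalue.
    """
    from scipy.ndimage import binary_erosion, sobel

    pixels = np.asarray(pixels, dtype=float)
    known = np.asarray(mask) == 1
    interior = binary_erosion(known, iterations=2)
    gx = sobel(pixels, axis=1)
    gy = sobel(pixels, axis=0)
    jxx = float((gx[interior] ** 2).sum())
    jyy = float((gy[interior] ** 2).sum())
    jxy = float((gx[interior] * gy[interior]).sum())
    J = np.array([[jxx, jxy], [jxy, jyy]])
    evals, evecs = np.linalg.eigh(J)
    v = evecs[:, 0]  # smallest eigenvalue: least variation
    return float(v[0]), float(v[1])


def directional_fill(
    pixels: np.ndarray,
    mask: np.ndarray,
    direction: tuple[float, float] | None = None,
) -> np.ndarray:
    """Fill hole pixels by 1-D interpolation along the coherence direction.

    For each hole pixel, march along +/- the direction until a known pixel
    is met on each side and interpolate linearly by distance (one-sided
    value if only one side reaches a known pixel).
    """
    pixels = np.asarray(pixels, dtype=float)
    hole = np.asarray(mask) == 0
    if not hole.any():
        return pixels.copy()
    if direction is None:
        direction = coherence_direction(pixels, mask)
    vx, vy = direction
    norm = np.hypot(vx, vy)
    if norm == 0:
        raise ValueError("zero coherence direction")
    vx, vy = vx / norm, vy / norm
    h, w = pixels.shape
    out = pixels.copy()
    ys, xs = np.nonzero(hole)
    max_steps = int(2 * max(h, w))

    def march(y, x, sy, sx):
        for step in range(1, max_steps):
            yy = int(round(y + sy * step))
            xx = int(round(x + sx * step))
            if not (0 <= yy < h and 0 <= xx < w):
                return None
            if not hole[yy, xx]:
                return step, pixels[yy, xx]
        return None

    for y, x in zip(ys, xs):
        fwd = march(y, x, vy, vx)
        bwd = march(y, x, -vy, -vx)
        if fwd is None and bwd is None:
            out[y, x] = pixels[~hole].mean()
        elif fwd is None:
            out[y, x] = bwd[1]
        elif bwd is None:
            out[y, x] = fwd[1]
        else:
            d1, p1 = fwd
            d2, p2 = bwd
            out[y, x] = (d2 * p1 + d1 * p2) / (d1 + d2)
    return out


def inpaint(masked: MaskedImage, model=None, baseline: str | None = None) -> StimulusImage:
    """Inpaint the hole and composite the prediction into the original image.

    Exactly one of ``model`` (an object with ``predict(pixels, mask)``) or
    ``baseline`` ('harmonic', 'mean_fill' or 'directional') must be given.
    Pixels outside the hole are returned bit-identical to the input.
    """
    if (model is None) == (baseline is None):
        raise ValueError("provide exactly one of model or baseline")
    px = masked.image.pixels
    mask = masked.mask
    if baseline is not None:
        try:
            fill = {"harmonic": harmonic_fill, "mean_fill": mean_fill,
                    "directional": directional_fill}[baseline]
        except KeyError:
            raise ValueError(f"unknown baseline inpainter {baseline!r}") from None
        pred = fill(px, mask)
    else:
        pred = model.predict(px, mask)
        if pred.shape != px.shape:
            raise ValueError("model prediction shape mismatch")
    out = np.where(mask == 1, px, pred)
    return StimulusImage(out, masked.image.deg_per_px)
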
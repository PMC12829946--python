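"""Receptive-field mapping from Gabor trials, unit selection, and laminar
classification.

Receptive fields are estimated by fitting an elliptical 2-D Gaussian to the
Gaussian-smoothed histogram of responses across Gabor probe positions.  Units
enter the analysis only if the fitted FWHM ellipse lies fully on screen, its
area is between 150 and 750 deg^2 (inclusive), and the fit quality rho
(Pearson correlation between fitted surface and smoothed histogram) strictly
exceeds 0.7.  Units are classified as superficial (putative layers 1-3) or
deep (layers 5-6); layer 4 is excluded from the laminar contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import curve_fit

from .types import FWHM_PER_SIGMA, ReceptiveField

logger = logging.getLogger(__name__)

AREA_MIN_DEG2 = 150.0
AREA_MAX_DEG2 = 750.0
RHO_MIN = 0.7

VISUAL_AREAS = ("V1", "VISl", "VISrl", "VISal", "VISpm", "VISam")


@dataclass
class UnitRecord:
    unit_id: int
    animal_id: int
    area: str
    putative_layer: int
    rf: ReceptiveField
    pref_sf: float
    pref_ori: float

    @property
    def layer_label(self) -> str:
        return classify_layer(self.putative_layer)


def classify_layer(putative_layer: int) -> str:
    """Map a putative cortical layer to 'superficial' (1-3), 'deep' (5-6) or 'other'."""
    if putative_layer not in range(1, 7):
        raise ValueError(f"putative layer must be in 1..6, got {putative_layer}")
    if putative_layer <= 3:
        return "superficial"
    if putative_layer >= 5:
        return "deep"
    return "other"


def layer_from_depth(depth_fraction: float) -> int:
    """Optional helper: fractional cortical depth (0 pia, 1 white matter) to layer."""
    if not 0.0 <= depth_fraction <= 1.0:
        raise ValueError("depth fraction must be in [0, 1]")
    bounds = (0.07, 0.29, 0.37, 0.50, 0.80)  # cumulative layer boundaries
    return int(np.searchsorted(bounds, depth_fraction) + 1)


def rf_histogram(
    gabor_trials: pd.DataFrame,
    smooth_sd_cells: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed 2-D histogram of mean evoked counts per Gabor position.

    ``gabor_trials`` needs columns ``x_deg``, ``y_deg``, ``count`` (one row
    per presentation).  Returns ``(hist, xs, ys)`` where ``hist[i, j]`` is the
    smoothed mean count at ``(ys[i], xs[j])``.  Positions with zero trials
    raise an error listing them.  Smoothing uses a normalized Gaussian kernel
    with symmetric (reflect) boundaries, which conserves the total summed
    response.
    """
    xs = np.unique(gabor_trials["x_deg"].to_numpy())
    ys = np.unique(gabor_trials["y_deg"].to_numpy())
    mean = (
        gabor_trials.groupby(["y_deg", "x_deg"])["count"].mean().unstack(fill_value=np.nan)
    )
    mean = mean.reindex(index=ys, columns=xs)
    if mean.isna().any().any():
        missing = [
            (float(y), float(x))
            for y in ys
            for x in xs
            if np.isnan(mean.loc[y, x])
        ]
        raise ValueError(f"gabor positions with zero trials: {missing}")
    hist = mean.to_numpy(dtype=float)
    if smooth_sd_cells > 0:
        hist = gaussian_filter(hist, smooth_sd_cells, mode="reflect")
    return hist, xs, ys


def _gauss2d(coords, amp, cx, cy, sx, sy, theta, offset):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (x - cx) + st * (y - cy)
    v = -st * (x - cx) + ct * (y - cy)
    return offset + amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def fit_rf_gaussian(
    hist: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    smooth_sd_cells: float = 1.0,
    deconvolve_smoothing: bool = True,
) -> ReceptiveField:
    """Nonlinear least-squares fit of an elliptical 2-D Gaussian + offset.

    Multi-starts from the grid argmax and from the response centroid; returns
    the best start with ``converged=False`` if neither converges.  Because the
    histogram is smoothed before fitting, the fitted widths include the
    smoothing kernel's variance; with ``deconvolve_smoothing`` the kernel
    variance (``smooth_sd_cells`` in grid cells) is subtracted from the fitted
    sigmas so the reported receptive field refers to the unsmoothed map.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape[0] < 5 or hist.shape[1] < 5:
        raise ValueError("histogram grid must be at least 5x5")
    if np.ptp(hist) == 0:
        raise ValueError("histogram is constant; cannot fit a receptive field")

    X, Y = np.meshgrid(xs, ys)
    coords = (X.ravel(), Y.ravel())
    z = hist.ravel()
    dx = float(np.mean(np.diff(xs)))
    offset0 = float(np.percentile(hist, 10))
    amp0 = float(hist.max() - offset0)

    iy, ix = np.unravel_index(np.argmax(hist), hist.shape)
    w = np.clip(hist - offset0, 0, None)
    cx_cen = float((X * w.reshape(hist.shape)).sum() / max(w.sum(), 1e-12))
    cy_cen = float((Y * w.reshape(hist.shape)).sum() / max(w.sum(), 1e-12))
    starts = [
        (amp0, float(xs[ix]), float(ys[iy]), 2 * dx, 2 * dx, 0.0, offset0),
        (amp0, cx_cen, cy_cen, 2 * dx, 2 * dx, 0.0, offset0),
    ]

    span_x = xs[-1] - xs[0]
    span_y = ys[-1] - ys[0]
    bounds = (
        [0.0, xs[0] - span_x, ys[0] - span_y, 0.1 * dx, 0.1 * dx, -np.pi, -np.inf],
        [np.inf, xs[-1] + span_x, ys[-1] + span_y, 2 * span_x, 2 * span_y, np.pi, np.inf],
    )

    best, best_sse, converged = None, np.inf, False
    for p0 in starts:
        try:
            popt, _ = curve_fit(_gauss2d, coords, z, p0=p0, bounds=bounds, maxfev=5000)
            sse = float(np.sum((_gauss2d(coords, *popt) - z) ** 2))
            if sse < best_sse:
                best, best_sse, converged = popt, sse, True
        except RuntimeError:
            if best is None:
                best = np.asarray(p0, dtype=float)
    assert best is not None
    amp, cx, cy, sx, sy, theta, offset = best
    fit_surface = _gauss2d(coords, *best)
    rho = float(np.corrcoef(fit_surface, z)[0, 1]) if np.ptp(fit_surface) > 0 else 0.0

    if deconvolve_smoothing and smooth_sd_cells > 0:
        smooth_sd_deg = smooth_sd_cells * dx
        sx = float(np.sqrt(max(sx**2 - smooth_sd_deg**2, (0.1 * dx) ** 2)))
        sy = float(np.sqrt(max(sy**2 - smooth_sd_deg**2, (0.1 * dx) ** 2)))
    return ReceptiveField(
        center_x=float(cx), center_y=float(cy),
        sigma_x=abs(float(sx)), sigma_y=abs(float(sy)),
        theta=float(theta), amplitude=float(amp), offset=float(offset),
        rho=float(np.clip(rho, -1.0, 1.0)), converged=converged,
    )


def rf_on_screen(rf: ReceptiveField, screen_deg: tuple[float, float]) -> bool:
    """True if the FWHM ellipse lies entirely within the (height, width) extent."""
    h, w = screen_deg
    r = rf.fwhm_diameter / 2.0  # conservative circumscribed circle
    return (
        rf.center_x - r >= 0
        and rf.center_x + r <= w
        and rf.center_y - r >= 0
        and rf.center_y + r <= h
    )


def select_units(
    units: list[UnitRecord], screen_deg: tuple[float, float]
) -> list[UnitRecord]:
    """Apply the selection rules: on-screen FWHM ellipse, area in
    [150, 750] deg^2 (inclusive bounds), rho strictly > 0.7."""
    kept = [
        u
        for u in units
        if rf_on_screen(u.rf, screen_deg)
        and AREA_MIN_DEG2 <= u.rf.area_deg2 <= AREA_MAX_DEG2
        and u.rf.rho > RHO_MIN
    ]
    if not kept:
        logger.warning("unit selection kept 0 of %d units", len(units))
    return kept


def units_table(units: list[UnitRecord]) -> pd.DataFrame:
    rows = []
    for u in units:
        rows.append(
            dict(
                unit_id=u.unit_id, animal_id=u.animal_id, area=u.area,
                putative_layer=u.putative_layer, layer_label=u.layer_label,
                center_x=u.rf.center_x, center_y=u.rf.center_y,
                sigma_x=u.rf.sigma_x, sigma_y=u.rf.sigma_y,
                theta=u.rf.theta, area_deg2=u.rf.area_deg2, rho=u.rf.rho,
                pref_sf=u.pref_sf, pref_ori=u.pref_ori,
            )
        )
    return pd.DataFrame(rows)


__all__ = [
    "AREA_MAX_DEG2", "AREA_MIN_DEG2", "FWHM_PER_SIGMA", "RHO_MIN",
    "ReceptiveField", "UnitRecord", "VISUAL_AREAS", "classify_layer",
    "fit_rf_gaussian", "layer_from_depth", "rf_histogram", "rf_on_screen",
    "select_units", "units_table",
]
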
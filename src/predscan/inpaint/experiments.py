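"""Synthetic-stimulus validation of the unpredictability metric.

Two parametric experiments probe the mask -> inpaint -> multi-level distance
pipeline with 384x384 stimuli:

* End-stopping: a horizontal striped bar either confined to the central RF
  mask ('no_context'), extending 20% beyond it ('some_context'), or spanning
  the full image width ('full_context').  More surround context makes the
  masked patch more predictable, so per-level normalized unpredictability
  should fall from no -> some -> full context.
* Feature-level mismatch: the surround is a fixed vertical grating and the
  hole's ground truth is either the continuous grating ('match'), an
  orthogonal grating ('shifted'), or the same grating with smoothly varying
  phase noise ('noisy').  The masked input — and hence the reconstruction —
  is identical across conditions, isolating how each mismatch type loads on
  low- versus high-level distances.

Per-level losses are normalized by the maximum across conditions at that
level, so each level's largest loss is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..types import ReceptiveField, StimulusImage
from .baselines import inpaint
from .features import FeatureHierarchy
from .masking import mask_rf
from .unpredictability import multilevel_unpredictability

SIZE_PX = 384
DEG_PER_PX = 120.0 / SIZE_PX  # full-field stimulus spanning 120 degrees
RF_FWHM_PX = 96  # central circular receptive field


@dataclass
class ExperimentConfig:
    size_px: int = SIZE_PX
    deg_per_px: float = DEG_PER_PX
    rf_fwhm_px: int = RF_FWHM_PX
    extractor_seed: int = 0
    baseline: str | None = "harmonic"
    model: object | None = None
    # end-stopping bar
    bar_height_frac: float = 0.5     # bar height relative to the RF diameter
    stripe_period_px: int = 24
    stripe_lo: float = 0.55
    stripe_hi: float = 0.95
    background: float = 0.35
    # mismatch gratings: the 'noisy' condition uses rough, strong phase
    # noise, i.e. a genuinely scrambled texture that keeps the carrier
    # orientation while destroying its spatial arrangement
    grating_period_px: int = 16
    grating_contrast: float = 0.45
    grating_mean: float = 0.5
    phase_noise_sd: float = 2.5      # radians
    phase_noise_scale_px: float = 4.0
    mismatch_baseline: str = "directional"
    seed: int = 0

    def receptive_field(self) -> ReceptiveField:
        sigma_deg = self.rf_fwhm_px * self.deg_per_px / (2 * np.sqrt(2 * np.log(2)))
        c = self.size_px / 2 * self.deg_per_px
        return ReceptiveField(center_x=c, center_y=c, sigma_x=sigma_deg, sigma_y=sigma_deg)


def _normalize(per_condition: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    names = list(per_condition)
    stack = np.stack([per_condition[n] for n in names])
    peak = stack.max(axis=0)
    peak[peak == 0] = 1.0
    return {n: per_condition[n] / peak for n in names}


def _run_metric(image: StimulusImage, cfg: ExperimentConfig, extractor: FeatureHierarchy,
                rf: ReceptiveField) -> np.ndarray:
    masked = mask_rf(image, rf)
    filled = inpaint(masked, model=cfg.model, baseline=cfg.baseline if cfg.model is None else None)
    return multilevel_unpredictability(image, filled, rf, extractor).levels


def _striped_bar_image(cfg: ExperimentConfig, bar_half_width_px: float) -> StimulusImage:
    n = cfg.size_px
    px = np.full((n, n), cfg.background)
    cy = cx = n / 2
    half_h = cfg.bar_height_frac * cfg.rf_fwhm_px / 2
    ys, xs = np.mgrid[0:n, 0:n]
    in_bar = (np.abs(ys + 0.5 - cy) <= half_h) & (np.abs(xs + 0.5 - cx) <= bar_half_width_px)
    stripes = ((ys // (cfg.stripe_period_px // 2)) % 2).astype(float)
    px[in_bar] = np.where(stripes[in_bar] > 0, cfg.stripe_hi, cfg.stripe_lo)
    return StimulusImage(px, cfg.deg_per_px)


def endstopping_experiment(cfg: ExperimentConfig | None = None) -> dict[str, np.ndarray]:
    """Normalized per-level unpredictability for the three bar-context stimuli."""
    cfg = cfg or ExperimentConfig()
    rf = cfg.receptive_field()
    extractor = FeatureHierarchy(seed=cfg.extractor_seed)
    r = cfg.rf_fwhm_px / 2
    widths = {
        "no_context": 0.9 * r,
        "some_context": 1.2 * r,
        "full_context": cfg.size_px,
    }
    raw = {}
    for name, hw in widths.items():
        image = _striped_bar_image(cfg, hw)
        raw[name] = _run_metric(image, cfg, extractor, rf)
    return _normalize(raw)


def _grating(n: int, period_px: float, mean: float, contrast: float,
             vertical: bool, phase: np.ndarray | float = 0.0) -> np.ndarray:
    ys, xs = np.mgrid[0:n, 0:n]
    coord = xs if vertical else ys
    return mean + contrast * np.sin(2 * np.pi * coord / period_px + phase)


def mismatch_experiment(cfg: ExperimentConfig | None = None) -> dict[str, np.ndarray]:
    """Normalized per-level losses for match / shifted / noisy hole contents.

    All three ground truths share the identical surround, so the masked
    input and the reconstruction are the same; each condition's loss is the
    distance between that single reconstruction and its ground truth.
    """
    cfg = cfg or ExperimentConfig()
    rf = cfg.receptive_field()
    extractor = FeatureHierarchy(seed=cfg.extractor_seed)
    n = cfg.size_px

    base = _grating(n, cfg.grating_period_px, cfg.grating_mean, cfg.grating_contrast, True)
    hole = rf.fwhm_mask(StimulusImage(base, cfg.deg_per_px))

    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(size=(n, n))
    noise = gaussian_filter(noise, cfg.phase_noise_scale_px)
    noise *= cfg.phase_noise_sd / noise.std()

    gts = {
        "match": base,
        "shifted": np.where(
            hole, _grating(n, cfg.grating_period_px, cfg.grating_mean, cfg.grating_contrast, False), base
        ),
        "noisy": np.where(
            hole, _grating(n, cfg.grating_period_px, cfg.grating_mean, cfg.grating_contrast, True, noise), base
        ),
    }

    masked = mask_rf(StimulusImage(base, cfg.deg_per_px), rf)
    filled = inpaint(
        masked, model=cfg.model,
        baseline=cfg.mismatch_baseline if cfg.model is None else None,
    )

    raw = {
        name: multilevel_unpredictability(
            StimulusImage(gt, cfg.deg_per_px), filled, rf, extractor
        ).levels
        for name, gt in gts.items()
    }
    return _normalize(raw)
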
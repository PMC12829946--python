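"""Synthetic stimuli, sessions, units and responses with known ground truth.

The generators emulate the logical structure of a natural-scenes
electrophysiology session — a stimulus set shown for 250 ms per trial over
repeated pseudo-random sweeps, per-unit 2-D Gaussian receptive fields mapped
with Gabor probes, eye traces with injected blinks and positional outliers,
and normalized firing rates produced by a time-resolved linear model with
predictor-specific temporal kernels.  Every generator is a pure function of
its seed.

Temporal coefficient kernels are truncated Gaussians with configurable peak
and width; by default the contrast kernel peaks at 70 ms and the
unpredictability kernel at 100 ms, so the predictability modulation arrives
later than the contrast modulation, and kernel amplitudes are set so the
mean coefficient in the 75-150 ms report window equals a requested value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regression import PREDICTABILITY_LEVELS
from .responses import TIME_MS, TRIAL_MS
from .types import GroundTruth, ReceptiveField, StimulusImage

IMAGE_KINDS = ("pink_noise", "texture", "grating", "mixed")
DEFAULT_WINDOW_MS = (75.0, 150.0)


# -- images ---------------------------------------------------------------

def _rescale01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(size=(n, n))
    f = np.fft.fftfreq(n)
    radius = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    with np.errstate(divide="ignore"):
        amp = np.where(radius > 0, 1.0 / np.maximum(radius, 1e-12), 0.0)
    spec = np.fft.fft2(white) * amp
    return _rescale01(np.real(np.fft.ifft2(spec)))


def _grating_image(n: int, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, np.pi)
    period = rng.uniform(n / 16, n / 3)
    phase = rng.uniform(0, 2 * np.pi)
    ys, xs = np.mgrid[0:n, 0:n]
    u = xs * np.cos(theta) + ys * np.sin(theta)
    return 0.5 + 0.5 * np.sin(2 * np.pi * u / period + phase)


def _texture_image(n: int, rng: np.random.Generator) -> np.ndarray:
    """Oriented bandpass noise: white noise filtered by a random Gabor."""
    from scipy.signal import fftconvolve

    theta = rng.uniform(0, np.pi)
    wavelength = rng.uniform(n / 24, n / 6)
    sigma = 0.6 * wavelength
    half = int(2 * sigma)
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    kern = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) * np.cos(2 * np.pi * u / wavelength)
    noise = rng.normal(size=(n, n))
    return _rescale01(fftconvolve(noise, kern, mode="same"))


def gen_images(
    n: int, kind: str, size_px: int, deg_per_px: float, seed: int
) -> list[StimulusImage]:
    """Generate ``n`` grayscale stimuli in [0, 1] of the requested kind."""
    if kind not in IMAGE_KINDS:
        raise ValueError(f"unknown image kind {kind!r}; expected one of {IMAGE_KINDS}")
    if n < 1:
        raise ValueError("need n >= 1")
    if size_px < 64:
        raise ValueError("size_px must be at least 64")
    rng = np.random.default_rng(seed)
    makers = {
        "pink_noise": _pink_noise,
        "grating": _grating_image,
        "texture": _texture_image,
    }
    out = []
    for _ in range(n):
        k = rng.choice(list(makers)) if kind == "mixed" else kind
        out.append(StimulusImage(makers[k](size_px, rng), deg_per_px))
    return out


def write_image_stack(images: list[StimulusImage], directory: str | Path) -> Path:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        name = f"stimulus_{i:04d}.png"
        iio.imwrite(directory / name, (np.clip(im.pixels, 0, 1) * 255).astype(np.uint8))
        rows.append(dict(stimulus_id=i, file=name, deg_per_px=im.deg_per_px))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# -- sessions -------------------------------------------------------------

@dataclass
class SessionTable:
    """Trial, running-speed and eye-trace records for one synthetic session."""

    trials: pd.DataFrame   # trial_id, stimulus_id, rep, onset_s
    running: pd.DataFrame  # time_s, speed_cm_s
    eye: pd.DataFrame      # time_s, x_deg, y_deg, blink
    injected: pd.DataFrame  # trial_id, kind in {blink, outlier} (generator log)


def gen_session(
    images: list[StimulusImage] | int,
    n_reps: int,
    blink_rate: float = 0.0,
    seed: int = 0,
    iti_s: float = 0.0,
    sample_hz: float = 30.0,
) -> SessionTable:
    """Pseudo-random trial order with running and eye traces.

    ``blink_rate`` is the per-trial contamination probability, split evenly
    between blink trials and eye-position excursions of 5 clean trial-mean
    SDs.  The margin is chosen so the session-level 2-SD filter flags the
    injected outliers deterministically even though the outliers themselves
    inflate the session SD (to at most ~1.5x clean at the injection rates
    used) and the trial's own mean wanders by ~1 SD.  The generator log in
    ``injected`` records exactly which trials were contaminated.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_images = images if isinstance(images, int) else len(images)
    rng = np.random.default_rng(seed)
    dur = TRIAL_MS / 1000.0 + iti_s

    rows = []
    tid = 0
    for rep in range(n_reps):
        for sid in rng.permutation(n_images):
            rows.append(dict(trial_id=tid, stimulus_id=int(sid), rep=rep, onset_s=tid * dur))
            tid += 1
    trials = pd.DataFrame(rows)

    end_s = tid * dur + 1.0
    t = np.arange(0.0, end_s, 1.0 / sample_hz)
    speed = np.abs(np.cumsum(rng.normal(0, 1.0, len(t))) * 0.2 + 5.0)
    running = pd.DataFrame(dict(time_s=t, speed_cm_s=speed))

    x = rng.normal(0.0, 1.0, len(t))
    y = rng.normal(0.0, 1.0, len(t))
    blink = np.zeros(len(t), dtype=bool)

    # trial-mean SD of clean traces, used to scale the injected excursions
    per_trial = np.clip(((t[None, :] >= trials["onset_s"].to_numpy()[:, None])
                         & (t[None, :] < trials["onset_s"].to_numpy()[:, None] + TRIAL_MS / 1000.0)), 0, 1)
    denom = per_trial.sum(axis=1)
    mean_x = (per_trial @ x) / np.maximum(denom, 1)
    sd_trial = mean_x.std()

    inj = []
    for tr in trials.itertuples():
        u = rng.uniform()
        sel = (t >= tr.onset_s) & (t < tr.onset_s + TRIAL_MS / 1000.0)
        if u < blink_rate / 2.0:
            blink[sel] = True
            inj.append(dict(trial_id=tr.trial_id, kind="blink"))
        elif u < blink_rate:
            sign = rng.choice([-1.0, 1.0])
            axis = rng.choice(["x", "y"])
            if axis == "x":
                x[sel] += sign * 5.0 * sd_trial
            else:
                y[sel] += sign * 5.0 * sd_trial
            inj.append(dict(trial_id=tr.trial_id, kind="outlier"))
    eye = pd.DataFrame(dict(time_s=t, x_deg=x, y_deg=y, blink=blink))
    return SessionTable(trials, running, eye, pd.DataFrame(inj, columns=["trial_id", "kind"]))


# -- receptive-field mapping trials ---------------------------------------

def gen_gabor_mapping_trials(
    rf: ReceptiveField,
    xs_deg: np.ndarray,
    ys_deg: np.ndarray,
    rate0: float = 2.0,
    amplitude: float = 20.0,
    n_per_pos: int = 45,
    duration_s: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson spike counts per Gabor probe position.

    Expected count at position (x, y) is ``(rate0 + amplitude * G(x, y)) *
    duration`` with G the unit-amplitude RF Gaussian.  The RF centre must
    lie inside the probe grid.
    """
    xs_deg = np.asarray(xs_deg, dtype=float)
    ys_deg = np.asarray(ys_deg, dtype=float)
    if not (xs_deg.min() <= rf.center_x <= xs_deg.max()
            and ys_deg.min() <= rf.center_y <= ys_deg.max()):
        raise ValueError("receptive field centre lies outside the probe grid")
    rng = np.random.default_rng(seed)
    rows = []
    for y in ys_deg:
        for x in xs_deg:
            g = (rf.evaluate(x, y) - rf.offset) / rf.amplitude
            lam = (rate0 + amplitude * g) * duration_s
            counts = rng.poisson(lam, size=n_per_pos)
            for c in counts:
                rows.append(dict(x_deg=float(x), y_deg=float(y), count=int(c)))
    return pd.DataFrame(rows)


# -- populations -----------------------------------------------------------

def gen_population(
    n_animals: int = 8,
    units_per_animal: int = 30,
    seed: int = 0,
    area: str = "V1",
    screen_deg: tuple[float, float] = (120.0, 120.0),
    sigma_range_deg: tuple[float, float] = (6.0, 10.0),
) -> pd.DataFrame:
    """Unit table with animals, alternating superficial/deep layers and RFs."""
    rng = np.random.default_rng(seed)
    rows = []
    uid = 0
    for a in range(n_animals):
        for k in range(units_per_animal):
            sigma = rng.uniform(*sigma_range_deg)
            margin = 2.0 * sigma * 2.3548  # keep FWHM ellipse and crop on screen
            rows.append(
                dict(
                    unit_id=uid,
                    animal_id=a,
                    area=area,
                    putative_layer=2 if k % 2 == 0 else 5,
                    layer_label="superficial" if k % 2 == 0 else "deep",
                    center_x=rng.uniform(margin, screen_deg[1] - margin),
                    center_y=rng.uniform(margin, screen_deg[0] - margin),
                    sigma_deg=sigma,
                    pref_sf=float(rng.choice([0.02, 0.04, 0.08, 0.16, 0.32])),
                    pref_ori=float(rng.choice(np.arange(8) * np.pi / 8)),
                )
            )
            uid += 1
    return pd.DataFrame(rows)


# -- ground truth and responses -------------------------------------------

def truncated_gaussian_kernel(
    peak_ms: float, width_ms: float, time_ms: np.ndarray = TIME_MS,
    support_sd: float = 2.5,
) -> np.ndarray:
    """Unit-amplitude Gaussian bump, zero beyond ``support_sd`` widths."""
    t = np.asarray(time_ms, dtype=float)
    k = np.exp(-0.5 * ((t - peak_ms) / width_ms) ** 2)
    k[np.abs(t - peak_ms) > support_sd * width_ms] = 0.0
    return k


def scale_kernel_to_window(
    kernel: np.ndarray,
    target_window_mean: float,
    time_ms: np.ndarray = TIME_MS,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> np.ndarray:
    """Scale a kernel so its mean over the report window equals the target."""
    sel = (time_ms >= window_ms[0]) & (time_ms <= window_ms[1])
    m = kernel[sel].mean()
    if m == 0:
        raise ValueError("kernel vanishes inside the report window")
    return kernel * (target_window_mean / m)


def make_ground_truth(
    beta_unpred_window: float = 0.08,
    beta_contrast_window: float = 0.20,
    unpred_peak_ms: float = 100.0,
    contrast_peak_ms: float = 70.0,
    kernel_width_ms: float = 18.0,
    laminar_scale: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    unpred_column: str = "overall",
    contrast_column: str = "CEpref",
    extra_kernels: dict[str, np.ndarray] | None = None,
) -> GroundTruth:
    """Default generative truth: a later unpredictability kernel (peak 100 ms)
    and an earlier contrast kernel (peak 70 ms), each scaled so its 75-150 ms
    window mean equals the requested value."""
    kernels: dict[str, np.ndarray] = {}
    if beta_contrast_window != 0.0:
        kernels[contrast_column] = scale_kernel_to_window(
            truncated_gaussian_kernel(contrast_peak_ms, kernel_width_ms),
            beta_contrast_window,
        )
    if beta_unpred_window != 0.0:
        kernels[unpred_column] = scale_kernel_to_window(
            truncated_gaussian_kernel(unpred_peak_ms, kernel_width_ms),
            beta_unpred_window,
        )
    if extra_kernels:
        kernels.update(extra_kernels)
    intercept = 1.2 * truncated_gaussian_kernel(80.0, 30.0)
    return GroundTruth(
        kernels=kernels, intercept=intercept, laminar_scale=laminar_scale,
        noise_sd=noise_sd, seed=seed,
    )


def gen_feature_table(
    n_images: int,
    n_chunks: int = 5,
    seed: int = 0,
    unpred_contrast_corr: float = 0.35,
) -> pd.DataFrame:
    """Synthetic per-(image, chunk) regressor table with realistic structure.

    Image-level features load on a shared latent (natural images make
    contrast statistics and predictability correlated); running speed varies
    by chunk.  Columns match the design-matrix names, including per-level
    unpredictability d1..d5 correlated with the overall estimate.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=n_images)

    def load(lam: float) -> np.ndarray:
        return lam * latent + np.sqrt(1 - lam**2) * rng.normal(size=n_images)

    cols: dict[str, np.ndarray] = {}
    for i, lam in enumerate((0.6, 0.55, 0.5, 0.45, 0.4)):
        cols[f"CE{i + 1}"] = load(lam)
    for i, lam in enumerate((0.3, 0.3, 0.25, 0.25, 0.2)):
        cols[f"SC{i + 1}"] = load(lam)
    cols["CEpref"] = load(0.65)
    cols["CV"] = load(0.2)
    cols["CEpref_m30"] = load(0.5)
    cols["CEpref_p30"] = load(0.5)
    cols["RMS"] = load(0.55)
    overall = unpred_contrast_corr * latent + np.sqrt(1 - unpred_contrast_corr**2) * rng.normal(size=n_images)
    cols["overall"] = overall
    for i, lam in enumerate((0.55, 0.65, 0.75, 0.85, 0.9)):
        cols[f"d{i + 1}"] = lam * overall + np.sqrt(1 - lam**2) * rng.normal(size=n_images)

    img = pd.DataFrame(cols)
    img["stimulus_id"] = np.arange(n_images)
    rows = img.loc[np.repeat(np.arange(n_images), n_chunks)].reset_index(drop=True)
    rows["chunk"] = np.tile(np.arange(n_chunks), n_images)
    rows["v"] = np.abs(rng.normal(8.0, 4.0, size=len(rows)))
    return rows


def gen_responses(
    design: pd.DataFrame,
    truth: GroundTruth,
    layer_label: str = "deep",
    rng: np.random.Generator | None = None,
    smooth_noise: bool = True,
) -> np.ndarray:
    """Fold-change responses y[obs, bin] from the time-resolved linear model.

    Predictors are standardized within the design before applying the
    kernels, so kernel amplitudes are in fold change per SD.  The laminar
    scale multiplies every unpredictability kernel for superficial units.
    The residual is white noise of SD ``truth.noise_sd`` passed through the
    same 30-ms (3-bin) moving average the rate pipeline applies, so the
    generated responses share the pipeline's temporal autocorrelation;
    ``smooth_noise=False`` keeps the residual white.
    """
    from .responses import moving_average_truncated

    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_obs = len(design)
    n_bins = len(truth.time_ms)
    y = np.tile(truth.intercept, (n_obs, 1))
    for col, kernel in truth.kernels.items():
        if col not in design.columns:
            raise ValueError(f"design lacks generative column {col!r}")
        x = design[col].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        k = kernel.copy()
        if layer_label == "superficial" and col in PREDICTABILITY_LEVELS:
            k = k * truth.laminar_scale
        y += np.outer(z, k)
    if truth.noise_sd > 0:
        eps = rng.normal(0.0, truth.noise_sd, size=(n_obs, n_bins))
        if smooth_noise:
            eps = moving_average_truncated(eps, 3, axis=-1)
        y += eps
    return y


def spikes_from_rates(
    y: np.ndarray,
    onsets_s: np.ndarray,
    base_rate_hz: float = 10.0,
    rate_floor_hz: float = 0.1,
    seed: int = 0,
    time_ms: np.ndarray = TIME_MS,
) -> pd.DataFrame:
    """Inhomogeneous-Poisson spike times from fold-change rate curves.

    Rates are ``max(base * (1 + y), floor)`` Hz per 10-ms bin; one row per
    spike with column ``spike_time_s``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    bin_s = (time_ms[1] - time_ms[0]) / 1000.0
    for onset, curve in zip(np.asarray(onsets_s, dtype=float), y):
        lam = np.maximum(base_rate_hz * (1.0 + curve), rate_floor_hz) * bin_s
        counts = rng.poisson(lam)
        for b, c in enumerate(counts):
            if c:
                ts = onset + (time_ms[b] - 5.0) / 1000.0 + rng.uniform(0, bin_s, c)
                rows.extend(ts)
    return pd.DataFrame({"spike_time_s": np.sort(np.asarray(rows))})


def ground_truth_to_json(truth: GroundTruth, path: str | Path) -> None:
    payload = dict(
        kernels={k: v.tolist() for k, v in truth.kernels.items()},
        intercept=truth.intercept.tolist(),
        laminar_scale=truth.laminar_scale,
        noise_sd=truth.noise_sd,
        seed=truth.seed,
        time_ms=truth.time_ms.tolist(),
    )
    Path(path).write_text(json.dumps(payload, indent=2))
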
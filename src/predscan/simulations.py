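"""End-to-end simulation studies on synthetic data with known ground truth.

These drivers assemble the full analysis chain — synthetic sessions or
images, feature extraction, inpainting-based unpredictability, time-resolved
regression, and multi-level inference — into parameter-recovery,
type-I-error, laminar-contrast, encoding-dissociation and noise-control
studies.  They are what the validation tests and the reproduction script
run; problem sizes default to desk scale (documented in the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as synth
from .encoding import layer_features, normalize_profile, pls_encode, profile_slope
from .inpaint import FeatureHierarchy, inpaint, mask_rf, multilevel_unpredictability
from .regression import (
    ModulationFunction,
    build_design,
    delta_r,
    fit_timecourse,
    latency_50,
    window_sensitivity,
)
from .responses import TIME_MS
from .stats import animal_average, bootstrap_ci, bootstrap_ttest, tfce_timecourse
from .stimulus_features import (
    build_filter_bank,
    divisive_normalize,
    energy_maps,
    rf_contrast_features,
)
from .types import GroundTruth, ReceptiveField, StimulusImage


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> np.uint32(1)]


# -- design-level synthetic sessions --------------------------------------

@dataclass
class DesignStudy:
    """Per-unit regressor tables and responses plus the generative truth."""

    units: pd.DataFrame
    designs: list[pd.DataFrame]
    responses: list[np.ndarray]
    truth: GroundTruth
    time_ms: np.ndarray


def simulate_design_study(
    seed: int,
    n_animals: int = 8,
    units_per_animal: int = 30,
    n_images: int = 118,
    n_chunks: int = 5,
    beta_unpred_window: float = 0.08,
    beta_contrast_window: float = 0.20,
    laminar_scale: float = 1.0,
    noise_sd: float = 1.0,
) -> DesignStudy:
    """Synthetic session at the regressor level: each unit gets its own
    feature table (n_images x n_chunks observations) and fold-change
    responses from the planted kernels."""
    s_pop, s_truth, *s_units = _child_seeds(seed, 2 + n_animals * units_per_animal)
    units = synth.gen_population(n_animals, units_per_animal, seed=s_pop)
    truth = synth.make_ground_truth(
        beta_unpred_window=beta_unpred_window,
        beta_contrast_window=beta_contrast_window,
        laminar_scale=laminar_scale,
        noise_sd=noise_sd,
        seed=s_truth,
    )
    designs, responses = [], []
    for u, s in zip(units.itertuples(), s_units):
        feats = synth.gen_feature_table(n_images, n_chunks, seed=s)
        rng = np.random.default_rng(s + 1)
        y = synth.gen_responses(feats, truth, layer_label=u.layer_label, rng=rng)
        designs.append(feats)
        responses.append(y)
    return DesignStudy(units, designs, responses, truth, TIME_MS)


def fit_study(
    study: DesignStudy, level: str = "overall"
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-unit extended-model fits.

    Returns (table with window sensitivities, unpredictability beta curves
    (units x bins), contrast beta curves).
    """
    rows, b_unp, b_con = [], [], []
    for u, feats, y in zip(study.units.itertuples(), study.designs, study.responses):
        design = build_design(feats, which="extended", level=level)
        mf = fit_timecourse(y, design, study.time_ms)
        rows.append(
            dict(
                unit_id=u.unit_id,
                animal_id=u.animal_id,
                layer_label=u.layer_label,
                ws_unpred=window_sensitivity(mf, level),
                ws_contrast=window_sensitivity(mf, "CEpref"),
            )
        )
        b_unp.append(mf.for_predictor(level))
        b_con.append(mf.for_predictor("CEpref"))
    return pd.DataFrame(rows), np.asarray(b_unp), np.asarray(b_con)


def _curve_latency(curve: np.ndarray, time_ms: np.ndarray) -> float | None:
    mf = ModulationFunction(np.asarray(curve)[None, :], ["x"], np.asarray(time_ms))
    return latency_50(mf, "x")


def parameter_recovery_run(seed: int, **study_kwargs) -> dict:
    """Recover the planted unpredictability window coefficient and the
    contrast-before-unpredictability latency ordering."""
    study = simulate_design_study(seed, **study_kwargs)
    table, b_unp, b_con = fit_study(study)
    per_animal = animal_average(table["ws_unpred"].to_numpy(), table["animal_id"].to_numpy())
    lo, hi = bootstrap_ci(per_animal.to_numpy(), seed=seed, method="studentized")
    true_ws = float(np.mean(
        study.truth.kernels["overall"][(study.time_ms >= 75) & (study.time_ms <= 150)]
    ))
    mean_unp = animal_average(b_unp, table["animal_id"].to_numpy()).mean(axis=0).to_numpy()
    mean_con = animal_average(b_con, table["animal_id"].to_numpy()).mean(axis=0).to_numpy()
    return dict(
        recovered_mean=float(per_animal.mean()),
        ci=(lo, hi),
        true_window_mean=true_ws,
        covered=bool(lo <= true_ws <= hi),
        latency_unpred=_curve_latency(mean_unp, study.time_ms),
        latency_contrast=_curve_latency(mean_con, study.time_ms),
    )


def type1_run(
    seed: int,
    n_animals: int = 8,
    units_per_animal: int = 6,
    n_images: int = 59,
    n_chunks: int = 2,
    n_boot: int = 10_000,
    null_adjust: int = 2,
) -> dict:
    """Null run (no unpredictability effect): p-values for the window-
    sensitivity test and the Delta-R test across animals."""
    study = simulate_design_study(
        seed,
        n_animals=n_animals,
        units_per_animal=units_per_animal,
        n_images=n_images,
        n_chunks=n_chunks,
        beta_unpred_window=0.0,
    )
    table, _, _ = fit_study(study)
    ws_animal = animal_average(table["ws_unpred"].to_numpy(), table["animal_id"].to_numpy())
    _, p_window = bootstrap_ttest(ws_animal.to_numpy(), n_boot=n_boot, seed=seed)

    drs = []
    for feats, y in zip(study.designs, study.responses):
        base = build_design(feats, which="baseline")
        ext = build_design(feats, which="extended", level="overall")
        drs.append(delta_r(y, base, ext, study.time_ms, seed=seed, null_adjust=null_adjust))
    dr_animal = animal_average(np.asarray(drs), study.units["animal_id"].to_numpy())
    _, p_dr = bootstrap_ttest(dr_animal.to_numpy(), n_boot=n_boot, seed=seed + 1)
    return dict(p_window=float(p_window), p_delta_r=float(p_dr))


def laminar_run(
    seed: int,
    laminar_scale: float = 2.0,
    noise_sd: float = 0.5,
    n_animals: int = 8,
    units_per_animal: int = 30,
    **study_kwargs,
) -> dict:
    """Planted superficial:deep kernel ratio; paired contrast and TFCE map."""
    study = simulate_design_study(
        seed,
        laminar_scale=laminar_scale,
        noise_sd=noise_sd,
        n_animals=n_animals,
        units_per_animal=units_per_animal,
        **study_kwargs,
    )
    table, b_unp, _ = fit_study(study)
    table = table.copy()
    merged = table.groupby(["animal_id", "layer_label"])["ws_unpred"].mean().unstack()
    paired = (merged["superficial"] - merged["deep"]).to_numpy()
    _, p_paired = bootstrap_ttest(paired, seed=seed)

    sup = table["layer_label"].to_numpy() == "superficial"
    aid = table["animal_id"].to_numpy()
    curves_sup = animal_average(b_unp[sup], aid[sup]).to_numpy()
    curves_deep = animal_average(b_unp[~sup], aid[~sup]).to_numpy()
    diff_curves = curves_sup - curves_deep
    _, pvals = tfce_timecourse(diff_curves, seed=seed)

    kernel = study.truth.kernels["overall"]
    return dict(
        paired_mean=float(paired.mean()),
        p_paired=float(p_paired),
        tfce_pvals=pvals,
        significant_bins=np.flatnonzero(pvals < 0.05),
        planted_bins=np.flatnonzero(kernel != 0),
    )


# -- image-level studies (real feature + inpainting path) ------------------

@dataclass
class ImageLevelStudy:
    images: list[StimulusImage]
    units: pd.DataFrame
    rfs: list[ReceptiveField]
    feature_tables: list[pd.DataFrame]  # per unit, per (image, chunk) rows
    stage_tables: list[np.ndarray]      # per-stage (n_images, d) encoder features
    extractor: FeatureHierarchy
    time_ms: np.ndarray


def image_level_study(
    seed: int,
    n_images: int = 32,
    size_px: int = 128,
    n_animals: int = 6,
    units_per_animal: int = 3,
    n_chunks: int = 5,
    image_kind: str = "mixed",
    extractor_seed: int = 0,
    inpainter=None,
) -> ImageLevelStudy:
    """Full stimulus-computable path: Gabor-energy baseline features and
    harmonic-inpainting unpredictability for every (unit, image) pair."""
    deg_per_px = 120.0 / size_px
    s_img, s_pop, s_feat = _child_seeds(seed, 3)
    images = synth.gen_images(n_images, image_kind, size_px, deg_per_px, s_img)
    ce_bank = build_filter_bank("CE", deg_per_px, image_shape=(size_px, size_px))
    sc_bank = build_filter_bank("SC", deg_per_px, image_shape=(size_px, size_px))
    extractor = FeatureHierarchy(seed=extractor_seed)

    ce_norm = [divisive_normalize(energy_maps(im, ce_bank)) for im in images]
    sc_norm = [divisive_normalize(energy_maps(im, sc_bank)) for im in images]

    rng = np.random.default_rng(s_pop)
    n_units = n_animals * units_per_animal
    rfs, unit_rows = [], []
    extent = size_px * deg_per_px
    for uid in range(n_units):
        sigma = rng.uniform(6.0, 7.0)
        margin = 1.1 * 0.75 * sigma * 2.3548
        rf = ReceptiveField(
            center_x=rng.uniform(margin, extent - margin),
            center_y=rng.uniform(margin, extent - margin),
            sigma_x=sigma, sigma_y=sigma,
        )
        rfs.append(rf)
        unit_rows.append(
            dict(
                unit_id=uid,
                animal_id=uid % n_animals,
                layer_label="superficial" if uid % 2 == 0 else "deep",
                pref_sf=float(rng.choice([0.04, 0.08, 0.16])),
                pref_ori=float(rng.choice(np.arange(8) * np.pi / 8)),
            )
        )
    units = pd.DataFrame(unit_rows)

    frng = np.random.default_rng(s_feat)
    tables = []
    for u, rf in zip(units.itertuples(), rfs):
        img_rows = []
        for i, im in enumerate(images):
            feats = rf_contrast_features(
                ce_norm[i], sc_norm[i], im, rf, u.pref_sf, u.pref_ori
            ).as_dict()
            masked = mask_rf(im, rf)
            if inpainter is None:
                filled = inpaint(masked, baseline="harmonic")
            else:
                filled = inpaint(masked, model=inpainter)
            dist = multilevel_unpredictability(im, filled, rf, extractor)
            feats.update(dist.as_dict())
            feats["stimulus_id"] = i
            img_rows.append(feats)
        df = pd.DataFrame(img_rows)
        df = df.loc[np.repeat(np.arange(n_images), n_chunks)].reset_index(drop=True)
        df["chunk"] = np.tile(np.arange(n_chunks), n_images)
        df["v"] = np.abs(frng.normal(8.0, 4.0, size=len(df)))
        tables.append(df)

    stage_tables = layer_features(images, extractor, pool_side=4)
    return ImageLevelStudy(images, units, rfs, tables, stage_tables, extractor, TIME_MS)


def _append_column(design, values: np.ndarray, name: str):
    """Return a copy of a DesignMatrix with one extra z-scored column."""
    from dataclasses import replace

    sd = values.std()
    if sd <= 0:
        raise ValueError(f"constant column {name!r}")
    z = (values - values.mean()) / sd
    return replace(
        design,
        X=np.column_stack([design.X, z]),
        columns=[*design.columns, name],
        mean=np.append(design.mean, values.mean()),
        sd=np.append(design.sd, sd),
    )


def _window_mean_response(y: np.ndarray, n_chunks: int, time_ms: np.ndarray,
                          window=(50.0, 200.0)) -> np.ndarray:
    """Per-image response: chunk- and window-averaged fold change."""
    sel = (time_ms >= window[0]) & (time_ms <= window[1])
    per_obs = y[:, sel].mean(axis=1)
    return per_obs.reshape(-1, n_chunks).mean(axis=1)


def encoding_dissociation_run(
    seed: int,
    n_animals: int = 6,
    units_per_animal: int = 2,
    n_images: int = 32,
    noise_sd: float = 0.35,
    beta_feature_window: float = 0.30,
    beta_unpred_window: float = 0.20,
    feature_stage: int = 2,
    unpred_level: str = "d5",
    n_chunks: int = 5,
) -> dict:
    """Responses driven by low-stage image features with a high-level
    unpredictability modulation; measures the opposite-tuning pattern."""
    study = image_level_study(
        seed, n_images=n_images, n_animals=n_animals, units_per_animal=units_per_animal,
        n_chunks=n_chunks,
    )
    rng = np.random.default_rng(_child_seeds(seed, 4)[3])
    stage = study.stage_tables[feature_stage - 1]

    feature_kernel = synth.scale_kernel_to_window(
        synth.truncated_gaussian_kernel(70.0, 18.0), beta_feature_window
    )
    truth = synth.make_ground_truth(
        beta_unpred_window=beta_unpred_window,
        beta_contrast_window=0.0,
        unpred_column=unpred_level,
        noise_sd=noise_sd,
        seed=seed,
        extra_kernels={"f_img": feature_kernel},
    )

    profiles, level_ws = [], []
    for u, feats in zip(study.units.itertuples(), study.feature_tables):
        w = rng.normal(size=stage.shape[1])
        f_img = stage @ w
        feats = feats.copy()
        feats["f_img"] = f_img[feats["stimulus_id"].to_numpy()]
        y = synth.gen_responses(feats, truth, layer_label="deep",
                                rng=np.random.default_rng(seed + 100 + u.unit_id))
        resp_img = _window_mean_response(y, n_chunks, study.time_ms)
        rs = pls_encode(study.stage_tables, resp_img, seed=seed + u.unit_id)
        prof = normalize_profile(rs)
        if prof is not None:
            profiles.append(prof)
        ws = []
        for level in ("d1", "d2", "d3", "d4", "d5"):
            design = build_design(feats, which="extended", level=level)
            # the unit's generative tuning feature is known in simulation;
            # include it as a nuisance column so its drive cannot leak into
            # the level coefficients (the real pipeline's contrast features
            # play this role for recorded units)
            design = _append_column(design, feats["f_img"].to_numpy(), "f_img")
            mf = fit_timecourse(y, design, study.time_ms)
            ws.append(window_sensitivity(mf, level))
        level_ws.append(ws)

    mean_profile = np.mean(profiles, axis=0)
    ws_df = pd.DataFrame(level_ws, columns=[f"d{i}" for i in range(1, 6)])
    ws_df["animal_id"] = study.units["animal_id"].to_numpy()
    animal_ws = ws_df.groupby("animal_id").mean()
    slopes = animal_ws.apply(lambda row: profile_slope(row.to_numpy()), axis=1).to_numpy()
    return dict(
        encoding_profile=mean_profile,
        encoding_peak_stage=int(np.argmax(mean_profile) + 1),
        unpred_slope_mean=float(slopes.mean()),
        unpred_slopes=slopes,
    )


def noise_control_run(
    seed: int,
    n_animals: int = 6,
    units_per_animal: int = 3,
    n_images: int = 32,
    noise_sd: float = 1.0,
    n_chunks: int = 5,
) -> dict:
    """Synthetic-noise control: responses independent of predictability;
    the across-animal slope of per-level sensitivity should be null."""
    study = image_level_study(
        seed, n_images=n_images, n_animals=n_animals, units_per_animal=units_per_animal,
        n_chunks=n_chunks, image_kind="pink_noise",
    )
    truth = synth.make_ground_truth(
        beta_unpred_window=0.0, beta_contrast_window=0.20, noise_sd=noise_sd, seed=seed,
    )
    level_ws = []
    for u, feats in zip(study.units.itertuples(), study.feature_tables):
        y = synth.gen_responses(feats, truth, layer_label="deep",
                                rng=np.random.default_rng(seed + 300 + u.unit_id))
        ws = []
        for level in ("d1", "d2", "d3", "d4", "d5"):
            design = build_design(feats, which="extended", level=level)
            mf = fit_timecourse(y, design, study.time_ms)
            ws.append(window_sensitivity(mf, level))
        level_ws.append(ws)
    ws_df = pd.DataFrame(level_ws, columns=[f"d{i}" for i in range(1, 6)])
    ws_df["animal_id"] = study.units["animal_id"].to_numpy()
    animal_ws = ws_df.groupby("animal_id").mean()
    slopes = animal_ws.apply(lambda row: profile_slope(row.to_numpy()), axis=1).to_numpy()
    _, p = bootstrap_ttest(slopes, seed=seed)
    return dict(slope_mean=float(slopes.mean()), p_slope=float(p), slopes=slopes)


# -- receptive-field recovery ----------------------------------------------

def rf_recovery_run(
    seed: int,
    n_units: int = 100,
    snr: float = 5.0,
    grid_step_deg: float = 5.0,
    grid_half_extent: int = 6,
    rate0: float = 2.0,
    n_per_pos: int = 45,
    duration_s: float = 0.2,
) -> pd.DataFrame:
    """Simulate Gabor-mapping units and recover their receptive fields.

    ``snr`` is the peak evoked count above baseline divided by the standard
    error of the per-position mean count at the peak; the probe amplitude is
    solved from it.
    """
    from .rf_units import fit_rf_gaussian, rf_histogram

    coords = np.arange(-grid_half_extent, grid_half_extent + 1) * grid_step_deg
    # solve amplitude a from: a*dur = snr * sqrt((rate0 + a)*dur / n)
    c = snr**2 / (duration_s * n_per_pos)
    a = (c + np.sqrt(c**2 + 4 * c * rate0)) / 2.0
    seeds = _child_seeds(seed, n_units)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_units):
        true = ReceptiveField(
            center_x=float(rng.uniform(-15, 15)),
            center_y=float(rng.uniform(-15, 15)),
            sigma_x=float(rng.uniform(6.0, 9.0)),
            sigma_y=float(rng.uniform(6.0, 9.0)),
        )
        trials = synth.gen_gabor_mapping_trials(
            true, coords, coords, rate0=rate0, amplitude=a,
            n_per_pos=n_per_pos, duration_s=duration_s, seed=seeds[i],
        )
        hist, xs, ys = rf_histogram(trials, smooth_sd_cells=1.0)
        fit = fit_rf_gaussian(hist, xs, ys, smooth_sd_cells=1.0)
        center_err = np.hypot(fit.center_x - true.center_x, fit.center_y - true.center_y)
        rows.append(
            dict(
                center_err_steps=center_err / grid_step_deg,
                area_true=true.area_deg2,
                area_fit=fit.area_deg2,
                area_rel_err=(fit.area_deg2 - true.area_deg2) / true.area_deg2,
                rho=fit.rho,
            )
        )
    return pd.DataFrame(rows)
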
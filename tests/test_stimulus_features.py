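"""Gabor banks, quadrature energy, divisive normalization and RF summaries."""

import numpy as np
import pytest

from predscan.stimulus_features import (
    CE_FREQS_CPD,
    SC_FREQS_CPD,
    EnergyMaps,
    build_filter_bank,
    circular_variance,
    divisive_normalize,
    energy_maps,
    local_coefficient_of_variation,
    rf_contrast_features,
)
from predscan.types import StimulusImage

DPP = 120.0 / 128


@pytest.fixture(scope="module")
def ce_bank():
    return build_filter_bank("CE", DPP, image_shape=(128, 128))


@pytest.fixture(scope="module")
def sc_bank():
    return build_filter_bank("SC", DPP, image_shape=(128, 128))


class TestFilterBank:
    def test_ce_bank_has_five_scales_eight_orientations_quadrature(self, ce_bank):
        assert ce_bank.freqs_cpd == CE_FREQS_CPD
        assert len(ce_bank.orientations) == 8
        assert ce_bank.n_filters == 80

    def test_sc_bank_spans_lower_frequencies(self, sc_bank):
        assert sc_bank.freqs_cpd == SC_FREQS_CPD
        assert sc_bank.freqs_cpd[0] == 0.015

    def test_filters_have_no_dc_response(self, ce_bank, sc_bank):
        for bank in (ce_bank, sc_bank):
            for row in bank.kernels:
                for kern in row:
                    assert abs(kern.real.sum()) < 1e-6
                    assert abs(kern.imag.sum()) < 1e-6

    def test_unknown_bank_rejected(self):
        with pytest.raises(ValueError, match="unknown bank"):
            build_filter_bank("XX", DPP)

    def test_oversized_filter_support_names_scale(self):
        with pytest.raises(ValueError, match="0.015"):
            build_filter_bank("SC", DPP, image_shape=(64, 64))


class TestEnergyMaps:
    def test_constant_image_yields_zero_energy(self, ce_bank):
        im = StimulusImage(np.full((128, 128), 0.7), DPP)
        e = energy_maps(im, ce_bank)
        gain = max(np.abs(k).sum() for row in ce_bank.kernels for k in row)
        assert e.energy.max() < 1e-8 * gain

    def test_grating_energy_is_phase_invariant(self, ce_bank, grating_image):
        e = energy_maps(grating_image, ce_bank).energy[2, 0]  # matched channel
        central = e[32:-32, 32:-32]
        assert central.std() / central.mean() < 0.05

    def test_channel_selectivity_argmax(self, ce_bank):
        ys, xs = np.mgrid[0:128, 0:128]
        theta = 3 * np.pi / 8
        u = xs * np.cos(theta) + ys * np.sin(theta)
        im = StimulusImage(0.5 + 0.5 * np.sin(2 * np.pi * 0.16 * DPP * u), DPP)
        means = energy_maps(im, ce_bank).energy.mean(axis=(2, 3))
        assert np.unravel_index(means.argmax(), means.shape) == (3, 3)

    def test_energy_invariant_to_added_constant(self, ce_bank, small_images):
        im = small_images[0]
        e1 = energy_maps(im, ce_bank).energy
        e2 = energy_maps(StimulusImage(im.pixels + 0.123, im.deg_per_px), ce_bank).energy
        assert np.allclose(e1, e2, rtol=1e-8, atol=1e-8 * e1.max())

    def test_nonfinite_pixels_rejected(self, ce_bank):
        px = np.full((128, 128), 0.5)
        px[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            energy_maps(StimulusImage(px, DPP), ce_bank)


def _brute_force_divnorm(E, sigma, truncate=3.0):
    """Direct per-pixel evaluation of the normalization formula."""
    radius = int(truncate * sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    w1 = np.exp(-(ax**2) / (2 * sigma**2))
    w1 /= w1.sum()
    w2 = np.outer(w1, w1)
    Ep = np.pad(E, radius, mode="symmetric")
    E2p = np.pad(E**2, radius, mode="symmetric")
    h, w = E.shape
    m = np.empty_like(E)
    m2 = np.empty_like(E)
    for i in range(h):
        for j in range(w):
            m[i, j] = (w2 * Ep[i : i + 2 * radius + 1, j : j + 2 * radius + 1]).sum()
            m2[i, j] = (w2 * E2p[i : i + 2 * radius + 1, j : j + 2 * radius + 1]).sum()
    S = np.sqrt(np.maximum(m2 - m**2, 0.0)) / (m + 1e-12)
    M = E.max()
    return E * M / (E + M * S + 1e-12)


class TestDivisiveNormalization:
    def test_matches_brute_force_on_random_map(self, rng):
        E = rng.uniform(0.0, 3.0, size=(16, 16))
        sigma = 5.0
        S = local_coefficient_of_variation(E, sigma)
        M = E.max()
        mine = E * M / (E + M * S + 1e-12)
        assert np.allclose(mine, _brute_force_divnorm(E, sigma), atol=1e-10)

    def test_all_zero_map_normalizes_to_zero(self, ce_bank):
        E = np.zeros((1, 1, 16, 16))
        out = divisive_normalize(EnergyMaps(ce_bank, np.tile(E, (5, 8, 1, 1))))
        assert np.all(out.energy == 0)

    def test_zero_energy_pixel_stays_zero(self, rng):
        E = rng.uniform(0.5, 1.0, size=(16, 16))
        E[8, 8] = 0.0
        S = local_coefficient_of_variation(E, 3.0)
        M = E.max()
        out = E * M / (E + M * S + 1e-12)
        assert out[8, 8] == 0.0

    def test_uniform_map_with_unit_cv_gives_half_max(self):
        # substituting E = max(E) and S = 1 into the formula gives M/2
        M = 2.5
        E = np.full((8, 8), M)
        S = np.ones_like(E)
        out = E * M / (E + M * S + 1e-12)
        assert np.allclose(out, M / 2, atol=1e-9)


@pytest.fixture(scope="module")
def maps(small_images, ce_bank, sc_bank):
    im = small_images[0]
    return (
        divisive_normalize(energy_maps(im, ce_bank)),
        divisive_normalize(energy_maps(im, sc_bank)),
        im,
    )


class TestRfFeatures:

    def test_all_features_finite(self, maps, central_rf):
        ce_n, sc_n, im = maps
        f = rf_contrast_features(ce_n, sc_n, im, central_rf, 0.08, 0.0)
        vals = np.array(list(f.as_dict().values()))
        assert np.all(np.isfinite(vals))
        assert 0.0 <= f.cv <= 1.0

    def test_circular_variance_extremes(self):
        # single-orientation energy -> CV 0; uniform energy over 8 orientations -> 1
        oris = np.arange(8) * np.pi / 8
        single = np.zeros(8)
        single[2] = 5.0
        assert circular_variance(single, oris) == pytest.approx(0.0, abs=1e-12)
        assert circular_variance(np.ones(8), oris) == pytest.approx(1.0, abs=1e-12)

    def test_circular_variance_matches_resultant_formula(self, rng):
        oris = np.arange(8) * np.pi / 8
        e = rng.uniform(0, 1, 8)
        expect = 1 - abs((e * np.exp(2j * oris)).sum()) / e.sum()
        assert circular_variance(e, oris) == pytest.approx(expect, abs=1e-12)

    def test_constant_luminance_rf_has_zero_rms(self, maps, central_rf, ce_bank, sc_bank):
        _, _, im = maps
        flat = StimulusImage(np.full_like(im.pixels, 0.4), im.deg_per_px)
        ce_n = divisive_normalize(energy_maps(flat, ce_bank))
        sc_n = divisive_normalize(energy_maps(flat, sc_bank))
        f = rf_contrast_features(ce_n, sc_n, flat, central_rf, 0.08, 0.0)
        assert f.rms == pytest.approx(0.0, abs=1e-9)

    def test_preferred_grating_beats_orthogonal(self, ce_bank, sc_bank, central_rf):
        def grating(theta):
            ys, xs = np.mgrid[0:128, 0:128]
            u = xs * np.cos(theta) + ys * np.sin(theta)
            return StimulusImage(0.5 + 0.5 * np.sin(2 * np.pi * 0.08 * DPP * u), DPP)

        vals = {}
        for name, theta in [("pref", 0.0), ("orth", np.pi / 2)]:
            im = grating(theta)
            ce_n = divisive_normalize(energy_maps(im, ce_bank))
            sc_n = divisive_normalize(energy_maps(im, sc_bank))
            f = rf_contrast_features(ce_n, sc_n, im, central_rf, 0.08, 0.0)
            vals[name] = f.ce_pref
        assert vals["pref"] > vals["orth"]

    def test_grating_in_rf_has_low_cv(self, ce_bank, sc_bank, central_rf, grating_image):
        ce_n = divisive_normalize(energy_maps(grating_image, ce_bank))
        sc_n = divisive_normalize(energy_maps(grating_image, sc_bank))
        f = rf_contrast_features(ce_n, sc_n, grating_image, central_rf, 0.08, 0.0)
        assert f.cv < 0.5

    def test_empty_rf_mask_rejected(self, maps):
        from predscan.types import ReceptiveField

        ce_n, sc_n, im = maps
        tiny = ReceptiveField(center_x=500.0, center_y=500.0, sigma_x=1.0, sigma_y=1.0)
        with pytest.raises(ValueError, match="empty"):
            rf_contrast_features(ce_n, sc_n, im, tiny, 0.08, 0.0)
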
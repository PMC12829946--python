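"""Receptive-field mapping, fitting, unit selection and laminar labels."""

import numpy as np
import pandas as pd
import pytest

from predscan import synthetic_data as synth
from predscan.rf_units import (
    UnitRecord,
    classify_layer,
    fit_rf_gaussian,
    layer_from_depth,
    rf_histogram,
    rf_on_screen,
    select_units,
)
from predscan.types import ReceptiveField


class TestLaminarClassification:
    @pytest.mark.parametrize(
        "layer,label",
        [(1, "superficial"), (2, "superficial"), (3, "superficial"),
         (4, "other"), (5, "deep"), (6, "deep")],
    )
    def test_layer_mapping(self, layer, label):
        assert classify_layer(layer) == label

    @pytest.mark.parametrize("bad", [0, 7, -1])
    def test_out_of_range_layer_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_layer(bad)

    def test_depth_helper_monotone(self):
        layers = [layer_from_depth(d) for d in np.linspace(0, 1, 21)]
        assert layers == sorted(layers)
        assert layers[0] == 1 and layers[-1] == 6


def _mk_unit(uid, area_deg2, rho, cx=60.0, cy=60.0):
    # circular RF with the requested FWHM area
    fwhm = np.sqrt(4 * area_deg2 / np.pi)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    rf = ReceptiveField(center_x=cx, center_y=cy, sigma_x=sigma, sigma_y=sigma, rho=rho)
    return UnitRecord(uid, 0, "V1", 2, rf, 0.08, 0.0)


class TestSelection:
    SCREEN = (120.0, 120.0)

    def test_hand_built_fixture_exact_decisions(self):
        # (area, rho, cx) -> expected keep; boundary areas sit a hair inside
        # the range because sigma -> area round-trips in floating point
        cases = [
            (150.0, 0.71, 60.0, True),     # at the lower area bound
            (749.99, 0.71, 60.0, True),    # just inside the upper bound
            (149.9, 0.9, 60.0, False),     # below area range
            (750.1, 0.9, 60.0, False),     # above area range
            (300.0, 0.70, 60.0, False),    # rho strictly > 0.7 required
            (300.0, 0.701, 60.0, True),
            (300.0, 0.9, -10.0, False),    # centre off screen
            (300.0, 0.9, 119.0, False),    # FWHM ellipse clips the edge
            (400.0, 0.95, 30.0, True),
            (600.0, 0.75, 90.0, True),
        ]
        units = [_mk_unit(i, a, r, cx) for i, (a, r, cx, _) in enumerate(cases)]
        kept = {u.unit_id for u in select_units(units, self.SCREEN)}
        expected = {i for i, (_, _, _, keep) in enumerate(cases) if keep}
        assert kept == expected

    def test_bounds_inclusive_rho_strict_at_exact_values(self):
        """Selection operators at exactly 150 / 750 deg^2 and rho = 0.7."""
        from types import SimpleNamespace

        def stub(area, rho):
            rf = SimpleNamespace(area_deg2=area, rho=rho, center_x=60.0,
                                 center_y=60.0, fwhm_diameter=20.0)
            return SimpleNamespace(unit_id=0, rf=rf)

        assert select_units([stub(150.0, 0.71)], self.SCREEN)
        assert select_units([stub(750.0, 0.71)], self.SCREEN)
        assert not select_units([stub(300.0, 0.7)], self.SCREEN)

    def test_selection_idempotent_and_filters_commute(self):
        units = [_mk_unit(i, a, r) for i, (a, r) in
                 enumerate([(300, 0.9), (100, 0.9), (300, 0.5), (800, 0.9)])]
        once = select_units(units, self.SCREEN)
        twice = select_units(once, self.SCREEN)
        assert [u.unit_id for u in once] == [u.unit_id for u in twice]
        # applying the rho filter before the area filter gives the same set
        rho_first = [u for u in units if u.rf.rho > 0.7]
        manual = [u for u in rho_first
                  if 150 <= u.rf.area_deg2 <= 750 and rf_on_screen(u.rf, self.SCREEN)]
        assert {u.unit_id for u in manual} == {u.unit_id for u in once}


class TestHistogram:
    def test_one_hot_without_smoothing(self):
        rows = []
        for x in range(5):
            for y in range(5):
                rows.append(dict(x_deg=float(x), y_deg=float(y),
                                 count=3 if (x, y) == (2, 2) else 0))
        hist, xs, ys = rf_histogram(pd.DataFrame(rows), smooth_sd_cells=0.0)
        assert hist[2, 2] == 3 and hist.sum() == 3

    def test_smoothing_conserves_total_response(self, rng):
        rows = []
        for x in range(7):
            for y in range(7):
                rows.append(dict(x_deg=float(x), y_deg=float(y),
                                 count=int(rng.integers(0, 10))))
        df = pd.DataFrame(rows)
        raw, *_ = rf_histogram(df, smooth_sd_cells=0.0)
        sm, *_ = rf_histogram(df, smooth_sd_cells=1.0)
        assert sm.sum() == pytest.approx(raw.sum(), rel=1e-6)

    def test_missing_position_listed(self):
        rows = [dict(x_deg=float(x), y_deg=0.0, count=1) for x in range(4)]
        with pytest.raises(ValueError, match="zero trials"):
            rf_histogram(pd.DataFrame(rows + [dict(x_deg=0.0, y_deg=1.0, count=1)]))


class TestGaussianFit:
    def test_noiseless_recovery(self):
        xs = ys = np.arange(-20, 21, 2.0)
        true = ReceptiveField(center_x=3.0, center_y=2.0, sigma_x=5.0, sigma_y=5.0,
                              amplitude=4.0, offset=0.5)
        X, Y = np.meshgrid(xs, ys)
        hist = true.evaluate(X, Y)
        fit = fit_rf_gaussian(hist, xs, ys, smooth_sd_cells=0.0)
        assert abs(fit.center_x - 3.0) < 0.1 and abs(fit.center_y - 2.0) < 0.1
        assert fit.rho > 0.999 and fit.converged

    def test_constant_grid_rejected(self):
        xs = ys = np.arange(5.0)
        with pytest.raises(ValueError, match="constant"):
            fit_rf_gaussian(np.ones((5, 5)), xs, ys)

    def test_rho_decreases_with_noise(self):
        xs = ys = np.arange(-20, 21, 4.0)
        true = ReceptiveField(center_x=0.0, center_y=0.0, sigma_x=6.0, sigma_y=6.0,
                              amplitude=4.0)
        X, Y = np.meshgrid(xs, ys)
        base = true.evaluate(X, Y)
        rhos = {}
        for noise in (0.1, 1.5):
            vals = []
            for s in range(10):
                noisy = base + np.random.default_rng(s).normal(0, noise, base.shape)
                vals.append(fit_rf_gaussian(noisy, xs, ys, smooth_sd_cells=0.0).rho)
            rhos[noise] = np.mean(vals)
        assert rhos[0.1] > rhos[1.5]


class TestMappingTrialsRoundTrip:
    def test_expected_count_peaks_at_rf_centre(self):
        rf = ReceptiveField(center_x=0.0, center_y=0.0, sigma_x=6.0, sigma_y=6.0)
        coords = np.arange(-20, 21, 5.0)
        trials = synth.gen_gabor_mapping_trials(rf, coords, coords, rate0=1.0,
                                                amplitude=200.0, seed=0)
        hist, xs, ys = rf_histogram(trials, smooth_sd_cells=0.0)
        iy, ix = np.unravel_index(hist.argmax(), hist.shape)
        assert (xs[ix], ys[iy]) == (0.0, 0.0)

    def test_determinism_under_seed(self):
        rf = ReceptiveField(center_x=0.0, center_y=0.0, sigma_x=6.0, sigma_y=6.0)
        coords = np.arange(-10, 11, 5.0)
        a = synth.gen_gabor_mapping_trials(rf, coords, coords, seed=7)
        b = synth.gen_gabor_mapping_trials(rf, coords, coords, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rf_outside_grid_rejected(self):
        rf = ReceptiveField(center_x=99.0, center_y=0.0, sigma_x=6.0, sigma_y=6.0)
        coords = np.arange(-10, 11, 5.0)
        with pytest.raises(ValueError, match="outside"):
            synth.gen_gabor_mapping_trials(rf, coords, coords)
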
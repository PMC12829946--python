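"""Autograd, partial convolutions, masking, baselines and the metric."""

import numpy as np
import pytest

from predscan.inpaint import (
    FeatureHierarchy,
    InpainterConfig,
    LevelDistances,
    PConvUNet,
    crop_rf_rectangle,
    directional_fill,
    harmonic_fill,
    inpaint,
    mask_rf,
    mean_fill,
    multilevel_unpredictability,
    partial_conv_forward,
)
from predscan.inpaint.autograd import Tensor, concat, conv2d, upsample_nearest
from predscan.types import ReceptiveField, StimulusImage

DPP = 120.0 / 128


class TestAutograd:
    @pytest.mark.parametrize(
        "expr",
        [
            lambda x, w: (x * x + 2.0 * x).mean(),
            lambda x, w: (x / (x.abs() + 1.5)).sum(),
            lambda x, w: conv2d(x, w, stride=2, padding=1).relu().sum(),
            lambda x, w: upsample_nearest(conv2d(x, w, padding=1).leaky_relu(), 2).abs().mean(),
            lambda x, w: (concat([x, x], axis=1) ** 2).mean(),
            lambda x, w: ((x.reshape(2, -1) @ x.reshape(2, -1).transpose(1, 0)) * 0.1).sum(),
        ],
    )
    def test_gradients_match_finite_differences(self, expr, rng):
        x = Tensor(rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = Tensor(rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
        loss = expr(x, w)
        loss.backward()
        for t in (x, w):
            if t.grad is None:
                continue
            idx = tuple(rng.integers(0, s) for s in t.data.shape)
            eps = 1e-6
            t.data[idx] += eps
            lp = float(expr(x, w).data)
            t.data[idx] -= 2 * eps
            lm = float(expr(x, w).data)
            t.data[idx] += eps
            assert t.grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestPartialConv:
    def test_all_ones_mask_equals_standard_convolution(self, rng):
        feats = rng.normal(size=(1, 2, 8, 8))
        kern = rng.normal(size=(3, 2, 3, 3))
        out, new_mask = partial_conv_forward(feats, np.ones((1, 1, 8, 8)), kern)
        ref = conv2d(Tensor(feats), Tensor(kern), padding=1).data
        assert np.allclose(out[:, :, 1:-1, 1:-1], ref[:, :, 1:-1, 1:-1])
        assert new_mask.all()

    def test_single_valid_pixel_renormalization(self):
        feats = np.zeros((1, 1, 5, 5))
        feats[0, 0, 2, 2] = 3.0
        mask = np.zeros((1, 1, 5, 5))
        mask[0, 0, 2, 2] = 1.0
        out, new_mask = partial_conv_forward(feats, mask, np.ones((1, 1, 3, 3)))
        assert out[0, 0, 2, 2] == pytest.approx(9 * 3.0)  # window 9 / 1 valid
        assert new_mask[0, 0].sum() == 9  # windows touching the pixel

    def test_all_zero_mask_gives_zero_output_no_nan(self, rng):
        feats = rng.normal(size=(1, 1, 6, 6))
        out, new_mask = partial_conv_forward(feats, np.zeros((1, 1, 6, 6)),
                                             rng.normal(size=(2, 1, 3, 3)))
        assert np.all(out == 0) and np.all(new_mask == 0)
        assert np.all(np.isfinite(out))

    def test_valid_fraction_grows_through_unet_encoder(self):
        cfg = InpainterConfig(depth=3, base_channels=4, max_channels=8, seed=0)
        net = PConvUNet(cfg)
        mask = np.ones((1, 1, 32, 32))
        mask[:, :, 10:22, 10:22] = 0.0
        x = Tensor(np.zeros((1, 1, 32, 32)))
        fracs = [mask.mean()]
        m = mask
        for enc in net.encoder:
            x, m = enc(x, m)
            fracs.append(m.mean())
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestMasking:
    def test_hole_area_matches_analytic_ellipse(self, central_rf, small_images):
        im = small_images[0]
        masked = mask_rf(im, central_rf)
        hole_px = (masked.mask == 0).sum()
        expect = central_rf.area_deg2 / im.deg_per_px**2
        assert hole_px == pytest.approx(expect, rel=0.02)

    def test_mask_partitions_image(self, central_rf, small_images):
        masked = mask_rf(small_images[0], central_rf)
        assert set(np.unique(masked.mask)) == {0.0, 1.0}

    def test_identical_rfs_give_identical_masks(self, central_rf, small_images):
        m1 = mask_rf(small_images[0], central_rf).mask
        m2 = mask_rf(small_images[1], central_rf).mask
        assert np.array_equal(m1, m2)

    def test_border_touching_hole_rejected(self, small_images):
        rf = ReceptiveField(center_x=2.0, center_y=60.0, sigma_x=6.0, sigma_y=6.0)
        with pytest.raises(ValueError, match="border"):
            mask_rf(small_images[0], rf)


class TestBaselines:
    def test_mean_fill_on_constant_image_is_identity(self, central_rf):
        im = StimulusImage(np.full((128, 128), 0.6), DPP)
        out = inpaint(mask_rf(im, central_rf), baseline="mean_fill")
        assert np.allclose(out.pixels, im.pixels, atol=1e-12, rtol=0)

    def test_harmonic_fill_exact_on_affine_ramp(self, central_rf):
        ys, xs = np.mgrid[0:128, 0:128]
        ramp = 0.2 + 0.004 * xs + 0.002 * ys
        im = StimulusImage(ramp, DPP)
        out = inpaint(mask_rf(im, central_rf), baseline="harmonic")
        assert np.max(np.abs(out.pixels - ramp)) < 1e-3

    def test_outside_hole_pixels_bit_identical(self, central_rf, small_images):
        im = small_images[2]
        masked = mask_rf(im, central_rf)
        out = inpaint(masked, baseline="harmonic")
        outside = masked.mask == 1
        assert np.array_equal(out.pixels[outside], im.pixels[outside])

    def test_directional_fill_continues_grating(self, central_rf):
        ys, xs = np.mgrid[0:128, 0:128]
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * xs / 16)
        im = StimulusImage(grating, DPP)
        out = inpaint(mask_rf(im, central_rf), baseline="directional")
        assert np.max(np.abs(out.pixels - grating)) < 1e-6

    def test_unknown_baseline_rejected(self, central_rf, small_images):
        with pytest.raises(ValueError, match="unknown baseline"):
            inpaint(mask_rf(small_images[0], central_rf), baseline="magic")

    def test_model_and_baseline_mutually_exclusive(self, central_rf, small_images):
        masked = mask_rf(small_images[0], central_rf)
        with pytest.raises(ValueError, match="exactly one"):
            inpaint(masked)


class _IdentityExtractor:
    """Single-stage linear 'hierarchy' for hand-computable distances."""

    n_stages = 1

    def stages(self, image):
        return [np.asarray(image, dtype=float)[None]]


class TestUnpredictability:
    def test_identical_images_give_zero_everywhere(self, central_rf, small_images):
        ext = FeatureHierarchy(seed=0)
        d = multilevel_unpredictability(small_images[0], small_images[0], central_rf, ext)
        assert np.all(d.levels == 0) and d.overall == 0

    def test_overall_is_arithmetic_mean(self):
        d = LevelDistances(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert d.overall == 3.0

    def test_hand_computed_l2_with_identity_extractor(self, central_rf):
        a = StimulusImage(np.zeros((128, 128)), DPP)
        b_px = np.zeros((128, 128))
        b_px[60, 60] = 0.5
        b_px[64, 64] = -0.5
        b = StimulusImage(b_px, DPP)
        d = multilevel_unpredictability(a, b, central_rf, _IdentityExtractor())
        assert d.levels[0] == pytest.approx(np.sqrt(0.25 + 0.25))

    def test_distance_invariant_to_channel_permutation(self, central_rf, small_images, rng):
        ext = FeatureHierarchy(seed=0)
        a = crop_rf_rectangle(small_images[0], central_rf)
        b = crop_rf_rectangle(small_images[1], central_rf)
        fa, fb = ext.stages(a), ext.stages(b)
        for x, y in zip(fa, fb):
            perm = rng.permutation(x.shape[0])
            assert np.linalg.norm(x - y) == pytest.approx(
                np.linalg.norm(x[perm] - y[perm])
            )

    def test_crop_exceeding_bounds_rejected(self, small_images):
        rf = ReceptiveField(center_x=10.0, center_y=60.0, sigma_x=6.0, sigma_y=6.0)
        with pytest.raises(ValueError, match="bounds"):
            crop_rf_rectangle(small_images[0], rf)
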
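"""Edge-sharpness chain: upsampling, Deriche gradient, Hough, profiles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from atriakit.core import AtriakitError
from atriakit.sharpness import (
    LineSegment,
    NoEdgeError,
    SharpnessConfig,
    compute_sharpness,
    deriche_gradient,
    detect_edge_line,
    profile_rise_distance,
    upsample_roi,
)
from atriakit.sharpness import _deriche_derivative, _deriche_smooth
from atriakit.synthetic_data import PhantomImageConfig, render_phantom_frame


def oracle_phantom(width, **geometry):
    return render_phantom_frame(
        PhantomImageConfig(edge_width_mm=width, **geometry)
    )


class TestUpsample:
    def test_factor_one_is_identity_crop(self, rng):
        img = rng.normal(size=(20, 30))
        np.testing.assert_array_equal(upsample_roi(img, (2, 3, 12, 19), 1),
                                      img[2:12, 3:19])

    def test_linear_ramp_stays_linear(self):
        img = np.outer(np.ones(16), np.arange(24.0))
        up = upsample_roi(img, None, 4)
        row = up[8]
        np.testing.assert_allclose(np.diff(row), np.diff(row)[0], atol=1e-12)

    def test_checkerboard_stencil(self):
        # hand-computed bilinear stencil: midpoints are 2-point averages
        img = np.indices((4, 4)).sum(axis=0) % 2 * 1.0
        up = upsample_roi(img, None, 2)
        assert up[0, 1] == pytest.approx(0.5)   # between 0 and 1 along a row
        assert up[1, 0] == pytest.approx(0.5)   # along a column
        assert up[1, 1] == pytest.approx(0.5)   # cell centre of 0,1,1,0
        assert up[0, 0] == img[0, 0] and up[2, 2] == img[1, 1]

    def test_roi_bounds_checked(self):
        with pytest.raises(AtriakitError):
            upsample_roi(np.zeros((10, 10)), (0, 0, 11, 5), 2)


class TestDericheGradient:
    def test_constant_image_zero_gradient(self):
        g = deriche_gradient(np.full((40, 40), 7.0), 1.0)
        assert g.max() < 1e-8

    def test_matches_truncated_kernel_convolution(self, rng):
        # independent oracle: direct convolution with the analytic kernels
        x = rng.normal(size=(1, 300))
        for alpha in (0.5, 1.0, 2.0):
            n = np.arange(-80, 81)
            ker_s = (alpha * np.abs(n) + 1) * np.exp(-alpha * np.abs(n))
            ker_s /= ker_s.sum()
            c = 1.0 / np.sum(n**2 * np.exp(-alpha * np.abs(n)))
            ker_d = -c * n * np.exp(-alpha * np.abs(n))
            xp = np.pad(x, ((0, 0), (100, 100)), mode="edge")
            rec_s = _deriche_smooth(xp, alpha, axis=1)[:, 100:-100]
            rec_d = _deriche_derivative(xp, alpha, axis=1)[:, 100:-100]
            fir_s = np.convolve(xp[0], ker_s, mode="same")[100:-100]
            fir_d = np.convolve(xp[0], ker_d, mode="same")[100:-100]
            np.testing.assert_allclose(rec_s[0], fir_s, atol=1e-10)
            np.testing.assert_allclose(rec_d[0], fir_d, atol=1e-10)

    def test_unit_ramp_response(self):
        ramp = np.outer(np.ones(30), np.arange(40.0))
        g = deriche_gradient(ramp, 1.0)
        assert g[15, 20] == pytest.approx(1.0, abs=1e-6)

    def test_step_edge_localised(self):
        img = np.zeros((60, 60))
        img[:, 30:] = 1.0
        g = deriche_gradient(img, 1.0)
        assert abs(np.argmax(g[30]) - 29.5) <= 1.0

    def test_rotation_isotropy(self, rng):
        img = gaussian_filter(rng.normal(size=(64, 64)), 2.0)
        g = deriche_gradient(img, 1.0)
        g_rot = deriche_gradient(np.rot90(img), 1.0)
        # interior comparison, 1 % tolerance for discretisation
        a, b = np.rot90(g)[8:-8, 8:-8], g_rot[8:-8, 8:-8]
        assert np.abs(a - b).max() <= 0.01 * np.abs(a).max()

    def test_rejects_nonfinite(self):
        img = np.zeros((10, 10))
        img[3, 3] = np.nan
        with pytest.raises(AtriakitError):
            deriche_gradient(img, 1.0)


class TestDetectEdgeLine:
    @staticmethod
    def tilted_edge_image(theta_deg, size=96):
        """Straight step edge whose normal points at theta_deg."""
        yy, xx = np.mgrid[0:size, 0:size]
        th = np.deg2rad(theta_deg)
        d = (xx - size / 2) * np.cos(th) + (yy - size / 2) * np.sin(th)
        return (d > 0).astype(float)

    @pytest.mark.parametrize("angle", [10.0, 30.0, 60.0, 73.0])
    def test_recovers_edge_angle(self, angle):
        img = self.tilted_edge_image(angle)
        seg = detect_edge_line(deriche_gradient(img, 1.0), 0.5)
        assert abs(np.rad2deg(seg.theta) - angle) <= 1.0
        # endpoints span at least 90 % of the true edge extent
        th = np.deg2rad(angle)
        crossing = 96 / max(abs(np.cos(th)), abs(np.sin(th)))
        assert seg.length >= 0.9 * crossing

    def test_longest_of_two_parallel_edges(self):
        mask = np.zeros((80, 80))
        mask[10:30, 40] = 1.0   # short vertical run
        mask[40:80, 20] = 1.0   # twice as long
        seg = detect_edge_line(mask, 0.5)
        x0, x1 = seg.p0[0], seg.p1[0]
        assert x0 == pytest.approx(20, abs=1.5)
        assert x1 == pytest.approx(20, abs=1.5)
        assert seg.length == pytest.approx(39, abs=2)

    def test_no_edge_error_on_blank(self):
        with pytest.raises(NoEdgeError):
            detect_edge_line(np.zeros((32, 32)), 0.5)


class TestProfileRiseDistance:
    @staticmethod
    def vertical_line(x, y0, y1):
        return LineSegment(
            p0=np.array([x, y0]), p1=np.array([x, y1]),
            theta=0.0, rho=x, votes=1,
        )

    def test_ideal_linear_ramp(self):
        # ramp of width w crossed perpendicularly: every d = 0.6 w
        w_px, spacing = 30.0, 0.1  # 3 mm wide at 0.1 mm spacing
        x = np.arange(200.0)
        profile = np.clip((x - 100 + w_px / 2) / w_px, 0, 1)
        img = np.tile(profile, (120, 1))
        line = self.vertical_line(100.0, 10.0, 110.0)
        cfg = SharpnessConfig(profile_half_length_mm=5.0, profile_sample_step=0.25)
        d, valid = profile_rise_distance(img, line, spacing, cfg)
        assert valid.all()
        np.testing.assert_allclose(d, 0.6 * w_px * spacing, rtol=0.01)

    def test_logistic_closed_form(self):
        # logistic edge of scale s: 20-80 % span is s * ln 16
        s_px, spacing = 8.0, 0.2
        x = np.arange(240.0)
        profile = 1.0 / (1.0 + np.exp(-(x - 120) / s_px))
        img = np.tile(profile, (140, 1))
        line = self.vertical_line(120.0, 20.0, 120.0)
        cfg = SharpnessConfig(profile_half_length_mm=9.0, profile_sample_step=0.2)
        d, valid = profile_rise_distance(img, line, spacing, cfg)
        assert valid.all()
        np.testing.assert_allclose(
            d, s_px * spacing * np.log(16.0), rtol=0.02
        )

    def test_noisy_plateau_monte_carlo(self):
        # 1 % contrast noise on the plateaus: mean d still within 5 %
        w_px, spacing = 30.0, 0.1
        x = np.arange(200.0)
        base = np.clip((x - 100 + w_px / 2) / w_px, 0, 1)
        line = self.vertical_line(100.0, 10.0, 110.0)
        cfg = SharpnessConfig(profile_half_length_mm=5.0)
        means = []
        for seed in range(100):
            noisy = base + np.random.default_rng(seed).normal(0, 0.01, base.size)
            img = np.tile(noisy, (120, 1))
            d, valid = profile_rise_distance(img, line, spacing, cfg)
            if valid.any():
                means.append(np.nanmean(d[valid]))
        assert np.mean(means) == pytest.approx(0.6 * w_px * spacing, rel=0.05)


class TestComputeSharpness:
    def test_matches_ramp_oracle(self, oracle_phantom_geometry):
        frame = oracle_phantom(3.0, **oracle_phantom_geometry)
        res = compute_sharpness(frame.image, frame.sidecar["pixel_spacing_mm"])
        assert res.sharpness == pytest.approx(1 / 1.8, rel=0.05)
        assert res.sharpness == pytest.approx(
            frame.sidecar["ground_truth_sharpness_mm_inv"], rel=0.05
        )

    def test_monotone_in_edge_width(self):
        sharp = {}
        for w in (2.0, 5.0):
            frame = oracle_phantom(w)  # acquisition-like default geometry
            sharp[w] = compute_sharpness(
                frame.image, frame.sidecar["pixel_spacing_mm"]
            ).sharpness
        assert sharp[2.0] > sharp[5.0]

    def test_affine_intensity_invariance(self, oracle_phantom_geometry):
        frame = oracle_phantom(3.0, **oracle_phantom_geometry)
        sp = frame.sidecar["pixel_spacing_mm"]
        ref = compute_sharpness(frame.image, sp).sharpness
        rescaled = compute_sharpness(3.7 * frame.image - 120.0, sp).sharpness
        assert rescaled == pytest.approx(ref, rel=1e-9)

    def test_rotation_invariance(self, oracle_phantom_geometry):
        geo = dict(oracle_phantom_geometry)
        base = oracle_phantom(4.0, **geo)
        geo["tilt_deg"] = geo["tilt_deg"] + 90.0
        rot = oracle_phantom(4.0, **geo)
        sp = base.sidecar["pixel_spacing_mm"]
        s0 = compute_sharpness(base.image, sp).sharpness
        s1 = compute_sharpness(rot.image, sp).sharpness
        assert s1 == pytest.approx(s0, rel=0.05)

    def test_extra_blur_never_sharpens(self, oracle_phantom_geometry):
        frame = oracle_phantom(3.0, **oracle_phantom_geometry)
        sp = frame.sidecar["pixel_spacing_mm"]
        ref = compute_sharpness(frame.image, sp).sharpness
        blurred = compute_sharpness(gaussian_filter(frame.image, 2.0), sp).sharpness
        assert blurred <= ref * 1.001

    def test_finer_sampling_changes_little(self):
        # halving the pixel spacing of the resolved noise-free ramp phantom
        geometries = [
            dict(pixel_spacing_mm=1.0, shape=(192, 192), semi_axes_mm=(60.0, 45.0),
                 tilt_deg=25.0, noise_sd=0.0),
            dict(pixel_spacing_mm=0.5, shape=(384, 384), semi_axes_mm=(60.0, 45.0),
                 tilt_deg=25.0, noise_sd=0.0),
        ]
        vals = []
        for geo in geometries:
            frame = oracle_phantom(4.0, **geo)
            vals.append(
                compute_sharpness(
                    frame.image, frame.sidecar["pixel_spacing_mm"]
                ).sharpness
            )
        assert vals[1] == pytest.approx(vals[0], rel=0.02)

    def test_conv_vs_cs_ordering(self):
        # the emulated acquisition comparison: conventional (sharper edge)
        # scores above CS (wider edge) frame for frame
        for seed in range(3):
            conv = render_phantom_frame(PhantomImageConfig(
                edge_width_mm=2.5, noise_sd=5.0, seed=seed, tilt_deg=20 + 7 * seed
            ))
            cs = render_phantom_frame(PhantomImageConfig(
                edge_width_mm=4.0, noise_sd=5.0, seed=seed + 50,
                tilt_deg=20 + 7 * seed,
            ))
            s_conv = compute_sharpness(
                conv.image, conv.sidecar["pixel_spacing_mm"]
            ).sharpness
            s_cs = compute_sharpness(
                cs.image, cs.sidecar["pixel_spacing_mm"]
            ).sharpness
            assert s_conv > s_cs

    def test_stage_errors_are_tagged(self):
        with pytest.raises(AtriakitError, match="line-detection"):
            compute_sharpness(np.zeros((64, 64)), 1.0)
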
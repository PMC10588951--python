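"""Straightening, profile fitting, separation and intensity measurements."""

import warnings

import numpy as np
import pytest

from scassembly.core_model import ImageStack, Trace
from scassembly.image_quant import (
    ProfileFit,
    chromosome_distance,
    classify_synapsis,
    fit_profile,
    measure_axis_separation,
    measure_roi,
    sample_profiles,
    select_projection,
    straighten,
)
from scassembly.synth_imaging import AxisPairGroundTruth, synthesize_axis_pair_stack


class TestStraighten:
    def test_horizontal_trace_equals_crop(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(size=(40, 80))
        trace = Trace(points=np.array([[10.0, 20.0], [69.0, 20.0]]))
        band = straighten(img, trace, band_width_px=7)
        # rows are normal offsets; for a horizontal +x trace the normal is +y
        crop = img[17:24, 10:70]
        assert band.shape == crop.shape
        np.testing.assert_allclose(band, crop, atol=1e-6)

    def test_semicircular_trace_arc_length_and_uniformity(self):
        """A radially uniform ring straightened along a semicircular trace is
        uniform along columns and has ~ pi*r columns."""
        h = w = 201
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(xx - 100, yy - 100)
        img = np.exp(-((r - 60.0) ** 2) / (2 * 8.0**2))
        theta = np.linspace(0, np.pi, 80)
        trace = Trace(points=np.column_stack(
            [100 + 60 * np.cos(theta), 100 + 60 * np.sin(theta)]
        ))
        band = straighten(img, trace, band_width_px=9)
        assert abs(band.shape[1] - np.pi * 60) <= 2
        center_row = band[4]
        assert center_row.std() / center_row.mean() < 0.02

    def test_degenerate_trace_raises(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            straighten(img, Trace(points=np.array([[5.0, 5.0], [5.0, 5.0]])), 5)

    def test_band_leaving_image_raises(self):
        img = np.zeros((20, 80))
        trace = Trace(points=np.array([[5.0, 2.0], [74.0, 2.0]]))
        with pytest.raises(ValueError, match="band"):
            straighten(img, trace, band_width_px=11)

    def test_even_band_width_rejected(self):
        img = np.zeros((20, 80))
        trace = Trace(points=np.array([[5.0, 10.0], [70.0, 10.0]]))
        with pytest.raises(ValueError, match="odd"):
            straighten(img, trace, band_width_px=8)

    def test_transpose_equivariance(self):
        """Transposing image and trace together yields the same band with
        the normal direction (rows) reversed."""
        rng = np.random.default_rng(5)
        img = rng.uniform(size=(90, 90))
        pts = np.column_stack([np.linspace(15, 75, 12),
                               40 + 3 * np.sin(np.linspace(0, 3, 12))])
        band = straighten(img, Trace(points=pts.copy()), band_width_px=9)
        band_t = straighten(img.T, Trace(points=pts[:, ::-1].copy()), band_width_px=9)
        np.testing.assert_allclose(band_t, band[::-1, :], atol=1e-6)


class TestSampleProfiles:
    def test_uniform_image_constant_profiles(self):
        band = np.full((9, 50), 3.5)
        profiles = sample_profiles(band, n_points=10, thickness_px=3)
        assert len(profiles) == 10
        for p in profiles:
            np.testing.assert_allclose(p, 3.5)

    def test_even_spacing_centers(self):
        """On a 100-column band the 10 sample centers are columns 5..95."""
        band = np.tile(np.arange(100.0), (9, 1))
        profiles = sample_profiles(band, n_points=10, thickness_px=1)
        centers = [p[0] for p in profiles]
        np.testing.assert_allclose(centers, np.arange(5.0, 100.0, 10.0))

    def test_thickness_three_is_column_mean(self):
        band = np.zeros((5, 30))
        band[:, 14] = 3.0  # center column of the sample at column 14
        profiles = sample_profiles(band, n_points=1, thickness_px=3)
        # sample center for n=1 is column 15; columns 14..16 average to 1.0
        np.testing.assert_allclose(profiles[0], 1.0)

    def test_too_few_columns_raises(self):
        with pytest.raises(ValueError):
            sample_profiles(np.zeros((5, 8)), n_points=10)


class TestFitProfile:
    def test_symmetric_double_gaussian_exact(self):
        x = np.arange(31, dtype=float)
        prof = (np.exp(-((x - 13.0) ** 2) / 2) + np.exp(-((x - 17.0) ** 2) / 2))
        fit = fit_profile(prof, pixel_size_nm=40.0)
        assert fit.n_peaks == 2
        assert fit.separation_nm == pytest.approx(160.0, abs=0.1)

    def test_single_peak_unresolved(self):
        x = np.arange(31, dtype=float)
        prof = np.exp(-((x - 15.0) ** 2) / (2 * 2.0**2))
        fit = fit_profile(prof, pixel_size_nm=40.0)
        assert fit.n_peaks == 1
        assert fit.separation_nm is None

    def test_noisy_separation_monte_carlo(self):
        """Two Gaussians 3.3 px apart, 2:1 amplitudes, SNR 10: the median
        absolute separation error over 200 noise draws is < 0.2 px."""
        x = np.arange(31, dtype=float)
        clean = (2.0 * np.exp(-((x - 13.35) ** 2) / (2 * 1.0**2))
                 + 1.0 * np.exp(-((x - 16.65) ** 2) / (2 * 1.0**2)))
        rng = np.random.default_rng(123)
        errors = []
        for _ in range(200):
            noisy = clean + rng.normal(scale=clean.max() / 10.0, size=x.size)
            fit = fit_profile(noisy, pixel_size_nm=1.0, prominence=0.3)
            if fit.n_peaks == 2 and fit.separation_nm is not None:
                errors.append(abs(fit.separation_nm - 3.3))
        assert len(errors) > 50
        assert np.median(errors) < 0.2

    def test_short_profile_raises(self):
        with pytest.raises(ValueError):
            fit_profile(np.zeros(5), 40.0)


class TestChromosomeDistance:
    @staticmethod
    def _fit(sep):
        if sep is None:
            return ProfileFit(1, (5.0,), (1.0,), (1.5,), None, 0.0)
        return ProfileFit(2, (3.0, 7.0), (1.0, 1.0), (1.5, 1.5), sep, 0.0)

    def test_mean_of_constants(self):
        mean, n = chromosome_distance([self._fit(132.0)] * 10)
        assert mean == pytest.approx(132.0) and n == 10

    def test_single_peak_profiles_excluded(self):
        fits = [self._fit(150.0)] * 5 + [self._fit(None)] * 5
        mean, n = chromosome_distance(fits)
        assert mean == pytest.approx(150.0) and n == 5

    def test_no_resolved_profiles_warns(self):
        with pytest.warns(UserWarning):
            mean, n = chromosome_distance([self._fit(None)] * 3)
        assert mean is None and n == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            chromosome_distance([])


class TestClassifySynapsis:
    @pytest.mark.parametrize("sep,expected", [
        (150.0, "synapsed"),
        (365.0, "unsynapsed"),
        (250.0, "unsynapsed"),  # boundary assigned to unsynapsed
    ])
    def test_threshold_rule(self, sep, expected):
        assert classify_synapsis(sep) == expected


class TestSelectProjection:
    def test_projection_window_around_focal_slice(self):
        stack = np.zeros((7, 4, 4))
        stack[3] += 10.0  # focal slice by total intensity
        stack[1, 0, 0] = 99.0   # inside window [1, 5]
        stack[6, 0, 1] = 99.0   # outside window
        proj = select_projection(ImageStack(voxels=stack, pixel_size_nm=40.0))
        assert proj[0, 0] == 99.0
        assert proj[0, 1] < 99.0

    def test_single_slice_clamps(self):
        stack = np.full((1, 3, 3), 2.0)
        proj = select_projection(ImageStack(voxels=stack, pixel_size_nm=40.0))
        np.testing.assert_allclose(proj, 2.0)

    def test_per_pixel_maximum_semantics(self):
        stack = np.zeros((5, 2, 2))
        stack[2] += 5.0
        stack[1, 1, 1] = 7.0  # one pixel peaks off the focal slice
        proj = select_projection(ImageStack(voxels=stack, pixel_size_nm=40.0))
        assert proj[1, 1] == 7.0


class TestMeasureRoi:
    RECT = np.array([[-0.5, -0.5], [9.5, -0.5], [9.5, 4.5], [-0.5, 4.5]])

    def test_self_background_cancels(self):
        img = np.full((20, 20), 10.0)
        res = measure_roi(img, self.RECT, self.RECT + [10, 10])
        assert res.integrated == pytest.approx(0.0)
        assert res.area_px == 50

    def test_constant_difference(self):
        img = np.full((20, 20), 4.0)
        img[:10, :10] = 10.0  # ROI region brighter
        res = measure_roi(img, self.RECT, self.RECT + [0, 10])
        assert res.area_px == 50
        assert res.integrated == pytest.approx((10.0 - 4.0) * 50)

    def test_gaussian_spot_mass_recovered(self):
        """An ROI enclosing ~all of a Gaussian spot recovers its summed
        signal within 2% after background subtraction."""
        h = w = 101
        yy, xx = np.mgrid[0:h, 0:w]
        sigma, amp = 4.0, 50.0
        spot = amp * np.exp(-(((xx - 50) ** 2 + (yy - 50) ** 2) / (2 * sigma**2)))
        img = spot + 7.0
        roi = np.array([[25.0, 25.0], [75.0, 25.0], [75.0, 75.0], [25.0, 75.0]])
        bg = np.array([[2.0, 2.0], [20.0, 2.0], [20.0, 20.0], [2.0, 20.0]])
        res = measure_roi(img, roi, bg)
        true_mass = 2 * np.pi * sigma**2 * amp
        assert res.integrated == pytest.approx(true_mass, rel=0.02)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, size=(30, 30))
        roi = np.array([[2.0, 2.0], [12.0, 2.0], [12.0, 12.0], [2.0, 12.0]])
        bg = np.array([[18.0, 18.0], [28.0, 18.0], [28.0, 28.0], [18.0, 28.0]])
        r1 = measure_roi(img, roi, bg)
        r2 = measure_roi(img + 100.0, roi, bg)
        assert r1.integrated == pytest.approx(r2.integrated)
        r3 = measure_roi(img * 3.0, roi, bg)
        assert r3.integrated == pytest.approx(3.0 * r1.integrated)

    def test_negative_flagged_and_overlap_warns(self):
        img = np.full((20, 20), 4.0)
        img[:10, :10] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = measure_roi(img, self.RECT, self.RECT + [0, 10])
        assert res.negative_flag and res.integrated < 0
        with pytest.warns(UserWarning, match="overlap"):
            measure_roi(img, self.RECT, self.RECT)


class TestEndToEnd:
    def test_separation_recovery_and_classification(self, gentle_midline):
        """Synthetic stacks spanning synapsed and unsynapsed truths are
        recovered within a few nm and classified correctly."""
        for sep, expected in ((145.0, "synapsed"), (332.0, "unsynapsed")):
            truth = AxisPairGroundTruth(
                true_separation_nm=sep, midline=gentle_midline, seed=4
            )
            stack, trace = synthesize_axis_pair_stack(truth, n_slices=9,
                                                      shape=(64, 160))
            out = measure_axis_separation(stack, trace)
            assert out["classification"] == expected
            assert out["mean_separation_nm"] == pytest.approx(sep, abs=10.0)
            assert out["n_valid"] >= 5
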
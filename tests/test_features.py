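"""Morphology, intensity, histogram, IVH, fractal and filter features on
analytic phantoms."""

import numpy as np
import pytest

from deltarad import (DiscretizationConfig, ImageVolume, RoiMask,
                      fractal_features, intensity_histogram_features,
                      ivh_features, local_intensity_features, log_filter,
                      shape_features, statistical_features, suv_peak,
                      wavelet_filter)
from deltarad.features import box_counting_dimension

from conftest import make_image, make_sphere_mask


class TestShape:
    def test_digital_sphere_volume_and_sphericity(self):
        r = 10
        mask = make_sphere_mask(r)
        fv = shape_features(mask)
        assert fv["volume"] == pytest.approx(4 / 3 * np.pi * r ** 3, rel=0.05)
        assert 0.9 < fv["sphericity"] <= 1.0

    def test_single_voxel_volume_uses_spacing(self):
        vals = np.zeros((3, 3, 3), dtype=bool)
        vals[1, 1, 1] = True
        fv = shape_features(RoiMask(vals, (1.0, 1.0, 3.0)))
        assert fv["volume"] == pytest.approx(3.0)

    def test_cube_max_diameter_is_corner_to_corner(self):
        # 2x2x2 cube of unit-spacing voxels: centers span 1 mm per axis
        vals = np.zeros((4, 4, 4), dtype=bool)
        vals[1:3, 1:3, 1:3] = True
        fv = shape_features(RoiMask(vals, (1.0, 1.0, 1.0)))
        assert fv["max-3d-diameter"] == pytest.approx(np.sqrt(3.0))

    def test_multi_segment_mask_rejected(self):
        vals = np.zeros((8, 4, 4), dtype=bool)
        vals[0, 0, 0] = True
        vals[6, 2, 2] = True
        with pytest.raises(ValueError):
            shape_features(RoiMask(vals, (1.0, 1.0, 1.0)))


class TestLocalIntensity:
    def test_constant_image_peaks_equal_constant(self, sphere_mask):
        img = make_image(np.full(sphere_mask.shape, 4.2), modality="PET-SUV")
        fv = local_intensity_features(img, sphere_mask)
        assert fv["global-peak"] == pytest.approx(4.2)
        assert fv["local-peak"] == pytest.approx(4.2)

    def test_single_hot_voxel_peak_by_sphere_enumeration(self):
        """Hot voxel in cold background: the peak equals hot/|sphere|,
        with sphere membership enumerated explicitly at PET spacing."""
        spacing = (4.0, 4.0, 3.0)
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 100.0
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        img = ImageVolume(vals, spacing, modality="PET-SUV")
        radius = (3000.0 / (4 * np.pi)) ** (1 / 3)
        count = sum(1 for dx in range(-2, 3) for dy in range(-2, 3)
                    for dz in range(-3, 4)
                    if (dx * 4.0) ** 2 + (dy * 4.0) ** 2 + (dz * 3.0) ** 2
                    <= radius ** 2)
        fv = local_intensity_features(img, RoiMask(mask, spacing))
        assert fv["global-peak"] == pytest.approx(100.0 / count)
        assert fv["local-peak"] == pytest.approx(100.0 / count)

    def test_suv_peak_matches_local_intensity_global_peak(self, rng):
        spacing = (4.0, 4.0, 3.0)
        vals = rng.uniform(0, 10, size=(8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        img = ImageVolume(vals, spacing, modality="PET-SUV")
        roi = RoiMask(mask, spacing)
        assert suv_peak(img, roi) == local_intensity_features(img, roi)["global-peak"]


class TestStatistics:
    def test_hand_arithmetic_small_roi(self):
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0], vals[0, 0, 1], vals[0, 1, 0], vals[0, 1, 1] = 1, 2, 3, 4
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0] = True
        fv = statistical_features(make_image(vals), RoiMask(mask, (1, 1, 1)))
        assert fv["mean"] == pytest.approx(2.5)
        assert fv["sd"] == pytest.approx(np.sqrt(1.25))
        assert fv["energy"] == pytest.approx(1 + 4 + 9 + 16)

    def test_constant_roi_undefined_moments_reported_as_zero(self, sphere_mask):
        img = make_image(np.full(sphere_mask.shape, 7.0))
        fv = statistical_features(img, sphere_mask)
        assert fv["sd"] == 0.0
        assert fv["skewness"] == 0.0
        assert fv["kurtosis"] == 0.0

    def test_gaussian_sample_moments(self, rng):
        vals = rng.normal(5.0, 2.0, size=(10, 10, 10))
        mask = np.ones((10, 10, 10), dtype=bool)
        fv = statistical_features(make_image(vals), RoiMask(mask, (1, 1, 1)))
        assert fv["mean"] == pytest.approx(5.0, abs=0.2)
        assert fv["sd"] == pytest.approx(2.0, abs=0.15)

    def test_ct_shift_equivariance(self, rng, sphere_mask):
        vals = rng.normal(size=sphere_mask.shape)
        f1 = statistical_features(make_image(vals), sphere_mask)
        f2 = statistical_features(make_image(vals + 100.0), sphere_mask)
        assert f2["mean"] == pytest.approx(f1["mean"] + 100.0)
        assert f2["sd"] == pytest.approx(f1["sd"])
        assert f2["iqr"] == pytest.approx(f1["iqr"])


class TestIntensityHistogram:
    DISC = DiscretizationConfig("fixed-bin-size", bin_width=1.0)

    def _fv(self, flat_values):
        n = len(flat_values)
        vals = np.zeros((n, 2, 2))
        vals[:, 0, 0] = flat_values
        mask = np.zeros((n, 2, 2), dtype=bool)
        mask[:, 0, 0] = True
        return intensity_histogram_features(make_image(vals),
                                            RoiMask(mask, (1, 1, 1)), self.DISC)

    def test_single_bin_entropy_zero_uniformity_one(self):
        fv = self._fv([3.0, 3.0, 3.0, 3.0])
        assert fv["entropy"] == 0.0
        assert fv["uniformity"] == 1.0

    def test_uniform_over_k_bins_entropy_log2k(self):
        fv = self._fv([1, 2, 3, 4, 1, 2, 3, 4])
        assert fv["entropy"] == pytest.approx(np.log2(4))

    def test_hand_computed_three_bin_entropy(self):
        fv = self._fv([1, 1, 2, 2, 2, 2, 2, 3, 3, 3])
        p = np.array([0.2, 0.5, 0.3])
        assert fv["entropy"] == pytest.approx(float(-(p * np.log2(p)).sum()))
        assert fv["mode"] == 2.0


class TestIvh:
    def test_uniform_sphere_full_volume_at_all_thresholds(self, sphere_mask):
        img = make_image(np.full(sphere_mask.shape, 6.0), modality="PET-SUV")
        curve, fv = ivh_features(img, sphere_mask)
        np.testing.assert_allclose(curve.mtv, sphere_mask.volume_mm3)
        np.testing.assert_allclose(curve.tlg, sphere_mask.volume_mm3 * 6.0)

    def test_two_level_roi_splits_at_half(self):
        vals = np.zeros((8, 2, 2))
        vals[:4, :, :] = 10.0
        vals[4:, :, :] = 4.0
        mask = np.ones((8, 2, 2), dtype=bool)
        img = ImageVolume(vals, (1, 1, 1), modality="PET-SUV")
        curve, fv = ivh_features(img, RoiMask(mask, (1, 1, 1)))
        i50 = curve.thresholds.index(50)
        assert curve.mtv[i50] == pytest.approx(16.0)     # half of 32 voxels
        assert curve.tlg[i50] == pytest.approx(16.0 * 10.0)

    def test_linear_ramp_matches_voxel_counting(self):
        vals = np.zeros((32, 2, 2))
        vals[:, 0, 0] = np.linspace(1.0, 20.0, 32)
        mask = np.zeros((32, 2, 2), dtype=bool)
        mask[:, 0, 0] = True
        img = ImageVolume(vals, (1, 1, 1), modality="PET-SUV")
        curve, _ = ivh_features(img, RoiMask(mask, (1, 1, 1)))
        x = vals[mask]
        for idx, pct in enumerate(curve.thresholds):
            sel = x >= 20.0 * pct / 100.0
            assert curve.mtv[idx] == pytest.approx(sel.sum() * 1.0)
            assert curve.tlg[idx] == pytest.approx(sel.sum() * x[sel].mean())

    def test_monotone_and_bounded(self, rng):
        for _ in range(50):
            vals = rng.uniform(0.1, 12.0, size=(6, 6, 4))
            mask = rng.random((6, 6, 4)) < 0.6
            if not mask.any():
                mask[0, 0, 0] = True
            img = ImageVolume(vals, (2, 2, 2), modality="PET-SUV")
            roi = RoiMask(mask, (2, 2, 2))
            curve, _ = ivh_features(img, roi)
            assert np.all(np.diff(curve.mtv) <= 1e-9)
            assert np.all(np.diff(curve.tlg) <= 1e-6)
            assert curve.mtv[0] <= roi.volume_mm3 + 1e-9
            suvmax = vals[mask].max()
            assert np.all(curve.tlg <= curve.mtv * suvmax + 1e-9)

    def test_requires_pet_and_positive_suvmax(self, sphere_mask):
        with pytest.raises(ValueError):
            ivh_features(make_image(np.ones(sphere_mask.shape)), sphere_mask)


class TestFractal:
    def test_solid_cube_dimension_near_three(self):
        binary = np.ones((32, 32, 32), dtype=bool)
        assert 2.8 <= box_counting_dimension(binary) <= 3.0

    def test_single_voxel_dimension_zero(self):
        binary = np.zeros((8, 8, 8), dtype=bool)
        binary[4, 4, 4] = True
        assert box_counting_dimension(binary) == pytest.approx(0.0, abs=1e-9)

    def test_dyadic_fractal_recovers_analytic_dimension(self):
        """A self-similar dyadic fractal (4 of 8 octants kept, 3 levels)
        has analytic dimension log4/log2 = 2; the dyadic box-counting
        estimator recovers it exactly, and its slope matches an
        independent log-log regression."""
        keep = {(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)}

        def fractal(level):
            if level == 0:
                return np.ones((1, 1, 1), dtype=bool)
            prev = fractal(level - 1)
            n = prev.shape[0]
            out = np.zeros((2 * n,) * 3, dtype=bool)
            for i, j, k in keep:
                out[i * n:(i + 1) * n, j * n:(j + 1) * n,
                    k * n:(k + 1) * n] = prev
            return out

        binary = fractal(3)  # 8^3 grid, 64 voxels
        dim = box_counting_dimension(binary)
        assert dim == pytest.approx(np.log(4) / np.log(2), abs=1e-9)

        counts = []
        for s in (1, 2, 4):
            m = 8 // s
            c = binary.reshape(m, s, m, s, m, s).any(axis=(1, 3, 5)).sum()
            counts.append(c)
        slope, _ = np.polyfit(np.log([1, 1 / 2, 1 / 4]), np.log(counts), 1)
        assert dim == pytest.approx(slope, abs=1e-9)

    def test_menger_sponge_matches_independent_regression(self):
        """On a base-3 object, dyadic boxes are misaligned with the
        self-similar structure, so the estimate is biased low relative to
        log20/log3; the estimator must still agree with an independent
        regression over the same dyadic counts."""
        def sponge(level):
            if level == 0:
                return np.ones((1, 1, 1), dtype=bool)
            prev = sponge(level - 1)
            n = prev.shape[0]
            out = np.zeros((3 * n,) * 3, dtype=bool)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        if (i == 1) + (j == 1) + (k == 1) >= 2:
                            continue
                        out[i * n:(i + 1) * n, j * n:(j + 1) * n,
                            k * n:(k + 1) * n] = prev
            return out

        binary = sponge(2)
        dim = box_counting_dimension(binary)
        counts = []
        for s in (1, 2, 4):
            pad = np.pad(binary, ((0, (-9) % s),) * 3)
            m = pad.shape[0] // s
            counts.append(pad.reshape(m, s, m, s, m, s)
                          .any(axis=(1, 3, 5)).sum())
        slope, _ = np.polyfit(np.log([1, 1 / 2, 1 / 4]), np.log(counts), 1)
        assert dim == pytest.approx(slope, abs=1e-9)
        assert 1.5 < dim < np.log(20) / np.log(3)

    def test_fractal_feature_vector_finite(self, rng, sphere_mask):
        img = make_image(rng.normal(size=sphere_mask.shape))
        fv = fractal_features(img, sphere_mask)
        assert set(fv.values) == {"dimension-mean", "dimension-sd", "lacunarity"}


class TestLog:
    def test_constant_image_maps_to_zero(self):
        img = make_image(np.full((16, 16, 16), 9.0))
        out = log_filter(img, (2.0,))["LoG-2mm"]
        assert np.abs(out.values).max() < 1e-6

    def test_impulse_response_matches_analytic_kernel(self):
        """Response to a delta equals the sampled LoG kernel up to the
        discretization of the underlying Gaussian."""
        n = 33
        vals = np.zeros((n, n, n))
        vals[n // 2, n // 2, n // 2] = 1.0
        sigma = 2.5
        out = log_filter(make_image(vals), (sigma,))[f"LoG-{sigma}mm"].values
        idx = np.indices((n, n, n)) - n // 2
        r2 = (idx ** 2).sum(axis=0).astype(float)
        g = np.exp(-r2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2) ** 1.5
        analytic = g * (r2 - 3 * sigma ** 2) / sigma ** 4
        assert np.abs(out - analytic).max() < 5e-4 * np.abs(analytic).max() + 1e-6

    def test_scale_selection_on_gaussian_blob(self):
        n = 48
        idx = np.indices((n, n, n)) - n // 2
        r2 = (idx ** 2).sum(axis=0).astype(float)
        s0 = 3.0
        blob = np.exp(-r2 / (2 * s0 ** 2))
        img = make_image(blob)
        responses = {}
        for s in (1.0, 2.0, 3.0, 5.0):
            out = log_filter(img, (s,))[f"LoG-{s:g}mm"].values
            # sigma^(5/2) normalization puts the 3D-blob extremum at
            # sigma = sigma0: maximizing s^p (s^2+s0^2)^(-5/2) at s=s0
            # requires p = 5/2
            responses[s] = abs(out[n // 2, n // 2, n // 2]) * s ** 2.5
        assert max(responses, key=responses.get) == 3.0


class TestWavelet:
    def test_constant_image_energy_only_in_lll(self):
        img = make_image(np.full((8, 8, 8), 5.0))
        wb = wavelet_filter(img)
        for label, band in wb.bands.items():
            if "H" in label:
                assert np.abs(band.values).max() < 1e-8, label
        np.testing.assert_allclose(wb.bands["LLL"].values,
                                   5.0 * 2.0 ** 1.5, rtol=1e-8)

    def test_pure_z_variation_energy_in_llh(self, rng):
        vals = np.broadcast_to(rng.normal(size=8)[None, None, :],
                               (8, 8, 8)).copy()
        wb = wavelet_filter(make_image(vals))
        energy = {lbl: float((b.values ** 2).sum())
                  for lbl, b in wb.bands.items()}
        assert energy["LLH"] > 100 * energy["LHL"]
        assert energy["LLH"] > 100 * energy["HLL"]
        assert energy["LLH"] > 100 * energy["HHH"]

    def test_perfect_reconstruction(self, rng):
        vals = rng.normal(size=(8, 10, 6))
        img = make_image(vals)
        wb = wavelet_filter(img)
        np.testing.assert_allclose(wb.reconstruct(), vals, atol=1e-8)

    def test_odd_shapes_cropped_to_input_grid(self, rng):
        vals = rng.normal(size=(7, 9, 5))
        wb = wavelet_filter(make_image(vals))
        for band in wb.bands.values():
            assert band.shape == (7, 9, 5)
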
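"""Discretisation, SUV statistics, histogram descriptors and shape."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spectomics.image import VoxelImage, Mask
from spectomics.features import (DiscretisationScheme, discretise,
                                 histogram_features, intensity_features,
                                 discretised_intensity_features,
                                 shape_features, suv_peak)
from spectomics.segmentation import rasterize_sphere


class TestDiscretise:
    def test_scheme_matches_protocol(self):
        scheme = DiscretisationScheme()
        assert scheme.n_bins == 64
        assert scheme.bin_width == 0.3125  # printed rounded as 0.3 SUV/bin
        assert scheme.bin_width * scheme.n_bins == scheme.upper - scheme.lower

    @pytest.mark.parametrize("x,level", [
        (0.0, 1), (20.0, 64), (25.0, 64), (-1.0, 1),
        (0.3125, 2),            # exact bin edge belongs to the next bin
        (0.3124999, 1), (19.999, 64), (10.0, 33),
    ])
    def test_boundary_levels(self, x, level):
        assert discretise([x])[0] == level

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 30, allow_nan=False), min_size=1, max_size=50))
    def test_levels_in_range_and_monotone(self, xs):
        levels = discretise(xs)
        assert ((1 <= levels) & (levels <= 64)).all()
        order = np.argsort(xs)
        assert (np.diff(levels[order]) >= 0).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            discretise([np.nan])


def _image_with_values(vals, voxel=1.0):
    """Cube image whose first len(vals) voxels are in the mask."""
    vals = np.asarray(vals, dtype=float)
    n = int(np.ceil(len(vals) ** (1 / 3))) + 1
    img = VoxelImage(np.zeros((n, n, n)), voxel, unit="SUV")
    m = np.zeros((n, n, n), dtype=bool)
    flat_idx = np.unravel_index(np.arange(len(vals)), (n, n, n))
    img.values[flat_idx] = vals
    m[flat_idx] = True
    return img, Mask(m, img.spacing, img.origin)


class TestIntensityStats:
    def test_quartiles_and_population_std(self):
        img, mask = _image_with_values([1, 2, 3, 4])
        out, degen = intensity_features(img, mask)
        assert out["SUVQ2"] == 2.5
        assert out["SUVstd"] == pytest.approx(1.118033988749895)
        assert out["SUVmin"] == 1 and out["SUVmax"] == 4
        assert not degen

    def test_constant_region_flags_moments_degenerate(self):
        img, mask = _image_with_values([2.0] * 27)
        out, degen = intensity_features(img, mask)
        assert out["SUVmean"] == out["SUVmin"] == out["SUVmax"] == 2.0
        assert out["SUVstd"] == 0.0
        assert {"SUV Skewness", "SUV Kurtosis", "SUV Excess Kurtosis"} <= degen

    def test_tlsre_is_mean_times_volume(self):
        # 3200 voxels of 2.5 mm -> exactly 50 ml at SUVmean 2 -> TLSRE 100
        img = VoxelImage(np.full((20, 20, 8), 2.0), 2.5, unit="SUV")
        mask = Mask(np.ones((20, 20, 8), dtype=bool), img.spacing, img.origin)
        out, _ = intensity_features(img, mask)
        assert mask.volume_ml == 50.0
        assert out["TLSRE"] == pytest.approx(100.0)

    def test_kurtosis_minus_three_is_excess(self, small_image):
        img, mask = small_image
        out, _ = intensity_features(img, mask)
        assert out["SUV Excess Kurtosis"] == pytest.approx(out["SUV Kurtosis"] - 3.0)

    def test_intensity_ignores_values_outside_mask(self, small_image):
        img, mask = small_image
        ref, _ = intensity_features(img, mask)
        poked = img.like(img.values.copy())
        poked.values[~mask.values] = 99.0
        # peak spheres may extend past the mask, so compare the pure stats
        out, _ = intensity_features(poked, mask)
        for k in ("SUVmin", "SUVmean", "SUVstd", "SUVmax", "SUVQ1", "SUVQ2",
                  "SUVQ3", "SUV Skewness", "SUV Kurtosis", "TLSRE"):
            assert out[k] == ref[k]

    def test_suv_peak_on_uniform_region_is_the_constant(self):
        img = VoxelImage(np.full((16, 16, 16), 3.0), 1.95, unit="SUV")
        m = np.zeros((16, 16, 16), dtype=bool)
        m[4:12, 4:12, 4:12] = True
        assert suv_peak(img, Mask(m, img.spacing, img.origin), 1.0) == pytest.approx(3.0)

    def test_suv_peak_finds_hottest_neighbourhood(self):
        img = VoxelImage(np.zeros((20, 20, 20)), 1.95, unit="SUV")
        img.values[5:8, 5:8, 5:8] = 10.0
        img.values[14, 14, 14] = 11.0  # hotter voxel, but tiny
        m = np.zeros((20, 20, 20), dtype=bool)
        m[3:18, 3:18, 3:18] = True
        mask = Mask(m, img.spacing, img.origin)
        out, _ = intensity_features(img, mask)
        assert out["SUVmax"] == 11.0
        assert out["SUVpeak 0.5 ml"] < 11.0  # averaging suppresses the spike
        assert out["SUVpeak 1.0 ml"] < out["SUVpeak 0.5 ml"]

    def test_empty_mask_rejected(self):
        img = VoxelImage(np.zeros((4, 4, 4)), 1.0, unit="SUV")
        with pytest.raises(ValueError):
            intensity_features(img, Mask(np.zeros((4, 4, 4), bool), 1.0))


class TestDiscretisedStats:
    def test_values_are_bin_centers(self):
        scheme = DiscretisationScheme()
        img, mask = _image_with_values([0.0, 0.5, 1.0, 19.99])
        out, _ = discretised_intensity_features(img, mask, scheme)
        # levels 1, 2, 4, 64 -> centres 0.15625, 0.46875, 1.09375, 19.84375
        assert out["Discretised SUVmin"] == pytest.approx(0.15625)
        assert out["Discretised SUVmax"] == pytest.approx(19.84375)

    def test_discretised_tlsre_uses_discretised_mean(self):
        scheme = DiscretisationScheme()
        img, mask = _image_with_values([5.0] * 8)
        out, _ = discretised_intensity_features(img, mask, scheme)
        assert out["Discretised TLSRE"] == pytest.approx(
            out["Discretised SUVmean"] * mask.volume_ml)


class TestHistogram:
    def test_single_level_limits(self):
        scheme = DiscretisationScheme()
        out, degen = histogram_features(np.full(10, 7), scheme)
        assert out["Discretised histogram energy"] == 1.0
        assert out["Discretised histogram entropy log2"] == 0.0
        assert "Discretised histogram Skewness" in degen

    def test_two_equiprobable_levels(self):
        scheme = DiscretisationScheme()
        out, _ = histogram_features(np.array([3] * 5 + [9] * 5), scheme)
        assert out["Discretised histogram entropy log2"] == pytest.approx(1.0)
        assert out["Discretised histogram energy"] == pytest.approx(0.5)
        assert out["Discretised histogram entropy log10"] == pytest.approx(np.log10(2))

    def test_uniform_over_all_64_levels(self):
        scheme = DiscretisationScheme()
        out, _ = histogram_features(np.repeat(np.arange(1, 65), 3), scheme)
        assert out["Discretised histogram entropy log2"] == pytest.approx(6.0)

    def test_excess_is_kurtosis_minus_three(self, rng):
        scheme = DiscretisationScheme()
        out, _ = histogram_features(rng.integers(1, 30, 200), scheme)
        assert out["Discretised histogram Excess Kurtosis"] == pytest.approx(
            out["Discretised histogram Kurtosis"] - 3.0)


class TestShape:
    def test_single_voxel_cube_faces(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        out, _ = shape_features(Mask(m, 2.0))
        assert out["Surface area"] == pytest.approx(6 * 2.0**2)
        assert out["Sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3))

    def test_scale_invariance_of_sphericity(self):
        m = np.zeros((12, 12, 12), dtype=bool)
        m[3:9, 3:9, 2:10] = True
        small, _ = shape_features(Mask(m, 1.0))
        big, _ = shape_features(Mask(m, 2.0))
        assert big["Volume"] == pytest.approx(8 * small["Volume"])
        assert big["Surface area"] == pytest.approx(4 * small["Surface area"])
        assert big["Sphericity"] == pytest.approx(small["Sphericity"])
        assert big["Compacity"] == pytest.approx(small["Compacity"])

    def test_sphere_series_sphericity_below_one_and_converging(self):
        sph = []
        for d in (12.0, 24.0, 48.0, 96.0):
            n = int(d / 1.95) + 8
            origin = tuple(-(n - 1) * 1.95 / 2 for _ in range(3))
            grid = VoxelImage(np.zeros((n, n, n)), 1.95, origin)
            out, _ = shape_features(rasterize_sphere((0, 0, 0), d, grid))
            sph.append(out["Sphericity"])
        assert all(0.85 < s < 1.0 for s in sph)
        assert abs(sph[3] - sph[2]) < abs(sph[1] - sph[0])  # converging plateau
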
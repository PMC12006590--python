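"""Phantom construction and the image-domain scan model."""

import dataclasses
import math

import numpy as np
import pytest

from spectomics import phantoms as ph
from spectomics.image import VoxelImage


class TestUniformPhantom:
    def test_interior_concentration_matches_activity_over_fill_volume(self):
        geom = ph.PhantomGeometry.uniform_cylinder()
        spec = ph.ActivitySpec.uniform(278.0, geom)
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        interior = ph.cylinder_interior_mask(geom, img).values
        assert np.allclose(img.values[interior], 278000.0 / 6244.0)  # ~44.52 kBq/ml
        assert (img.values[~interior] == 0).all()

    def test_zero_activity_gives_empty_image(self, small_cylinder):
        geom, _ = small_cylinder
        spec = ph.ActivitySpec.uniform(0.0, geom)
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        assert (img.values == 0).all()

    def test_rasterised_integral_matches_analytic_cylinder_volume(self, tc_uniform_scan):
        # grid integral of concentration vs conc x analytic cylinder volume:
        # rasterisation error < 2% at 1.95 mm voxels on the full-size phantom
        geom, spec, _ = tc_uniform_scan
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        integral_mbq = img.values.sum() * img.voxel_volume_ml / 1000.0
        analytic_ml = math.pi * (geom.cylinder_diameter / 2) ** 2 * geom.cylinder_height / 1000
        conc = spec.total_activity * 1000.0 / geom.fill_volume
        assert integral_mbq == pytest.approx(conc * analytic_ml / 1000.0, rel=0.02)

    def test_voxel_larger_than_radius_is_degenerate(self, small_cylinder):
        geom, spec = small_cylinder
        with pytest.raises(ValueError, match="degenerate"):
            ph.build_uniform_phantom(geom, spec, voxel=40.0)


class TestRevolverPhantom:
    def test_syringe_values_are_ratio_times_background(self):
        geom = ph.PhantomGeometry.revolver(5.0)
        spec = ph.ActivitySpec(total_activity=100.0, background_concentration=10.0,
                               phantom_mass=9735.0, ratios=(16, 4, 8, 4, 8, 4, 8))
        img = ph.build_revolver_phantom(geom, spec, 1.95)
        inside = img.values > 0
        assert set(np.unique(img.values[inside])) == {10.0, 40.0, 80.0, 160.0}

    def test_unit_ratios_look_uniform_inside_body(self):
        geom = ph.PhantomGeometry.revolver(5.0)
        spec = ph.ActivitySpec(total_activity=100.0, background_concentration=10.0,
                               phantom_mass=9735.0, ratios=(1,) * 7)
        img = ph.build_revolver_phantom(geom, spec, 1.95)
        inside = img.values > 0
        assert img.values[inside].max() == img.values[inside].min()

    @pytest.mark.parametrize("syr_ml", [2.5, 5.0, 10.0])
    def test_hot_volume_close_to_seven_syringes(self, syr_ml):
        geom = ph.PhantomGeometry.revolver(syr_ml)
        spec = ph.ActivitySpec.revolver(472.0, geom)
        img = ph.build_revolver_phantom(geom, spec, 1.95)
        hot = img.values > spec.background_concentration
        hot_ml = hot.sum() * img.voxel_volume_ml
        # one voxel shell around each barrel bounds the rasterisation error
        r = geom.syringe_inner_diameter / 2
        shell_ml = 7 * (math.pi * ((r + 1.95) ** 2 - r ** 2) * geom.syringe_length
                        + 2 * math.pi * r**2 * 1.95) / 1000
        assert abs(hot_ml - 7 * syr_ml) < shell_ml

    def test_syringe_geometry_volume_invariant(self):
        geom = ph.PhantomGeometry.revolver(10.0)
        r = geom.syringe_inner_diameter / 2
        assert geom.syringe_length * math.pi * r * r == pytest.approx(
            geom.syringe_volume * 1000.0, rel=0.005)

    def test_bundle_outside_body_raises(self):
        with pytest.raises(ph.GeometryError):
            ph.PhantomGeometry.revolver(10.0, insert_center=(140.0, 0.0, 0.0))

    def test_bad_ratio_count_rejected(self):
        geom = ph.PhantomGeometry.revolver(5.0)
        with pytest.raises(ValueError):
            ph.ActivitySpec.revolver(472.0, geom, ratios=(4, 8, 16))


class TestSUVConversion:
    def test_uniform_phantom_maps_to_suv_one(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        suv = ph.to_suv(img, spec)
        inside = img.values > 0
        assert np.allclose(suv.values[inside], 1.0)
        assert suv.unit == "SUV"

    def test_revolver_syringe_suv_is_ratio_times_background(self):
        geom = ph.PhantomGeometry.revolver(5.0)
        spec = ph.ActivitySpec.revolver(386.0, geom)
        suv = ph.to_suv(ph.build_revolver_phantom(geom, spec, 1.95), spec)
        inside = suv.values > 0
        levels = np.unique(suv.values[inside])
        bg = levels.min()
        assert np.allclose(np.sort(levels / bg), [1.0, 4.0, 8.0, 16.0])

    def test_mass_balance_mean_suv_about_one(self):
        geom = ph.PhantomGeometry.revolver(10.0)
        spec = ph.ActivitySpec.revolver(386.0, geom)
        suv = ph.to_suv(ph.build_revolver_phantom(geom, spec, 1.95), spec)
        inside = suv.values > 0
        mean_times_mass = suv.values[inside].mean() * inside.sum() * suv.voxel_volume_ml
        # in-phantom mean SUV x rasterised volume ~ phantom mass (discretisation error)
        assert mean_times_mass == pytest.approx(spec.phantom_mass, rel=0.03)

    def test_zero_activity_raises(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        bad = dataclasses.replace(spec, total_activity=0.0)
        with pytest.raises(ZeroDivisionError):
            ph.to_suv(img, bad)


class TestScanSimulation:
    def test_identity_limit_without_blur_or_noise(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        model = ph.ImagingModel(psf_fwhm=0.0, count_scale=1.0, sample_noise=False)
        scan = ph.simulate_scan(img, model, spec)
        assert np.array_equal(scan.values, ph.to_suv(img, spec).values)

    def test_same_seed_is_bit_identical(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        model = ph.ImagingModel(psf_fwhm=6.0, count_scale=1.0, seed=11)
        a = ph.simulate_scan(img, model, spec)
        b = ph.simulate_scan(img, model, spec)
        assert np.array_equal(a.values, b.values)

    def test_blur_conserves_total_signal(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95, margin=30.0)
        model = ph.ImagingModel(psf_fwhm=8.0, count_scale=1.0, sample_noise=False)
        scan = ph.simulate_scan(img, model, spec)
        suv = ph.to_suv(img, spec)
        assert scan.values.sum() == pytest.approx(suv.values.sum(), rel=1e-3)

    def test_interior_cov_follows_poisson_closed_form(self, small_cylinder):
        # CoV across interior voxels ~ 1/sqrt(count_scale x concentration),
        # checked at expected counts = 100 per voxel, no blur
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        conc = spec.total_activity * 1000.0 / geom.fill_volume
        model = ph.ImagingModel(psf_fwhm=0.0, count_scale=100.0 / conc, seed=3)
        scan = ph.simulate_scan(img, model, spec)
        interior = ph.cylinder_interior_mask(geom, img).values
        v = scan.values[interior]
        assert v.std() / v.mean() == pytest.approx(0.10, rel=0.05)

    def test_negative_psf_rejected(self):
        with pytest.raises(ValueError):
            ph.ImagingModel(psf_fwhm=-1.0, count_scale=1.0)

    def test_cov_decreases_with_count_scale(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 3.9)
        interior = ph.cylinder_interior_mask(
            ph.PhantomGeometry.uniform_cylinder(height=40, diameter=40), img).values
        covs = []
        for scale in (0.05, 0.2, 0.8):
            model = ph.ImagingModel(psf_fwhm=6.0, count_scale=scale, seed=5)
            stack = np.stack([
                ph.simulate_scan(img, dataclasses.replace(model, seed=5 + k), spec).values
                for k in range(20)])[:, interior]
            cov = stack.std(axis=0, ddof=1) / stack.mean(axis=0)
            covs.append(cov.mean())
        assert covs[0] > covs[1] > covs[2]

    def test_uniform_cylinder_symmetric_under_quarter_turn(self, small_cylinder):
        geom, spec = small_cylinder
        img = ph.build_uniform_phantom(geom, spec, 1.95)
        model = ph.ImagingModel(psf_fwhm=8.0, count_scale=1.0, sample_noise=False)
        scan = ph.simulate_scan(img, model, spec)
        rotated = np.rot90(scan.values, k=1, axes=(0, 1))
        assert np.allclose(scan.values, rotated, atol=1e-9)


class TestRepeatSeries:
    def test_four_repeats_pairwise_different_with_noise(self, small_cylinder):
        geom, spec = small_cylinder
        model = ph.ImagingModel(psf_fwhm=6.0, count_scale=0.5, seed=2)
        scans = ph.generate_repeat_series(geom, spec, model, 4, voxel=3.9)
        assert len(scans) == 4
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.array_equal(scans[i].values, scans[j].values)

    def test_noise_free_repeats_identical(self, small_cylinder):
        geom, spec = small_cylinder
        model = ph.ImagingModel(psf_fwhm=6.0, count_scale=0.5, seed=2,
                                sample_noise=False)
        scans = ph.generate_repeat_series(geom, spec, model, 3, voxel=3.9)
        assert all(np.array_equal(scans[0].values, s.values) for s in scans[1:])

    def test_singleton_series(self, small_cylinder):
        geom, spec = small_cylinder
        model = ph.ImagingModel(psf_fwhm=6.0, count_scale=0.5)
        assert len(ph.generate_repeat_series(geom, spec, model, 1, voxel=3.9)) == 1
        with pytest.raises(ValueError):
            ph.generate_repeat_series(geom, spec, model, 0, voxel=3.9)

    def test_mean_of_repeats_converges_to_noise_free_image(self, small_cylinder):
        # law of large numbers: voxelwise z-scores of the n-repeat mean
        geom, spec = small_cylinder
        model = ph.ImagingModel(psf_fwhm=6.0, count_scale=2.0, seed=9)
        noiseless = ph.simulate_scan(
            ph.build_uniform_phantom(geom, spec, 3.9),
            dataclasses.replace(model, sample_noise=False), spec)
        n = 150
        stack = np.stack([s.values for s in
                          ph.generate_repeat_series(geom, spec, model, n, voxel=3.9)])
        mean = stack.mean(axis=0)
        sigma = stack.std(axis=0, ddof=1)
        hot = noiseless.values > 0.5 * noiseless.values.max()
        z = (mean[hot] - noiseless.values[hot]) / (sigma[hot] / np.sqrt(n))
        assert np.abs(z).max() < 6.0
        assert np.abs(z).mean() < 1.2
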
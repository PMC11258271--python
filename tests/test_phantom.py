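"""Ground-truth contracts of the digital phantom generator."""

import math

import numpy as np
import pytest

from cmrprecision.image_io import ImageStack
from cmrprecision.phantom import (CoilModel, InfarctWedge, PhantomSpec,
                                  add_rician_noise, apply_coil_sensitivity,
                                  coil_sensitivity_field, generate_cine_phantom,
                                  generate_lge_phantom, generate_ttc_photos)


class TestCinePhantom:
    def test_noiseless_intensities_match_spec(self, cine_phantom, cine_spec):
        stack, truth = cine_phantom
        masks = truth.label_masks[0]
        frame = stack.voxels[..., 0]
        blood_only = masks["blood_pool"] & ~masks["papillary"]
        assert np.all(frame[blood_only] == cine_spec.intensities["blood"])
        assert np.all(frame[masks["myocardium"]] == cine_spec.intensities["myocardium"])
        # papillary muscle renders at myocardial intensity inside the cavity
        assert np.all(frame[masks["papillary"]] == cine_spec.intensities["myocardium"])

    def test_no_contraction_gives_zero_ef(self):
        spec = PhantomSpec(n_slices=3, rows=96, cols=96, n_phases=4,
                           endo_radius_ed=15.0, endo_radius_es=15.0, wall_thickness_ed=8.0)
        _, truth = generate_cine_phantom(spec)
        assert truth.true_ef_pct == 0.0

    def test_cylinder_volumes_match_closed_form(self):
        # single-radius cylinder: EDV = pi r^2 h exactly
        spec = PhantomSpec(n_slices=10, rows=128, cols=128, pixel_spacing=(0.7, 0.7),
                           slice_thickness_mm=6.0, n_phases=4,
                           endo_radius_ed=15.0, endo_radius_es=11.0, wall_thickness_ed=8.0)
        _, truth = generate_cine_phantom(spec)
        h = 10 * 6.0
        assert truth.true_edv_ml == pytest.approx(math.pi * 15**2 * h / 1000.0, rel=1e-12)
        assert truth.true_esv_ml == pytest.approx(math.pi * 11**2 * h / 1000.0, rel=1e-12)
        expected_ef = 100.0 * (15**2 - 11**2) / 15**2
        assert truth.true_ef_pct == pytest.approx(expected_ef, rel=1e-12)

    def test_mask_volumes_within_2pct_of_analytic(self, cine_phantom, cine_spec):
        _, truth = cine_phantom
        vox_ml = (truth.label_masks[0]["blood_pool"].sum()
                  * cine_spec.pixel_spacing[0] * cine_spec.pixel_spacing[1]
                  * cine_spec.slice_thickness_mm / 1000.0)
        assert vox_ml == pytest.approx(truth.true_edv_ml, rel=0.02)

    def test_myocardial_area_conserved_across_phases(self, cine_phantom, cine_spec):
        # analytic conservation is exact by construction; voxelized areas
        # fluctuate only by boundary discretization
        _, truth = cine_phantom
        for p in range(cine_spec.n_phases):
            endo = cine_spec.endo_radius_at_phase(p)
            epi = cine_spec.epi_radius(endo)
            analytic = np.pi * (epi**2 - endo**2)
            np.testing.assert_allclose(analytic, cine_spec.annulus_area_mm2, rtol=1e-12)
        areas = np.array([m["myocardium"].sum() for m in truth.label_masks], float)
        assert np.ptp(areas) / areas.mean() < 0.015

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(n_slices=3, rows=64, cols=64, n_phases=4,
                           endo_radius_ed=10.0, endo_radius_es=7.0, wall_thickness_ed=5.0,
                           pixel_spacing=(0.9, 0.9), noise_sigma=4.0, seed=123)
        a, _ = generate_cine_phantom(spec)
        b, _ = generate_cine_phantom(spec)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="wall thickness"):
            PhantomSpec(wall_thickness_ed=-1.0).validate()
        with pytest.raises(ValueError, match="contraction"):
            PhantomSpec(endo_radius_ed=10.0, endo_radius_es=12.0).validate()
        with pytest.raises(ValueError, match="field of view"):
            PhantomSpec(rows=48, cols=48, pixel_spacing=(0.5, 0.5)).validate()


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, cine_phantom):
        stack, _ = cine_phantom
        out = add_rician_noise(stack, 0.0, seed=1)
        np.testing.assert_array_equal(out.voxels, stack.voxels)

    def test_background_second_moment_is_rayleigh(self):
        bg = ImageStack(np.zeros((1, 300, 300)), (1.0, 1.0), 6.0)
        noisy = add_rician_noise(bg, 5.0, seed=2)
        # E[v^2] = 2 sigma^2 for Rayleigh background
        assert np.mean(noisy.voxels**2) == pytest.approx(2 * 25.0, rel=0.02)

    def test_high_snr_limit_preserves_mean(self):
        sig = ImageStack(np.full((1, 300, 300), 1000.0), (1.0, 1.0), 6.0)
        noisy = add_rician_noise(sig, 5.0, seed=3)
        assert np.mean(noisy.voxels) == pytest.approx(1000.0, rel=1e-3)

    def test_negative_sigma_rejected(self, cine_phantom):
        with pytest.raises(ValueError, match="sigma"):
            add_rician_noise(cine_phantom[0], -1.0)


class TestCoilSensitivity:
    def _stack(self):
        return ImageStack(np.full((4, 64, 64), 100.0), (1.0, 1.0), 6.0)

    def test_infinite_decay_is_identity(self):
        coil = CoilModel([(0.0, 32.0, 12.0)], decay_mm=np.inf)
        out = apply_coil_sensitivity(self._stack(), coil)
        np.testing.assert_array_equal(out.voxels, self._stack().voxels)

    def test_sensitivity_peaks_at_element(self):
        coil = CoilModel([(10.0, 32.0, 12.0)], decay_mm=80.0)
        field = coil_sensitivity_field(self._stack(), coil)
        peak = np.unravel_index(np.argmax(field), field.shape)
        # element at y=10, x=32, z=12 -> voxel (slice 1 covers z in [6,12)), row 9/10, col 31/32
        assert abs(peak[1] - 9.5) <= 1 and abs(peak[2] - 31.5) <= 1

    def test_farther_heart_has_lower_mean_intensity(self):
        means = []
        for d in (40.0, 60.0, 80.0):
            coil = CoilModel([(32.0 - d, 32.0, 12.0)], decay_mm=80.0)
            out = apply_coil_sensitivity(self._stack(), coil)
            means.append(out.voxels.mean())
        assert means[0] > means[1] > means[2]


class TestLgePhantom:
    def test_full_transmural_quarter_wedge_is_25pct(self):
        spec = PhantomSpec(n_slices=4, rows=128, cols=128, pixel_spacing=(0.7, 0.7),
                           endo_radius_ed=15.0, endo_radius_es=11.0, wall_thickness_ed=8.0,
                           infarct_wedge=InfarctWedge(0.0, 90.0, 1.0))
        _, truth = generate_lge_phantom(spec)
        assert truth.true_infarct_fraction_pct == pytest.approx(25.0, rel=1e-12)

    def test_zero_transmurality_is_no_infarct(self):
        spec = PhantomSpec(n_slices=4, rows=128, cols=128, pixel_spacing=(0.7, 0.7),
                           endo_radius_ed=15.0, endo_radius_es=11.0, wall_thickness_ed=8.0,
                           infarct_wedge=InfarctWedge(0.0, 90.0, 0.0))
        _, truth = generate_lge_phantom(spec)
        assert truth.true_infarct_fraction_pct == 0.0
        assert truth.label_masks[0]["infarct_hyper"].sum() == 0

    def test_60deg_half_transmural_wedge_is_8_33pct(self):
        spec = PhantomSpec(n_slices=4, rows=192, cols=192, pixel_spacing=(0.5, 0.5),
                           endo_radius_ed=15.0, endo_radius_es=11.0, wall_thickness_ed=8.0,
                           infarct_wedge=InfarctWedge(-30.0, 30.0, 0.5))
        _, truth = generate_lge_phantom(spec)
        assert truth.true_infarct_fraction_pct == pytest.approx(100 * 60 / 360 * 0.5, rel=1e-12)
        m = truth.label_masks[0]
        vox_frac = 100.0 * (m["infarct_hyper"].sum() + m["infarct_hypo"].sum()) / m["myocardium"].sum()
        assert vox_frac == pytest.approx(truth.true_infarct_fraction_pct, rel=0.03)

    def test_requires_wedge(self, cine_spec):
        with pytest.raises(ValueError, match="infarct_wedge"):
            generate_lge_phantom(cine_spec)

    def test_magnitude_is_abs_of_psir(self):
        spec = PhantomSpec(n_slices=3, rows=96, cols=96, pixel_spacing=(0.8, 0.8),
                           endo_radius_ed=12.0, endo_radius_es=8.0, wall_thickness_ed=6.0,
                           infarct_wedge=InfarctWedge(0.0, 90.0, 1.0),
                           noise_sigma=8.0, seed=9)
        mag, _ = generate_lge_phantom(spec, source="magnitude")
        assert np.all(mag.voxels >= 0)
        psir, _ = generate_lge_phantom(spec, source="psir")
        assert psir.modality == "lge-psir"


class TestTtcPhotos:
    def test_no_infarct_means_zero_white_area(self):
        spec = PhantomSpec(n_slices=5, endo_radius_ed=15.0, endo_radius_es=11.0,
                           wall_thickness_ed=8.0)
        photos = generate_ttc_photos(spec)
        assert all(p.true_infarct_area_mm2 == 0.0 for p in photos)

    def test_ruler_calibration_truth(self):
        spec = PhantomSpec(n_slices=5, endo_radius_ed=15.0, endo_radius_es=11.0,
                           wall_thickness_ed=8.0)
        photos = generate_ttc_photos(spec, mm_per_px=0.1, ruler_tick_spacing_mm=1.0)
        assert photos[0].mm_per_px == 0.1  # ticks drawn 10 px apart

    def test_top_and_bottom_views_per_slice(self):
        spec = PhantomSpec(n_slices=5, endo_radius_ed=15.0, endo_radius_es=11.0,
                           wall_thickness_ed=8.0,
                           infarct_wedge=InfarctWedge(-45.0, 45.0, 1.0))
        photos = generate_ttc_photos(spec)  # 30 mm of tissue -> 6 TTC slices, 2 views
        assert len(photos) == 12
        assert {p.view for p in photos} == {"top", "bottom"}

    def test_cone_infarct_faces_differ_by_analytic_amount(self):
        spec = PhantomSpec(n_slices=5, endo_radius_ed=15.0, endo_radius_es=11.0,
                           wall_thickness_ed=8.0,
                           infarct_wedge=InfarctWedge(-45.0, 45.0, 1.0))
        photos = generate_ttc_photos(spec, apical_taper=0.6)
        top0 = next(p for p in photos if p.view == "top" and p.slice_index == 0)
        bot0 = next(p for p in photos if p.view == "bottom" and p.slice_index == 0)
        # span shrinks linearly with depth: faces at z=0 and z=5 of 30 mm total
        full = top0.true_infarct_area_mm2
        expected_bot = full * (1 - 0.6 * 5.0 / 30.0)
        assert bot0.true_infarct_area_mm2 == pytest.approx(expected_bot, rel=1e-9)
        assert top0.true_infarct_area_mm2 > bot0.true_infarct_area_mm2


class TestNoiseCalibrationProperty:
    def test_estimated_sigma_linear_in_true_sigma(self):
        """Half-RMS background estimate scales linearly with channel sigma."""
        from scipy.stats import pearsonr
        from cmrprecision.quality import estimate_noise_sd

        bg = ImageStack(np.zeros((1, 200, 200)), (1.0, 1.0), 6.0)
        sigmas = [2.0, 5.0, 10.0]
        est = []
        for i, s in enumerate(sigmas):
            noisy = add_rician_noise(bg, s, seed=100 + i)
            est.append(estimate_noise_sd(noisy.voxels[0], (slice(0, 50), slice(0, 50)),
                                         n_receivers=1))
        r = pearsonr(sigmas, est).statistic
        assert r > 0.999
        ratios = np.array(est) / np.array(sigmas)
        assert np.allclose(ratios, ratios[0], rtol=0.02)
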
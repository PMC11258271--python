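"""Blood-tissue contrast, noise/SNR estimation, flip angles, distance weight."""

import math

import numpy as np
import pytest
from scipy.stats import pearsonr

from cmrprecision.image_io import ImageStack
from cmrprecision.phantom import (CoilModel, PhantomSpec, add_rician_noise,
                                  apply_coil_sensitivity, generate_cine_phantom)
from cmrprecision.quality import (auto_noise_roi, compute_btc,
                                  compute_distance_weight, compute_snr,
                                  estimate_fa_from_b1, estimate_noise_sd,
                                  filter_blood_pool, normalize_snr_receive,
                                  quality_report)


class TestBloodPoolFilter:
    def test_bright_blood_untouched(self, rng):
        img = np.full((20, 20), 100.0)
        img += rng.normal(0, 1.0, img.shape)
        blood = np.zeros((20, 20), bool)
        blood[5:15, 5:15] = True
        img[blood] = 150.0  # far above myo mean + SD
        myo = ~blood
        kept = filter_blood_pool(img, blood, myo)
        np.testing.assert_array_equal(kept, blood)

    def test_pixels_at_myocardial_mean_removed(self):
        img = np.zeros((10, 10))
        myo = np.zeros((10, 10), bool)
        myo[:, :3] = True
        img[myo] = 100.0
        blood = np.zeros((10, 10), bool)
        blood[:, 5:] = True
        img[blood] = 200.0
        img[2, 6] = 100.0  # papillary pixel exactly at myo mean: zero deviation
        kept = filter_blood_pool(img, blood, myo)
        assert not kept[2, 6]
        assert kept.sum() == blood.sum() - 1

    def test_removed_set_matches_papillary_truth(self, cine_phantom, cine_spec):
        """The filter recovers the papillary mask on the phantom (Jaccard >= 0.9).

        Checked on the noiseless stack: papillary renders exactly at the
        myocardial mean, the filter's worst case. (Under iid voxel noise the
        per-pixel removal probability saturates at ~68% by construction —
        real papillary muscle is a coherent structure, not iid pixels.)
        """
        stack, truth = cine_phantom
        masks = truth.label_masks[0]
        s = 2
        img = truth.noiseless_stack.voxels[s, :, :, 0]
        blood = masks["blood_pool"][s]
        kept = filter_blood_pool(img, blood, masks["myocardium"][s])
        removed = blood & ~kept
        pap = masks["papillary"][s]
        jaccard = (removed & pap).sum() / (removed | pap).sum()
        assert jaccard >= 0.9


class TestBtc:
    def test_uniform_two_to_one(self):
        img = np.zeros((1, 16, 16))
        myo = np.zeros((1, 16, 16), bool)
        blood = np.zeros((1, 16, 16), bool)
        myo[0, :, :5] = True
        blood[0, :, 10:] = True
        img[myo] = 100.0
        img[blood] = 200.0
        btc, per_slice = compute_btc(img, myo, blood)
        assert btc == pytest.approx(2.0)
        assert per_slice == [pytest.approx(2.0)]

    def test_noisy_phantom_btc_within_3pct(self, cine_phantom):
        stack, truth = cine_phantom
        noisy = add_rician_noise(stack, 5.0, seed=22)
        masks = truth.label_masks[0]
        btc, _ = compute_btc(noisy.voxels[..., 0], masks["myocardium"], masks["blood_pool"])
        assert btc == pytest.approx(250.0 / 100.0, rel=0.03)

    def test_scale_invariance(self, cine_phantom):
        stack, truth = cine_phantom
        masks = truth.label_masks[0]
        img = stack.voxels[..., 0]
        b1, _ = compute_btc(img, masks["myocardium"], masks["blood_pool"])
        b2, _ = compute_btc(3.7 * img, masks["myocardium"], masks["blood_pool"])
        assert b2 == pytest.approx(b1, rel=1e-12)

    def test_zero_myocardium_rejected(self):
        img = np.zeros((1, 8, 8))
        myo = np.zeros((1, 8, 8), bool)
        myo[0, 0, 0] = True
        blood = np.zeros((1, 8, 8), bool)
        blood[0, 4, 4] = True
        img[blood] = 10.0
        with pytest.raises(ValueError, match="zero"):
            compute_btc(img, myo, blood)


class TestNoiseSd:
    def test_all_zero_region_gives_zero(self):
        assert estimate_noise_sd(np.zeros((60, 60)), (slice(0, 50), slice(0, 50))) == 0.0

    def test_constant_region_closed_form(self):
        # sigma = sqrt(64 * 2500 / (2 * 2500 * 16)) = sqrt(2)
        img = np.full((50, 50), 8.0)
        sigma = estimate_noise_sd(img, (slice(0, 50), slice(0, 50)), n_receivers=16)
        assert sigma == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_rayleigh_background_matches_monte_carlo_expectation(self):
        """The estimator's mean on Rayleigh background equals its analytic
        expectation sigma/sqrt(n) (E[v^2] = 2 sigma^2 under the n-receiver
        normalization), evaluated here by Monte Carlo."""
        true_sigma, n_rec = 5.0, 16
        rng = np.random.default_rng(33)
        mc = []
        for _ in range(40):
            bg = np.hypot(rng.normal(0, true_sigma, (50, 50)),
                          rng.normal(0, true_sigma, (50, 50)))
            mc.append(np.sqrt(np.sum(bg**2) / (2 * bg.size * n_rec)))
        expected = true_sigma / math.sqrt(n_rec)
        assert np.mean(mc) == pytest.approx(expected, rel=0.01)
        est = estimate_noise_sd(
            np.hypot(np.random.default_rng(1).normal(0, true_sigma, (50, 50)),
                     np.random.default_rng(2).normal(0, true_sigma, (50, 50))),
            (slice(0, 50), slice(0, 50)), n_receivers=n_rec)
        assert est == pytest.approx(expected, rel=0.05)

    def test_scale_equivariance(self, rng):
        img = rng.random((60, 60)) * 10
        roi = (slice(0, 50), slice(0, 50))
        assert estimate_noise_sd(4.0 * img, roi) == pytest.approx(
            4.0 * estimate_noise_sd(img, roi), rel=1e-12)

    def test_auto_roi_picks_darkest_corner(self):
        img = np.full((120, 120), 50.0)
        img[70:, 70:] = 1.0
        r, c = auto_noise_roi(img)
        assert r.start == 70 and c.start == 70

    def test_tissue_overlap_warns(self):
        img = np.ones((60, 60))
        tissue = np.zeros((60, 60), bool)
        tissue[10, 10] = True
        with pytest.warns(UserWarning, match="overlap"):
            estimate_noise_sd(img, (slice(0, 50), slice(0, 50)), tissue_mask=tissue)


class TestSnr:
    def test_closed_form(self):
        img = np.full((1, 10, 10), 100.0)
        myo = np.ones((1, 10, 10), bool)
        snr, snr_map = compute_snr(img, myo, 10.0)
        assert snr == 10.0
        assert np.nanmax(snr_map) == 10.0

    def test_linearity_in_signal(self, cine_phantom):
        stack, truth = cine_phantom
        myo = truth.label_masks[0]["myocardium"]
        img = stack.voxels[..., 0]
        s1, _ = compute_snr(img, myo, 5.0)
        s2, _ = compute_snr(2.0 * img, myo, 5.0)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_map_rendered_only_inside_myocardium(self, cine_phantom):
        stack, truth = cine_phantom
        myo = truth.label_masks[0]["myocardium"]
        _, snr_map = compute_snr(stack.voxels[..., 0], myo, 5.0)
        assert np.all(np.isnan(snr_map[~myo]))
        assert np.all(np.isfinite(snr_map[myo]))

    def test_snr_decreases_with_coil_distance(self):
        """Mirrors the negative SNR-distance relation on a phantom series."""
        snrs, distances = [], [40.0, 60.0, 80.0]
        for d in distances:
            spec = PhantomSpec(n_slices=4, rows=160, cols=160, pixel_spacing=(1.0, 1.0),
                               n_phases=4, endo_radius_ed=16.0, endo_radius_es=10.0,
                               wall_thickness_ed=8.0, noise_sigma=2.0, seed=77,
                               coil_model=CoilModel([(80.0 - d, 80.0, 12.0)], decay_mm=90.0))
            stack, truth = generate_cine_phantom(spec)
            masks = truth.label_masks[0]
            img = stack.voxels[..., 0]
            sigma = np.mean([estimate_noise_sd(img[s]) for s in range(4)])
            snr, _ = compute_snr(img, masks["myocardium"], sigma)
            snrs.append(snr)
        assert snrs[0] > snrs[1] > snrs[2]


class TestFlipAngle:
    def test_uniform_map(self):
        b1 = np.full((7, 40, 40), 50.0)
        assert estimate_fa_from_b1(b1, (20, 20), 5.0) == pytest.approx(50.0)

    def test_mip_takes_slicewise_maximum(self):
        b1 = np.zeros((5, 30, 30))
        for s, v in enumerate([40.0, 45.0, 50.0, 45.0, 40.0]):
            b1[s] = v
        assert estimate_fa_from_b1(b1, (15, 15), 4.0) == pytest.approx(50.0)

    def test_dropout_recovery_within_2pct(self, rng):
        """MIP over slices recovers a smooth field despite random dropouts."""
        yy, xx = np.mgrid[0:60, 0:60]
        field = 45.0 + 8.0 * np.exp(-((yy - 30) ** 2 + (xx - 30) ** 2) / 800.0)
        b1 = np.repeat(field[None], 5, axis=0)
        drop = rng.random(b1.shape) < 0.4  # independent dropout per slice
        b1[drop] = 0.0
        est = estimate_fa_from_b1(b1, (30, 30), 8.0)
        truth = float(field[(yy - 30) ** 2 + (xx - 30) ** 2 <= 64].mean())
        assert est == pytest.approx(truth, rel=0.02)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slices"):
            estimate_fa_from_b1(np.ones((3, 10, 10)), (5, 5), 2.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            estimate_fa_from_b1(np.ones((5, 10, 10)), (-20, -20), 2.0)


class TestReceiveNormalization:
    def test_max_flip_angle_scan_unchanged(self):
        assert normalize_snr_receive(120.0, 55.0, 55.0) == pytest.approx(120.0)

    def test_sine_ratio_closed_form(self):
        # 100 * sin(60deg)/sin(30deg) = 100 * 0.8660/0.5
        assert normalize_snr_receive(100.0, 30.0, 60.0) == pytest.approx(173.2, abs=0.05)

    def test_literal_mode(self):
        expected = 100.0 / math.sin(30.0 / 60.0)
        assert normalize_snr_receive(100.0, 30.0, 60.0, mode="literal") == pytest.approx(expected)

    def test_transmit_invariance_on_phantoms(self):
        """Two scans differing only in transmit scaling agree after
        normalization while their raw SNR differs."""
        base = PhantomSpec(n_slices=4, rows=160, cols=160, pixel_spacing=(1.0, 1.0),
                           n_phases=4, endo_radius_ed=16.0, endo_radius_es=10.0,
                           wall_thickness_ed=8.0, noise_sigma=0.0, seed=88)
        fa_max = 50.0
        results = []
        for fa in (50.0, 30.0):
            stack, truth = generate_cine_phantom(base)
            scale = math.sin(math.radians(fa)) / math.sin(math.radians(fa_max))
            img = stack.voxels[..., 0] * scale  # transmit-driven signal loss
            img = add_rician_noise(ImageStack(img, base.pixel_spacing, 6.0), 2.0,
                                   seed=89).voxels
            sigma = np.mean([estimate_noise_sd(img[s]) for s in range(4)])
            snr, _ = compute_snr(img, truth.label_masks[0]["myocardium"], sigma)
            results.append((snr, normalize_snr_receive(snr, fa, fa_max)))
        (snr_hi, recv_hi), (snr_lo, recv_lo) = results
        assert snr_lo < 0.75 * snr_hi  # raw SNR clearly differs
        assert recv_lo == pytest.approx(recv_hi, rel=0.03)

    def test_zero_flip_angle_rejected(self):
        with pytest.raises(ValueError, match="flip angle"):
            normalize_snr_receive(100.0, 0.0, 60.0)


class TestDistanceWeight:
    @pytest.mark.parametrize("d, offset, d_max, expected_corr, expected_w", [
        (80.0, 0.0, 80.0, 80.0, 1.0),
        (40.0, 0.0, 80.0, 40.0, 0.5),
        (50.0, 60.0, 80.0, 25.0, 25.0 / 80.0),
    ])
    def test_closed_forms(self, d, offset, d_max, expected_corr, expected_w):
        d_corr, w = compute_distance_weight(d, offset, d_max)
        assert d_corr == pytest.approx(expected_corr, rel=1e-12)
        assert w == pytest.approx(expected_w, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_distance_weight(0.0, 0.0, 80.0)
        with pytest.raises(ValueError):
            compute_distance_weight(40.0, 95.0, 80.0)
        with pytest.raises(ValueError):
            compute_distance_weight(40.0, 0.0, 0.0)


def test_snr_distance_correlation_negative_on_phantom_series():
    """Six phantoms at increasing coil distance: Pearson r(SNR, d) < 0."""
    distances = [45.0, 52.0, 58.0, 64.0, 70.0, 76.0]
    snrs = []
    for i, d in enumerate(distances):
        spec = PhantomSpec(n_slices=3, rows=160, cols=160, pixel_spacing=(1.0, 1.0),
                           n_phases=2, endo_radius_ed=16.0, endo_radius_es=10.0,
                           wall_thickness_ed=8.0, noise_sigma=2.0, seed=200 + i,
                           coil_model=CoilModel([(80.0 - d, 80.0, 9.0)], decay_mm=90.0))
        stack, truth = generate_cine_phantom(spec)
        qr = quality_report(stack.voxels[..., 0], truth.label_masks[0]["myocardium"],
                            truth.label_masks[0]["blood_pool"])
        snrs.append(qr.snr_myo)
    assert pearsonr(snrs, distances).statistic < 0
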
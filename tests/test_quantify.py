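"""SBR/dB identities, display normalization algebra, integration and profiles."""

import numpy as np
import pytest

from gvscan.assemble import ROISet, build_volume, rois_from_truth
from gvscan.config import ScanPlan, display_constants
from gvscan.quantify import (
    ex_vivo_profile,
    integrate_2d,
    normalize_display,
    overlay,
    sbr,
    to_db,
    total_signal,
)
from gvscan.simulate import VolumeTruth, simulate_scan


@pytest.fixture
def demo_volume(small_invivo_config):
    plan = ScanPlan(3, 1.6, 6, 0.5)
    gv = np.zeros((6, 24, 48))
    gv[2, 10, 20] = 5.0
    gv[4, 15, 40] = 2.0
    truth = VolumeTruth(gv=gv, background=np.ones_like(gv), noise_sd=0.0, speckle_scale=0.0)
    ss = simulate_scan(plan, truth, small_invivo_config, seed=0)
    return build_volume(ss, rois_from_truth(ss))


class TestSBRAndDb:
    def test_self_ratio_is_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 5, (10, 10))
        roi = np.zeros((10, 10), dtype=bool)
        roi[2:6, 2:6] = True
        assert sbr(img, roi, roi) == pytest.approx(1.0)
        assert to_db(sbr(img, roi, roi)) == pytest.approx(0.0, abs=1e-12)

    def test_ratio_of_means(self):
        img = np.zeros((4, 4))
        img[:2] = 10.0
        img[2:] = 2.0
        assert sbr(img, img >= 10, img < 10) == pytest.approx(5.0)

    def test_db_oracle(self):
        rng = np.random.default_rng(1)
        for x in rng.uniform(0.01, 100, 50):
            assert to_db(x) == pytest.approx(20.0 * np.log10(x), abs=1e-12)
        assert to_db(10.0) == pytest.approx(20.0, abs=1e-12)

    def test_db_log_identity(self):
        a, b = 3.7, 12.1
        assert to_db(a * b) == pytest.approx(to_db(a) + to_db(b), abs=1e-12)

    def test_invalid_inputs_flagged(self):
        img = np.zeros((4, 4))
        roi = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            sbr(img, roi, roi)  # zero background mean
        with pytest.raises(ValueError):
            to_db(0.0)
        with pytest.raises(ValueError):
            sbr(img, np.zeros((4, 4), dtype=bool), roi)

    def test_sbr_monotone_in_gv_amplitude(self, small_invivo_config):
        """Phantom wells at increasing expression level give increasing SBR."""
        from gvscan.reconstruct import burst_invitro
        from gvscan.simulate import SceneTruth, simulate_acquisition

        sample = np.zeros((24, 16), dtype=bool)
        sample[8:12, 6:10] = True
        background = np.zeros((24, 16), dtype=bool)
        background[18:22, 6:10] = True
        values = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            gv = np.where(sample, amp, 0.0)
            scene = SceneTruth(gv_map=gv, background_map=np.ones((24, 16)),
                               speckle_scale=0.0, noise_sd=0.0, seed=0)
            cfg = small_invivo_config
            stack = simulate_acquisition(cfg, scene)
            from gvscan.reconstruct import burst_star

            img = burst_star(stack).pixels + 1.0  # shift off zero background
            values.append(sbr(img, sample, background))
        assert all(b > a for a, b in zip(values, values[1:]))


class TestNormalizeDisplay:
    def test_background_equal_image_maps_to_unity(self):
        params = display_constants("burst", "L22-14v")
        imgs, (lo, hi) = normalize_display([np.full((5, 5), 4.0)], params)
        # normalized image is 1 -> 0 dB, floored to the lower limit A in dB
        assert lo == pytest.approx(20 * np.log10(3.0))
        np.testing.assert_allclose(imgs[0], lo)

    def test_scale_invariance_across_compared_set(self):
        params = display_constants("burst", "L22-14vX")
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0.5, 3, (6, 6)), rng.uniform(0.5, 3, (6, 6))
        out1, lim1 = normalize_display([a, b], params)
        out2, lim2 = normalize_display([7.3 * a, 7.3 * b], params)
        np.testing.assert_allclose(out1[0], out2[0], atol=1e-10)
        np.testing.assert_allclose(out1[1], out2[1], atol=1e-10)
        assert lim1 == pytest.approx(lim2)

    def test_limits_shared_across_set_not_per_image(self):
        params = display_constants("burst", "L22-14v")
        dim = np.full((4, 4), 1.0)
        bright = np.full((4, 4), 1.0)
        bright[0, 0] = 50.0
        _, (lo_set, hi_set) = normalize_display([dim, bright], params)
        _, (lo_dim, hi_dim) = normalize_display([dim], params)
        assert hi_set > hi_dim  # the set maximum drives the shared upper limit

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            normalize_display([], display_constants("burst", "L22-14v"))


class TestIntegrationAndTotals:
    def test_fubini_2d_sum_equals_total_signal(self, demo_volume):
        _, burst_2d = integrate_2d(demo_volume, bmode_depth_range=(0.0, 2.0))
        assert burst_2d.sum() == pytest.approx(total_signal(demo_volume), abs=1e-12)

    def test_depth_window_selects_bmode_rows(self, small_invivo_config):
        plan = ScanPlan(1, 1.6, 2, 0.5)
        gv = np.zeros((2, 24, 16))
        truth = VolumeTruth(gv=gv, background=np.ones_like(gv), speckle_scale=0.0)
        ss = simulate_scan(plan, truth, small_invivo_config, seed=0)
        vol = build_volume(ss, ROISet(masks={j: np.ones((24, 16), bool) for j in range(2)}))
        bmode_2d, _ = integrate_2d(vol, bmode_depth_range=(0.5, 1.0))
        # [0.5, 1.0) mm at 0.1 mm/px -> rows 5..9, five rows of unit background
        np.testing.assert_allclose(bmode_2d, 5.0)

    def test_impulse_depth_routing(self, small_invivo_config):
        """A deep inclusion appears in the BURST* map but not the B-mode window."""
        plan = ScanPlan(1, 1.6, 1, 0.5)
        gv = np.zeros((1, 24, 16))
        gv[0, 20, 8] = 3.0  # 2.0 mm deep
        truth = VolumeTruth(gv=gv, background=np.ones_like(gv), speckle_scale=0.0)
        ss = simulate_scan(plan, truth, small_invivo_config, seed=0)
        vol = build_volume(ss, rois_from_truth(ss))
        bmode_2d, burst_2d = integrate_2d(vol, bmode_depth_range=(0.0, 1.0))
        assert burst_2d[0, 8] > 0
        assert bmode_2d[0, 8] == pytest.approx(10.0)  # background only in window

    def test_total_signal_additivity_and_empty_mask(self, demo_volume):
        both = total_signal(demo_volume)
        v1 = demo_volume
        only_first = np.zeros_like(v1.mask)
        only_first[2] = v1.mask[2]
        only_second = np.zeros_like(v1.mask)
        only_second[4] = v1.mask[4]
        import dataclasses

        t1 = total_signal(dataclasses.replace(v1, mask=only_first))
        t2 = total_signal(dataclasses.replace(v1, mask=only_second))
        assert both == pytest.approx(t1 + t2, abs=1e-12)
        assert total_signal(dataclasses.replace(v1, mask=np.zeros_like(v1.mask))) == 0.0

    def test_total_monotone_in_gv_amplitude(self, small_invivo_config):
        totals = []
        for amp in (1.0, 2.0, 4.0):
            plan = ScanPlan(1, 1.6, 2, 0.5)
            gv = np.zeros((2, 24, 16))
            gv[1, 10, 8] = amp
            truth = VolumeTruth(gv=gv, background=np.ones_like(gv), speckle_scale=0.0)
            ss = simulate_scan(plan, truth, small_invivo_config, seed=0)
            totals.append(total_signal(build_volume(ss, rois_from_truth(ss))))
        assert all(b > a for a, b in zip(totals, totals[1:]))


class TestOverlay:
    def test_threshold_above_max_shows_pure_bmode(self):
        rng = np.random.default_rng(0)
        burst = rng.uniform(0, 1, (8, 8))
        bm = rng.uniform(1, 2, (8, 8))
        comp = overlay(burst, bm, threshold=burst.max() + 1)
        from matplotlib import cm

        gray_only = cm.gray(np.zeros((8, 8)))[..., :3]
        assert comp.shape == (8, 8, 3)
        # no hot pixels: all three channels equal (gray)
        assert np.allclose(comp[..., 0], comp[..., 1])
        assert np.allclose(comp[..., 1], comp[..., 2])

    def test_percentile_policy_bounds_shown_fraction(self):
        rng = np.random.default_rng(1)
        burst = rng.uniform(0, 1, (50, 50))
        bm = np.ones((50, 50))
        comp = overlay(burst, bm, percentile=97.5)
        shown = ~(
            np.isclose(comp[..., 0], comp[..., 1]) & np.isclose(comp[..., 1], comp[..., 2])
        )
        assert shown.mean() <= 0.026

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay(np.ones((4, 4)), np.ones((5, 5)))


class TestExVivoProfile:
    def _series(self, config, amp=1.0, station_of_signal=5, n=10):
        from gvscan.assemble import assemble_ex_vivo
        from gvscan.simulate import SceneTruth, simulate_acquisition

        stacks = []
        for st in range(n):
            gv = np.zeros((24, 16))
            if st == station_of_signal:
                gv[8, 8] = amp
            scene = SceneTruth(gv_map=gv, background_map=np.ones((24, 16)),
                               speckle_scale=0.0, noise_sd=0.0, seed=st)
            stack = simulate_acquisition(config, scene)
            stack.station = st
            stacks.append(stack)
        return assemble_ex_vivo(stacks, landmark_station=2)

    def test_all_zero_series_profile_zero(self, small_invivo_config):
        series = self._series(small_invivo_config, amp=0.0)
        prof = ex_vivo_profile(series, depth_range_mm=(0.0, 2.4), axial_spacing=0.1)
        np.testing.assert_array_equal(prof.integrated_signal.to_numpy(), 0.0)

    def test_linearity_in_amplitude(self, small_invivo_config):
        p1 = ex_vivo_profile(self._series(small_invivo_config, amp=1.0),
                             depth_range_mm=(0.0, 2.4), axial_spacing=0.1)
        p2 = ex_vivo_profile(self._series(small_invivo_config, amp=2.0),
                             depth_range_mm=(0.0, 2.4), axial_spacing=0.1)
        np.testing.assert_allclose(
            p2.integrated_signal.to_numpy(), 2.0 * p1.integrated_signal.to_numpy(),
            atol=1e-12,
        )

    def test_depth_band_excludes_shallow_signal(self, small_invivo_config):
        series = self._series(small_invivo_config)  # signal at 0.8 mm depth
        prof = ex_vivo_profile(series, depth_range_mm=(1.0, 2.4), axial_spacing=0.1)
        np.testing.assert_array_equal(prof.integrated_signal.to_numpy(), 0.0)
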
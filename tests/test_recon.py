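import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import rotcam as rc
from rotcam.recon import KernelConfig, SkyMap, kernel_profile


def single_event(scatterer=0, absorber=4, e1=93.35, e2=114.65, theta_rot=0.0, weight=1.0):
    return pd.DataFrame({
        "event_id": [0], "time_lag_ns": [0.0],
        "scatterer": [scatterer], "absorber": [absorber],
        "e1_kev": [e1], "e2_kev": [e2],
        "theta_rot_deg": [theta_rot], "weight": [weight],
    })


class TestScatteringAngle:
    def test_forward_limit(self):
        assert rc.scattering_angle(0.0, 170.0) == pytest.approx(0.0)

    def test_equal_half_kev_deposits_give_right_angle(self):
        # 1/255.5 - 1/511 = 1/511 exactly, so cos(theta) = 0
        assert rc.scattering_angle(255.5, 255.5) == pytest.approx(90.0)

    def test_backscatter_boundary(self):
        assert rc.scattering_angle(93.35, 114.65) == pytest.approx(180.0, abs=0.5)

    def test_unphysical_raises(self):
        with pytest.raises(ValueError, match="cos"):
            rc.scattering_angle(1300.0, 5.0)


class TestKernels:
    def test_conventional_peaks_at_one(self):
        g = kernel_profile(np.array([42.0]), 42.0, KernelConfig("conventional", 8.0))
        assert g[0] == pytest.approx(1.0)

    def test_sharpening_profile_integrates_to_zero(self):
        cfg = KernelConfig("sharpening", 8.0, 1.7)
        val, _ = quad(lambda t: kernel_profile(t, 40.0, cfg), -np.inf, np.inf)
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_sharpening_peak_value(self):
        cfg = KernelConfig("sharpening", 8.0, 1.0)
        peak = kernel_profile(np.array([40.0]), 40.0, cfg)[0]
        # 2 - 2 exp(-2) at the ring center
        assert peak == pytest.approx(2 - 2 * np.exp(-2.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KernelConfig("boxcar", 8.0)
        with pytest.raises(ValueError):
            KernelConfig("sharpening", -1.0)
        with pytest.raises(ValueError):
            KernelConfig("sharpening", 8.0, k=0.0)


class TestBackprojection:
    def test_single_ring_geometry(self, caf2_detector):
        # scatterer on +x axis, absorber on +z axis: the cone axis points from
        # the absorber to the scatterer; a 90 degree ring passes near the map
        # point whose direction from the apex is perpendicular to that axis
        ev = single_event(scatterer=0, absorber=4, e1=255.5, e2=255.5)
        sky = rc.backproject(ev, caf2_detector, KernelConfig("conventional", 8.0))
        # unit peak up to pixel-center discretization of the ring
        assert sky.data.max() == pytest.approx(1.0, abs=0.02)
        # ring: pixels at the maximum sit ~90 deg from the axis seen from the apex
        axis = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        apex = caf2_detector.crystal_centers[0]
        pix = sky.pixel_directions() * sky.radius_cm - apex
        pix /= np.linalg.norm(pix, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(pix @ axis, -1, 1)))
        hot = sky.data.ravel() > 0.95
        assert hot.any()
        assert np.all(np.abs(ang[hot] - 90.0) < 3.0)

    def test_additivity(self, caf2_detector, run208):
        ev = run208.ordered.iloc[:400]
        a = rc.backproject(ev.iloc[:150], caf2_detector)
        b = rc.backproject(ev.iloc[150:].reset_index(drop=True), caf2_detector)
        both = rc.backproject(ev, caf2_detector)
        np.testing.assert_allclose(a.data + b.data, both.data, rtol=1e-10, atol=1e-12)

    def test_empty_event_list_warns_and_zero_map(self, caf2_detector):
        with pytest.warns(UserWarning, match="no events"):
            sky = rc.backproject(run_events_empty(), caf2_detector)
        assert np.all(sky.data == 0)

    def test_peak_at_source_direction(self, sky208):
        # one 2-degree bin of slack plus statistical wander at 3000 events
        _, az, el = sky208.peak()
        assert abs(az) <= 4.0 and abs(el) <= 4.0

    def test_sharpening_background_near_zero(self, sky208):
        # positive and negative ring lobes cancel away from the source; the
        # residue at these statistics stays a few percent of the peak
        daz = sky208.azimuth_centers
        far = np.abs(daz) > 60
        bg = sky208.data[:, far]
        assert abs(bg.mean()) < 0.05 * sky208.data.max()

    def test_rotation_compensation_matches_unrotated(self, caf2_detector):
        # the same physical configuration simulated with and without source
        # rotation must reconstruct to the same peak direction and width
        reports = {}
        for rotate, seed in ((True, 301), (False, 302)):
            run = rc.simulate_point_source(caf2_detector, 208.0, target_ordered=1500,
                                           seed=seed, rotate_source=rotate,
                                           resolution=rc.CSI_MEASURED)
            rep, sky = rc.evaluate_point_source(run)
            reports[rotate] = (rep, sky)
        for rep, sky in reports.values():
            _, az, el = sky.peak()
            assert abs(az) <= 3.0 and abs(el) <= 3.0
        s_rot = reports[True][0].sigma_deg
        s_fix = reports[False][0].sigma_deg
        assert s_rot == pytest.approx(s_fix, rel=0.25)


def run_events_empty():
    return pd.DataFrame({
        "event_id": [], "time_lag_ns": [], "scatterer": [], "absorber": [],
        "e1_kev": [], "e2_kev": [], "theta_rot_deg": [], "weight": [],
    })


class TestCalibration:
    def test_calibrated_peak_equals_n_by_construction(self, caf2_detector, run208):
        ev = run208.ordered
        k = rc.calibrate_k(ev, caf2_detector)
        sky = rc.backproject(ev, caf2_detector, KernelConfig("sharpening", 8.0, k))
        n = float(ev["weight"].sum())
        assert sky.data.max() == pytest.approx(n, rel=1e-9)

    def test_independent_run_peak_near_n(self, caf2_detector, run208):
        k = rc.calibrate_k(run208.ordered, caf2_detector)
        other = rc.simulate_point_source(caf2_detector, 208.0, target_ordered=1500,
                                         seed=777, resolution=rc.CSI_MEASURED)
        sky = rc.backproject(other.ordered, caf2_detector, KernelConfig("sharpening", 8.0, k))
        n = float(other.ordered["weight"].sum())
        assert sky.data.max() == pytest.approx(n, rel=0.15)

    def test_linearity_in_event_count(self, caf2_detector, run208):
        ev = run208.ordered
        k = rc.calibrate_k(ev, caf2_detector)
        # trim to half the source events: peak should halve
        codes = pd.factorize(ev["event_id"])[0]
        half = ev[codes < codes.max() // 2].reset_index(drop=True)
        sky = rc.backproject(half, caf2_detector, KernelConfig("sharpening", 8.0, k))
        n_half = float(half["weight"].sum())
        assert sky.data.max() == pytest.approx(n_half, rel=0.15)


class TestSkyMap:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="90x180"):
            SkyMap(data=np.zeros((10, 10)))

    def test_grid_conventions(self):
        sky = SkyMap()
        assert sky.azimuth_centers[0] == -179.0
        assert sky.azimuth_centers[-1] == 179.0
        assert sky.elevation_centers[0] == -89.0
        assert sky.elevation_centers[-1] == 89.0
        dirs = sky.pixel_directions()
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0)
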
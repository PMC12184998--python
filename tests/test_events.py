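import numpy as np
import pandas as pd
import pytest

import rotcam as rc
from rotcam.events import EnergyWindow, _double_gauss_exp, total_energy_spectrum
from rotcam.transport import HistoryBatch


def make_batch(deposits, theta_rot=None):
    dep = np.asarray(deposits, dtype=float)
    rot = np.zeros(len(dep)) if theta_rot is None else np.asarray(theta_rot, float)
    return HistoryBatch(rot, dep, n_emitted=len(dep), solid_angle_fraction=1.0,
                        seed=0, energy=208.0)


def two_crystal_rows(n, e0=208.0, e1=50.0):
    dep = np.zeros((n, 6))
    dep[:, 0] = e0
    dep[:, 1] = e1
    return dep


class TestResolutionModel:
    def test_caf2_two_sigma_window_at_208(self):
        s = float(rc.CAF2_MEASURED.sigma(208.0))
        assert s == pytest.approx(14.16, abs=0.02)
        w = rc.CAF2_MEASURED.window(208.0, 2)
        assert w.upper - w.center == pytest.approx(28.3, abs=0.1)
        w113 = rc.CAF2_MEASURED.window(113.0, 2)
        assert w113.center - w113.lower == pytest.approx(20.9, abs=0.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            rc.ResolutionModel(-1.0, 0.5)
        with pytest.raises(ValueError):
            rc.ResolutionModel(1.0, 1.5)

    def test_asymmetric_window(self):
        w = rc.CAF2_MEASURED.window(141.0, 2, n_sigma_low=1)
        s = float(rc.CAF2_MEASURED.sigma(141.0))
        assert w.lower == pytest.approx(141.0 - s)
        assert w.upper == pytest.approx(141.0 + 2 * s)

    def test_window_ordering_enforced(self):
        with pytest.raises(ValueError):
            EnergyWindow(100.0, 120.0, 140.0)


class TestSmearing:
    def test_sample_sd_matches_model(self):
        batch = make_batch(two_crystal_rows(100_000))
        out = rc.smear_deposits(batch, rc.CAF2_MEASURED, threshold_kev=10.0, rng=1)
        sd = out["e_a_kev"].std()
        assert sd == pytest.approx(float(rc.CAF2_MEASURED.sigma(208.0)), rel=0.01)
        assert out["e_a_kev"].mean() == pytest.approx(208.0, rel=0.002)

    def test_vanishing_resolution_limit(self):
        batch = make_batch(two_crystal_rows(1000))
        sharp = rc.ResolutionModel(1e-9, 0.5)
        out = rc.smear_deposits(batch, sharp, rng=2)
        np.testing.assert_allclose(out["e_a_kev"], 208.0, atol=1e-5)
        np.testing.assert_allclose(out["e_b_kev"], 50.0, atol=1e-5)

    def test_only_exactly_two_crystal_events_survive(self):
        dep = np.zeros((4, 6))
        dep[0, 0] = 208.0                      # one crystal -> dropped
        dep[1, :2] = (150.0, 58.0)             # two -> kept
        dep[2, :3] = (100.0, 60.0, 48.0)       # three -> dropped
        dep[3, :2] = (200.0, 11.0)             # second may fall below threshold
        out = rc.smear_deposits(make_batch(dep), rc.ResolutionModel(1e-9, 0.5),
                                threshold_kev=10.0, rng=3)
        assert set(out["event_id"]) <= {1, 3}
        assert 1 in set(out["event_id"])

    def test_all_smeared_values_positive(self):
        dep = np.zeros((20_000, 6))
        dep[:, 0] = 12.0  # heavily smeared small deposit: redraw path exercised
        dep[:, 1] = 208.0
        out = rc.smear_deposits(make_batch(dep), rc.CAF2_MEASURED, threshold_kev=0.1, rng=4)
        assert (out[["e_a_kev", "e_b_kev"]].to_numpy() > 0).all()

    def test_theta_rot_carried_through(self):
        rot = np.arange(5.0)
        out = rc.smear_deposits(make_batch(two_crystal_rows(5), rot),
                                rc.ResolutionModel(1e-9, 0.5), rng=5)
        np.testing.assert_allclose(out["theta_rot_deg"], rot)


def event_frame(sums, lags=None):
    n = len(sums)
    return pd.DataFrame({
        "event_id": np.arange(n),
        "time_lag_ns": np.zeros(n) if lags is None else np.asarray(lags, float),
        "crystal_a": np.zeros(n, dtype=int),
        "crystal_b": np.ones(n, dtype=int),
        "e_a_kev": np.asarray(sums, float) / 2,
        "e_b_kev": np.asarray(sums, float) / 2,
        "theta_rot_deg": np.zeros(n),
    })


class TestCuts:
    def test_tdc_window_boundaries(self):
        df = event_frame([208.0] * 3, lags=[399.0, 401.0, -400.0])
        out = rc.tdc_cut(df, 400.0)
        assert list(out["time_lag_ns"]) == [399.0, -400.0]

    def test_tdc_passthrough_for_simulated(self):
        df = event_frame([208.0] * 10)
        assert len(rc.tdc_cut(df)) == 10

    def test_tdc_counting(self, rng):
        lags = rng.uniform(-1000, 1000, 500)
        df = event_frame([208.0] * 500, lags=lags)
        out = rc.tdc_cut(df, 400.0)
        assert len(out) == 500 - int((np.abs(lags) > 400).sum())

    def test_adc_closed_interval(self):
        w = EnergyWindow(208.0, 180.0, 236.0)
        df = event_frame([208.0, 236.0, 236.1, 179.9, 180.0])
        out = rc.adc_cut(df, w)
        assert sorted(out["e_a_kev"] * 2) == [180.0, 208.0, 236.0]

    def test_adc_counting_against_brute_force(self, rng):
        sums = rng.uniform(100, 300, 1000)
        w = EnergyWindow(208.0, 180.0, 236.0)
        out = rc.adc_cut(event_frame(sums), w)
        assert len(out) == int(((sums >= 180.0) & (sums <= 236.0)).sum())

    def test_cuts_idempotent(self, rng):
        df = event_frame(rng.uniform(100, 300, 400), lags=rng.uniform(-800, 800, 400))
        w = EnergyWindow(208.0, 180.0, 236.0)
        once = rc.adc_cut(rc.tdc_cut(df), w)
        twice = rc.adc_cut(rc.tdc_cut(once), w)
        pd.testing.assert_frame_equal(once, twice)


def pair_frame(ea, eb):
    return pd.DataFrame({
        "event_id": [0],
        "time_lag_ns": [0.0],
        "crystal_a": [0],
        "crystal_b": [1],
        "e_a_kev": [ea],
        "e_b_kev": [eb],
        "theta_rot_deg": [0.0],
    })


class TestOrdering:
    def test_backscatter_boundary_keeps_single_ordering(self):
        # 208 keV photon scattered at 180 deg: E1 = 93.35, E2 = 114.65
        out = rc.order_scatterer_absorber(pair_frame(93.35, 114.65))
        assert len(out) == 1
        assert out.loc[0, "e2_kev"] == pytest.approx(114.65)
        assert out.loc[0, "weight"] == 1.0
        theta = rc.scattering_angle(out.loc[0, "e1_kev"], out.loc[0, "e2_kev"])
        assert theta == pytest.approx(180.0, abs=0.5)

    def test_symmetric_511_split_both_ways(self):
        out = rc.order_scatterer_absorber(pair_frame(255.5, 255.5))
        assert len(out) == 2
        np.testing.assert_allclose(out["weight"], 0.5)
        for _, row in out.iterrows():
            assert rc.scattering_angle(row["e1_kev"], row["e2_kev"]) == pytest.approx(90.0)

    def test_tiny_absorber_deposit_invalid(self):
        # 501 keV split (1, 500): E2 = 1 keV implies |cos theta| > 1
        out = rc.order_scatterer_absorber(pair_frame(1.0, 500.0))
        assert len(out) == 1
        assert out.loc[0, "e2_kev"] == pytest.approx(500.0)

    def test_fully_unphysical_event_discarded_and_counted(self):
        # an even 104/104 split of 208 keV: either absorber deposit is below
        # the 114.7 keV backscatter floor, so no assignment is physical
        out = rc.order_scatterer_absorber(pair_frame(104.0, 104.0))
        assert len(out) == 0
        assert out.attrs["n_discarded"] == 1

    def test_weights_sum_to_one_per_kept_event(self, run208):
        w = run208.ordered.groupby("event_id")["weight"].sum()
        np.testing.assert_allclose(w, 1.0)

    def test_lower_first_strategy(self):
        out = rc.order_scatterer_absorber(pair_frame(150.0, 58.0), strategy="lower_first")
        assert len(out) == 1
        assert out.loc[0, "e1_kev"] == 58.0
        assert out.loc[0, "weight"] == 1.0

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="strategy"):
            rc.order_scatterer_absorber(pair_frame(100.0, 100.0), strategy="random")


class TestPhotopeakFit:
    def synth_spectrum(self, p, rng, n_scale=1.0):
        e = np.arange(61.0, 260.0, 2.0)
        y = _double_gauss_exp(e, *p) * n_scale
        return e, rng.poisson(np.maximum(y, 0.0)).astype(float)

    def test_parameter_recovery_within_three_se(self, rng):
        truth = [900.0, 9.0, 350.0, 10.0, -0.012, 6.0]
        e, y = self.synth_spectrum(truth, rng)
        res = rc.fit_photopeaks(e, y)
        for i in (0, 2):
            assert abs(res["params"][i] - truth[i]) < 3 * res["errors"][i] + 1e-9
        assert res["sigma_113"] == pytest.approx(9.0, abs=1.0)
        assert res["sigma_141"] == pytest.approx(10.0, abs=1.5)
        w = res["window_141"]
        assert w.lower == pytest.approx(141.0 - res["sigma_141"], abs=1e-9)
        assert w.upper == pytest.approx(141.0 + 2 * res["sigma_141"], abs=1e-9)

    def test_absent_141_peak_consistent_with_zero(self, rng):
        truth = [900.0, 9.0, 0.0, 10.0, -0.012, 6.0]
        e, y = self.synth_spectrum(truth, rng)
        res = rc.fit_photopeaks(e, y)
        assert abs(res["params"][2]) < 3 * res["errors"][2] + 5.0

    def test_pure_exponential_recovers_continuum(self, rng):
        truth = [0.0, 9.0, 0.0, 10.0, -0.015, 7.5]
        e, y = self.synth_spectrum(truth, rng)
        res = rc.fit_photopeaks(e, y)
        assert res["params"][4] == pytest.approx(-0.015, abs=0.002)
        assert res["params"][5] == pytest.approx(7.5, abs=0.4)

    def test_spectrum_binning(self):
        df = event_frame([100.0, 101.0, 150.0])
        centers, counts = total_energy_spectrum(df, bin_kev=2.0, e_min=60.0, e_max=260.0)
        assert counts.sum() == 3
        assert centers[0] == 61.0

    def test_centers_are_fixed(self):
        with pytest.raises(ValueError, match="113"):
            rc.fit_photopeaks(np.arange(60, 260, 2.0), np.ones(100), peaks=(100.0, 141.0))
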
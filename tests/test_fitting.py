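"""Parameter estimation from thermograms, optical melts and titrations."""

import numpy as np
import pytest

import thermostab as ts
from thermostab.constants import celsius_to_kelvin
from thermostab.fitting import NoTransitionError
from thermostab.thermogram import Thermogram


def excess_from(params, noise_sd=0.0, seed=0, grid=(15.0, 95.0, 0.1)):
    tg, _ = ts.simulate_thermogram(
        ts.SimulationSpec(params=params, noise_sd=noise_sd, seed=seed, grid=grid)
    )
    return tg.with_values(tg.values, stage="excess")


class TestInitialGuess:
    @pytest.mark.parametrize(
        "tm_c,dh_cal,dh_vh",
        [(62.5, 111.6e3, 96.3e3), (71.0, 120.4e3, 139.9e3), (45.0, 80e3, 80e3)],
    )
    def test_noiseless_guess_within_5_percent(self, tm_c, dh_cal, dh_vh):
        p = ts.TwoStateParams(celsius_to_kelvin(tm_c), dh_cal, dh_vh)
        guess = ts.initial_guess(excess_from(p))
        assert guess.tm == pytest.approx(p.tm, rel=0.005)
        assert guess.dh_cal == pytest.approx(p.dh_cal, rel=0.05)
        assert guess.dh_vh == pytest.approx(p.dh_vh, rel=0.05)

    def test_flat_input_raises(self):
        t = np.linspace(290, 360, 100)
        with pytest.raises(NoTransitionError):
            ts.initial_guess(Thermogram(t, np.zeros(100), stage="excess"))

    def test_edge_peak_raises(self):
        t = np.linspace(290, 360, 100)
        values = np.linspace(0, 1000, 100)  # maximum at the last grid point
        with pytest.raises(NoTransitionError):
            ts.initial_guess(Thermogram(t, values, stage="excess"))


class TestTwoStateFit:
    def test_noiseless_recovery_exact(self, apo_params):
        res = ts.fit_two_state(excess_from(apo_params))
        assert res.converged
        assert res.params.tm == pytest.approx(apo_params.tm, rel=1e-6)
        assert res.params.dh_cal == pytest.approx(apo_params.dh_cal, rel=1e-6)
        assert res.params.dh_vh == pytest.approx(apo_params.dh_vh, rel=1e-6)

    def test_destabilised_mutant_midpoint_recovered(self):
        res = ts.fit_two_state(excess_from(ts.G325D_PARAMS))
        assert res.summary()["tm_celsius"] == pytest.approx(52.1, abs=0.1)

    def test_noisy_recovery_over_seeds(self, apo_params):
        tms, dhs = [], []
        for seed in range(20):
            res = ts.fit_two_state(excess_from(apo_params, noise_sd=100.0, seed=seed))
            s = res.summary()
            tms.append(s["tm_celsius"])
            dhs.append(s["dh_cal_kcal"])
        assert np.mean(tms) == pytest.approx(62.5, abs=0.1)
        assert np.mean(dhs) == pytest.approx(111.6, rel=0.03)

    def test_standard_errors_positive_under_noise(self, apo_params):
        res = ts.fit_two_state(excess_from(apo_params, noise_sd=100.0, seed=1))
        assert all(v > 0 for v in res.std_errors.values())

    def test_scan_rate_metadata_ignored(self, apo_params):
        """Equilibrium analysis: the fit cannot depend on the scan rate."""
        fits = []
        for rate in (0.3, 1.5):
            tg, _ = ts.simulate_thermogram(
                ts.SimulationSpec(params=apo_params, scan_rate_k_per_min=rate)
            )
            fits.append(ts.fit_two_state(tg.with_values(tg.values, stage="excess")))
        assert fits[0].params == fits[1].params

    def test_grid_refinement_invariance(self, apo_params):
        coarse = ts.fit_two_state(excess_from(apo_params, grid=(15.0, 95.0, 0.1)))
        fine = ts.fit_two_state(excess_from(apo_params, grid=(15.0, 95.0, 0.05)))
        assert coarse.params.tm == pytest.approx(fine.params.tm, rel=1e-4)
        assert coarse.params.dh_cal == pytest.approx(fine.params.dh_cal, rel=1e-4)

    def test_sklearn_estimator_interface(self, apo_params):
        tg = excess_from(apo_params)
        est = ts.TwoStateCalorimetryModel()
        est.fit(tg.temperature_c.reshape(-1, 1), tg.values)
        assert est.tm_celsius_ == pytest.approx(62.5, abs=1e-4)
        pred = est.predict(tg.temperature_c)
        assert np.allclose(pred, tg.values, atol=1e-6)
        assert est.get_params()["tol"] == ts.TwoStateCalorimetryModel().tol


class TestVantHoffRatio:
    def test_equal_enthalpies_give_unity(self):
        p = ts.TwoStateParams(335.0, 1e5, 1e5)
        assert ts.vant_hoff_ratio(p) == 1.0

    @pytest.mark.parametrize(
        "dh_cal,dh_vh,expected",
        [(111.6e3, 96.3e3, 1.16), (120.4e3, 139.9e3, 0.86)],
    )
    def test_reference_ratios_inside_two_state_band(self, dh_cal, dh_vh, expected):
        r = ts.vant_hoff_ratio(ts.TwoStateParams(335.0, dh_cal, dh_vh))
        assert r == pytest.approx(expected, abs=0.005)
        assert 0.8 <= r <= 1.2


class TestCdMeltFit:
    def test_noiseless_recovery(self, cd_params):
        mc, _ = ts.simulate_cd_melt(
            ts.SimulationSpec(params=cd_params, grid=(25.0, 95.0, 0.5))
        )
        res = ts.fit_cd_melt(mc)
        assert res.converged
        assert res.params.tm_app == pytest.approx(cd_params.tm_app, rel=1e-6)
        assert res.params.dh_vh_app == pytest.approx(cd_params.dh_vh_app, rel=1e-4)

    def test_flat_baseline_midpoint_at_half_height(self):
        p = ts.CdMeltParams(celsius_to_kelvin(60.0), 1e5, 0.0, 0.0, 1.0, 0.0)
        mc, _ = ts.simulate_cd_melt(ts.SimulationSpec(params=p, grid=(25.0, 95.0, 0.5)))
        res = ts.fit_cd_melt(mc)
        i = np.argmin(np.abs(mc.signal - 0.5))
        assert res.summary()["tm_app_celsius"] == pytest.approx(
            mc.temperature_c[i], abs=0.5
        )

    def test_noisy_midpoint_within_half_degree(self, cd_params):
        amplitude = 7.0  # native/denatured separation in signal units
        tms = []
        for seed in range(20):
            mc, _ = ts.simulate_cd_melt(
                ts.SimulationSpec(
                    params=cd_params,
                    grid=(25.0, 95.0, 0.5),
                    noise_sd=0.02 * amplitude,
                    seed=seed,
                )
            )
            tms.append(ts.fit_cd_melt(mc).summary()["tm_app_celsius"])
        assert np.mean(tms) == pytest.approx(68.0, abs=0.5)

    def test_too_few_points_rejected(self, cd_params):
        mc, _ = ts.simulate_cd_melt(
            ts.SimulationSpec(params=cd_params, grid=(25.0, 95.0, 10.0))
        )
        with pytest.raises(ValueError):
            ts.fit_cd_melt(mc)


class TestTitrationFit:
    def concs(self):
        return np.concatenate([[0.0], np.logspace(-8, -2.1, 11)])

    def test_noiseless_recovery(self, linkage_params):
        series, _ = ts.simulate_titration_series(linkage_params, self.concs())
        res = ts.fit_titration(series, linkage_params.dh0)
        assert res.params.tm0 == pytest.approx(linkage_params.tm0, rel=1e-3)
        assert res.params.kd == pytest.approx(linkage_params.kd, rel=1e-3)

    def test_degenerate_flat_series_flags_kd(self, linkage_params):
        series = ts.TitrationSeries(self.concs(), np.full(12, 335.65))
        res = ts.fit_titration(series, linkage_params.dh0)
        assert res.std_errors["kd"] > res.params.kd  # unidentifiable

    def test_missing_zero_anchor_warns(self, linkage_params):
        series, _ = ts.simulate_titration_series(
            linkage_params, np.logspace(-8, -3, 6)
        )
        with pytest.warns(UserWarning, match="zero-concentration"):
            ts.fit_titration(series, linkage_params.dh0)

    def test_noisy_kd_within_factor_two(self, linkage_params):
        kds = []
        for seed in range(20):
            series, _ = ts.simulate_titration_series(
                linkage_params, self.concs(), noise_sd_tm=0.2, seed=seed
            )
            kds.append(ts.fit_titration(series, linkage_params.dh0).params.kd)
        geo_mean = np.exp(np.mean(np.log(kds)))
        assert linkage_params.kd / 2 < geo_mean < linkage_params.kd * 2
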
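"""Tide-pool calcification: Eq.-style TA anomaly, light response, daily NEC."""

import numpy as np
import pandas as pd
import pytest

from reefkit.nec import (
    LightResponseFit,
    TidePoolSeries,
    compare_station_slopes,
    fit_light_response,
    integrate_daily_nec,
    seawater_density,
    series_windows,
    window_nec,
)


class TestSeawaterDensity:
    def test_reference_value(self):
        assert seawater_density(25.0, 35.0) == pytest.approx(1023.3, abs=0.5)

    def test_fresh_water_reference(self):
        # EOS-80 pure-water check value at 5 degC
        assert seawater_density(5.0, 0.0) == pytest.approx(999.96675, abs=0.01)

    def test_monotone_in_salinity(self):
        assert seawater_density(25.0, 36.0) > seawater_density(25.0, 34.0)

    def test_constant_override(self):
        assert seawater_density(25.0, 35.0, constant=1023.0) == 1023.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            seawater_density(45.0, 35.0)


def make_series(
    slope=-0.2, n=5, dt_h=0.33, depth=0.5, stagnant=None, ta0=2.2,
    temp=25.0, sal=35.0,
):
    t = np.arange(n) * dt_h
    samples = pd.DataFrame(
        {
            "time_h": t,
            "ta_mmol_kg": ta0 + slope * t,
            "depth_m": depth,
            "temp_c": temp,
            "salinity": sal,
            "photon_flux": 800.0,
            "stagnant": stagnant if stagnant is not None else [True] * n,
        }
    )
    return TidePoolSeries(station_id="st1", date="2019-07-02", samples=samples)


class TestWindowNec:
    def test_forced_arithmetic(self):
        # TA slope -0.2 mmol/kg/h, Zbar 0.5 m, rho 1023 -> NEC = 51.15
        series = make_series(slope=-0.2)
        est = window_nec(series, 0, 3, density_constant=1023.0)
        assert est.nec == pytest.approx(51.15, abs=1e-9)
        assert est.ta_slope == pytest.approx(-0.2)

    def test_unit_chain(self):
        # (mmol kg^-1 h^-1) * m * (kg m^-3) -> mmol m^-2 h^-1, doubled depth
        # and doubled slope each double the flux
        base = window_nec(make_series(slope=-0.2), 0, 3, density_constant=1000.0)
        deep = window_nec(make_series(slope=-0.2, depth=1.0), 0, 3, density_constant=1000.0)
        fast = window_nec(make_series(slope=-0.4), 0, 3, density_constant=1000.0)
        assert deep.nec == pytest.approx(2 * base.nec)
        assert fast.nec == pytest.approx(2 * base.nec)

    def test_zero_slope_zero_nec(self):
        est = window_nec(make_series(slope=0.0), 0, 3)
        assert est.nec == pytest.approx(0.0, abs=1e-12)

    def test_rising_ta_gives_negative_nec(self):
        # dissolution: TA increases, NEC must be negative
        est = window_nec(make_series(slope=+0.1), 0, 3)
        assert est.nec < 0

    def test_window_outside_stagnant_rejected(self):
        series = make_series(stagnant=[True, True, False, True, True])
        with pytest.raises(ValueError, match="stagnant|advection"):
            window_nec(series, 0, 4)

    def test_short_window_rejected(self):
        series = make_series(dt_h=0.1)
        with pytest.raises(ValueError, match="30 min"):
            window_nec(series, 0, 3)

    def test_noisy_recovery_within_2se(self, rng):
        true_slope = -0.15
        series = make_series(slope=true_slope, n=12, dt_h=0.2)
        noisy = series.samples.copy()
        noisy["ta_mmol_kg"] += rng.normal(0, 0.004, len(noisy))
        series = TidePoolSeries("st1", "d", noisy)
        est = window_nec(series, 0, 12, density_constant=1023.0)
        truth = -0.5 * true_slope * 0.5 * 1023.0
        assert abs(est.nec - truth) < 2 * est.se


class TestLightResponse:
    def test_linear_recovery(self, rng):
        light = rng.uniform(0, 1500, 30)
        nec = 0.004 * light - 1.0 + rng.normal(0, 0.3, 30)
        fit = fit_light_response(nec, light, force_form="linear")
        se_b = np.sqrt(fit.covariance[0, 0])
        assert abs(fit.params["b"] - 0.004) < 2 * se_b + 1e-4

    def test_tanh_recovery_and_selection(self, rng):
        successes = 0
        for i in range(5):
            light = np.concatenate([[0.0] * 4, rng.uniform(50, 2000, 26)])
            truth = 6.0 * np.tanh(light / 500.0) - 1.0
            nec = truth + rng.normal(0, 0.3, light.size)
            fit = fit_light_response(nec, light)
            if fit.form != "tanh":
                continue
            ok = (
                abs(fit.params["a"] - 6.0) < 2 * np.sqrt(fit.covariance[0, 0]) + 0.3
                and abs(fit.params["i_k"] - 500.0) < 2 * np.sqrt(fit.covariance[1, 1]) + 50
            )
            successes += ok
        assert successes >= 4

    def test_linear_truth_prefers_linear(self, rng):
        light = rng.uniform(0, 1000, 40)
        nec = 0.002 * light + rng.normal(0, 0.2, 40)
        fit = fit_light_response(nec, light)
        assert fit.form == "linear"

    def test_constant_light_rejected(self):
        with pytest.raises(ValueError, match="light"):
            fit_light_response(np.arange(5.0), np.full(5, 300.0))

    def test_covariance_symmetric_psd(self, rng):
        light = rng.uniform(0, 1500, 25)
        nec = 5 * np.tanh(light / 400) + rng.normal(0, 0.2, 25)
        fit = fit_light_response(nec, light)
        cov = fit.covariance
        assert cov == pytest.approx(cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10


def flat_light_day(flux):
    t = np.linspace(0.0, 24.0, 97)
    return pd.DataFrame({"time_h": t, "photon_flux": np.full_like(t, flux)})


class TestDailyIntegration:
    def test_linear_constant_light_closed_form(self):
        fit = LightResponseFit(
            form="linear", params={"b": 0.01, "c": -0.5},
            covariance=np.zeros((2, 2)), aicc=0.0, n_points=10,
        )
        daily = integrate_daily_nec(fit, flat_light_day(400.0))
        assert daily.value == pytest.approx(24 * (0.01 * 400 - 0.5), rel=1e-12)
        assert daily.sd == 0.0

    def test_zero_function_integrates_to_zero(self):
        fit = LightResponseFit(
            form="linear", params={"b": 0.0, "c": 0.0},
            covariance=np.zeros((2, 2)), aicc=0.0, n_points=10,
        )
        daily = integrate_daily_nec(fit, flat_light_day(800.0))
        assert daily.value == 0.0 and daily.sd == 0.0

    def test_delta_method_matches_monte_carlo(self, rng):
        cov = np.array([[4e-6, -1e-6], [-1e-6, 0.04]])
        fit = LightResponseFit(
            form="linear", params={"b": 0.008, "c": -1.0},
            covariance=cov, aicc=0.0, n_points=20,
        )
        t = np.linspace(0, 24, 97)
        light = 1500 * np.sin(np.pi * np.clip((t - 6) / 12, 0, 1)) ** 2
        day = pd.DataFrame({"time_h": t, "photon_flux": light})
        daily = integrate_daily_nec(fit, day)
        params = rng.multivariate_normal([0.008, -1.0], cov, size=10_000)
        values = [
            np.trapezoid(b * light + c, t) for b, c in params
        ]
        mc_sd = np.std(values, ddof=1)
        assert daily.sd == pytest.approx(mc_sd, rel=0.10)

    def test_gap_rejected(self):
        day = pd.DataFrame({"time_h": [0.0, 12.0, 24.0], "photon_flux": [0.0, 100.0, 0.0]})
        fit = LightResponseFit(
            form="linear", params={"b": 0.0, "c": 0.0},
            covariance=np.zeros((2, 2)), aicc=0.0, n_points=5,
        )
        with pytest.raises(ValueError, match="gap"):
            integrate_daily_nec(fit, day)

    def test_incomplete_day_rejected(self):
        day = pd.DataFrame({"time_h": np.linspace(6, 18, 20), "photon_flux": 0.0})
        fit = LightResponseFit(
            form="linear", params={"b": 0.0, "c": 0.0},
            covariance=np.zeros((2, 2)), aicc=0.0, n_points=5,
        )
        with pytest.raises(ValueError, match="24"):
            integrate_daily_nec(fit, day)


class TestStationComparison:
    def _station(self, rng, slope, n=12, noise=0.003):
        series = make_series(slope=slope, n=n, dt_h=0.2)
        samples = series.samples.copy()
        samples["ta_mmol_kg"] += rng.normal(0, noise, n)
        return TidePoolSeries(series.station_id, series.date, samples)

    def test_different_drawdown_detected(self, rng):
        stations = {
            "a": self._station(rng, -0.1),
            "b": self._station(rng, -0.2),
        }
        out = compare_station_slopes(stations)
        assert out["interaction"]["p"] < 0.01
        assert (out["pairwise"]["p_tukey"] < 0.01).all()

    def test_null_calibration(self, rng):
        rejections = 0
        reps = 100
        for _ in range(reps):
            stations = {
                "a": self._station(rng, -0.15),
                "b": self._station(rng, -0.15),
                "c": self._station(rng, -0.15),
            }
            out = compare_station_slopes(stations)
            rejections += out["interaction"]["p"] <= 0.05
        rate = rejections / reps
        sigma = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3.5 * sigma + 1e-9

    def test_slope_table_reproduces_window_nec(self, rng):
        station = self._station(rng, -0.12)
        out = compare_station_slopes({"a": station, "b": self._station(rng, -0.3)})
        est = window_nec(station, 0, len(station.stagnant_samples))
        assert out["slopes"].loc["a", "ta_slope"] == pytest.approx(est.ta_slope)

    def test_insufficient_station_skipped(self, rng):
        tiny = make_series(n=2, dt_h=0.4)
        stations = {"a": self._station(rng, -0.1), "b": self._station(rng, -0.2), "c": tiny}
        out = compare_station_slopes(stations)
        assert "c" not in out["slopes"].index


def test_series_windows_enforces_span_rule(rng):
    series = make_series(slope=-0.2, n=8, dt_h=0.2)
    # 3-sample windows span only 24 min (< 30 min rule): all skipped
    assert series_windows(series, size=3) == []
    # 4-sample windows span 36 min: every rolling window kept
    wins = series_windows(series, size=4)
    assert len(wins) == 5
    assert all(w.n_samples == 4 for w in wins)


def test_ta_units_warning(caplog):
    samples = pd.DataFrame(
        {
            "time_h": [0.0, 0.5, 1.0],
            "ta_mmol_kg": [2200.0, 2190.0, 2180.0],   # umol values by mistake
            "depth_m": 0.5, "temp_c": 25.0, "salinity": 35.0,
            "photon_flux": 0.0, "stagnant": True,
        }
    )
    with caplog.at_level("WARNING"):
        TidePoolSeries("st", "d", samples)
    assert any("units" in r.message for r in caplog.records)
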
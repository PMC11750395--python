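import datetime as dt

import numpy as np
import pandas as pd
import pytest

from germflow import environment
from germflow.types import Env41Params, ObservationSeries, TreatmentEnv

REFERENCE_SET = Env41Params(a=1.42, T0=12.6, b=0.23, beta=1.2, theta0=1.0,
                        thetar=0.05)


def _const_env(T=16.0, theta=0.65, days=30, freq="h"):
    idx = pd.date_range("2018-10-05", periods=days * 24, freq=freq)
    return TreatmentEnv(sowing_date=dt.date(2018, 10, 5),
                        temps=pd.Series(np.full(len(idx), T), index=idx),
                        swc=pd.Series(np.full(len(idx), theta), index=idx))


class TestGerminationSpeed:
    def test_zero_at_base_temperature(self):
        assert environment.germination_speed(12.6, 0.65, REFERENCE_SET) == 0.0

    @pytest.mark.parametrize("theta", [0.05, 1.0, 0.01, 1.1])
    def test_zero_outside_moisture_band(self, theta):
        assert environment.germination_speed(18.0, theta, REFERENCE_SET) == 0.0

    def test_hand_evaluated_value(self):
        # 0.9612 * 0.5964 * 0.60 * 0.2837 ~= 0.0976 per day
        u = environment.germination_speed(18.0, 0.65, REFERENCE_SET)
        assert u == pytest.approx(0.0976, abs=2e-4)

    def test_optimum_temperature_matches_closed_form(self):
        T = np.linspace(12.6, 18.8, 2001)
        u = environment.germination_speed(T, 0.65, REFERENCE_SET)
        T_star = REFERENCE_SET.T0 + REFERENCE_SET.a / (2 * REFERENCE_SET.b)
        assert T[np.argmax(u)] == pytest.approx(T_star, abs=0.01)

    def test_nonnegative_everywhere(self):
        T = np.linspace(-10, 40, 51)
        th = np.linspace(0, 1.2, 25)
        TT, HH = np.meshgrid(T, th)
        assert np.all(environment.germination_speed(TT, HH, REFERENCE_SET) >= 0)


class TestDispersionRelation:
    def test_power_form_linear_special_case(self):
        rel = environment.DispersionRelation("power", (0.05, 1.0))
        assert rel.predict(0.1) == pytest.approx(0.005)

    def test_monotone_in_speed(self):
        rel = environment.DispersionRelation("power", (0.05, 1.3))
        assert rel.predict(0.2) > rel.predict(0.1)

    def test_fit_round_trip(self):
        u = np.geomspace(0.03, 0.3, 12)
        D = 0.05 * u ** 1.3
        rel = environment.fit_dispersion_relation(u, D, "power")
        assert rel.coeffs[0] == pytest.approx(0.05, abs=1e-6)
        assert rel.coeffs[1] == pytest.approx(1.3, abs=1e-6)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            environment.DispersionRelation().predict(-0.1)


class TestTimeAverage:
    def test_constant_series(self):
        T, th = environment.time_average_drivers(_const_env(16.0, 0.65), 14.0)
        assert (T, th) == (pytest.approx(16.0), pytest.approx(0.65))

    def test_diurnal_oscillation_averages_out(self):
        idx = pd.date_range("2018-10-05", periods=14 * 24, freq="h")
        hours = np.arange(len(idx))
        temps = 16 + 5 * np.sin(2 * np.pi * hours / 24)
        env = TreatmentEnv(sowing_date=dt.date(2018, 10, 5),
                           temps=pd.Series(temps, index=idx),
                           swc=pd.Series(np.full(len(idx), 0.6), index=idx))
        T, _ = environment.time_average_drivers(env, 14.0)
        assert T == pytest.approx(16.0, abs=1e-6)

    def test_linear_ramp_mean(self):
        idx = pd.date_range("2018-10-05", periods=14, freq="D")
        temps = np.linspace(12, 20, 14)
        env = TreatmentEnv(sowing_date=dt.date(2018, 10, 5),
                           temps=pd.Series(temps, index=idx),
                           swc=pd.Series(np.full(14, 0.6), index=idx))
        T, _ = environment.time_average_drivers(env, 14.0)
        assert T == pytest.approx(16.0)

    def test_emergence90_window_rule(self):
        obs = ObservationSeries(days=np.arange(1.0, 11.0),
                                emerged_pct=np.array([0, 5, 20, 50, 70, 85,
                                                      90, 93, 94, 95.0]))
        # 90% of final (95) = 85.5 -> first day reaching it is day 7
        env = _const_env()
        T, th = environment.time_average_drivers(env, "emergence90", obs=obs)
        assert T == pytest.approx(16.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            environment.time_average_drivers(_const_env(), 0.0)


class TestFitEnv41:
    @staticmethod
    def _design():
        T = np.repeat([14.0, 15.0, 16.0, 17.0, 18.0], 3)
        th = np.tile([0.55, 0.65, 0.75], 5)
        return T, th

    def test_noise_free_round_trip_recovers_reference_set(self):
        T, th = self._design()
        u = environment.germination_speed(T, th, REFERENCE_SET)
        p, rss = environment.fit_env41(list(zip(T, th, u)))
        assert rss < 1e-10
        assert p.a == pytest.approx(1.42, abs=1e-6)
        assert p.T0 == pytest.approx(12.6, abs=1e-6)
        assert p.b == pytest.approx(0.23, abs=1e-6)
        assert p.beta == pytest.approx(1.2, abs=1e-6)

    def test_noisy_recovery_of_a(self, rng):
        # small measurement noise on the speeds barely moves the coefficient
        T, th = self._design()
        u = environment.germination_speed(T, th, REFERENCE_SET)
        devs = []
        for _ in range(100):
            pts = list(zip(T, th, u + rng.normal(0, 1e-4, size=len(u))))
            p, _ = environment.fit_env41(pts)
            devs.append(abs(p.a - 1.42))
        assert np.median(devs) < 0.02

    def test_single_moisture_level_rejected(self):
        T = np.linspace(14, 18, 8)
        th = np.full(8, 0.65)
        u = environment.germination_speed(T, th, REFERENCE_SET)
        with pytest.raises(ValueError, match="rank-deficient"):
            environment.fit_env41(list(zip(T, th, u)))


class TestSoilPhysics:
    def test_chamber_porosity_worked_example(self):
        assert environment.porosity(1.1, 2.67) == pytest.approx(0.588, abs=5e-4)

    def test_field_porosity(self):
        # 1 - 1.45/2.67 = 0.4569 (the printed 45.6% is a rounding quirk)
        assert environment.porosity(1.45, 2.67) == pytest.approx(0.4569, abs=5e-5)

    def test_equal_densities_rejected(self):
        with pytest.raises(ValueError):
            environment.porosity(2.67, 2.67)

    def test_diffusivity_fold(self):
        fold = environment.gas_diffusivity_ratio(0.588, 0.456)
        assert fold == pytest.approx(2.33, abs=0.01)
        assert environment.gas_diffusivity_ratio(0.5, 0.5) == 1.0
        assert environment.gas_diffusivity_ratio(0.6, 0.3, exponent=1.0) == \
            pytest.approx(2.0)
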
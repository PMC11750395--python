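import numpy as np
import pytest

from germflow import calibrate, synthetic
from germflow.solver import SolverSettings, simulate
from germflow.types import ObservationSeries, PhysioDomain, SeedLot, StageParams


class TestRSquared:
    def test_perfect_fit(self):
        obs = [0.0, 40.0, 80.0, 100.0]
        assert calibrate.r_squared(obs, obs) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([0.0, 40.0, 80.0, 100.0])
        assert calibrate.r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        obs = [0.0, 40.0, 80.0, 100.0]
        sim = [0.0, 50.0, 70.0, 100.0]
        # SS_res = 200, SS_tot = 5900
        assert calibrate.r_squared(obs, sim) == pytest.approx(1 - 200 / 5900)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            calibrate.r_squared([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestNormalizeViable:
    def test_direct_ratios(self):
        out = calibrate.normalize_viable([60, 54, 48])
        assert np.allclose(out, [1.0, 0.9, 0.8])

    def test_single_treatment(self):
        assert calibrate.normalize_viable([37])[0] == 1.0

    def test_ties_at_max(self):
        out = calibrate.normalize_viable([50, 50, 25])
        assert out[0] == out[1] == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            calibrate.normalize_viable([0, 0])


class TestEstimateGamma:
    def test_simple_ratio(self):
        assert calibrate.estimate_gamma(300, 60) == 5.0
        assert calibrate.estimate_gamma(0, 60) == 0.0

    def test_zero_emergence_rejected(self):
        with pytest.raises(ValueError):
            calibrate.estimate_gamma(300, 0)

    def test_binomial_noise_recovery(self, rng):
        # counts around a gamma=4 study; estimate within +-0.2 typically
        errs = []
        for _ in range(50):
            emerged = rng.binomial(100, 0.95)
            tillers = rng.poisson(4.0 * emerged)
            errs.append(calibrate.estimate_gamma(tillers, emerged) - 4.0)
        assert abs(np.median(errs)) < 0.2


class TestCalibrateStage:
    def test_noise_free_round_trip_with_truth_on_grid(self):
        days = np.arange(1.0, 25.0)
        fac = calibrate.analytic_sim_factory(days)
        obs = fac(0.10, 0.005)
        res = calibrate.calibrate_stage(
            days, grid_u=[0.05, 0.10, 0.2], grid_D=[0.001, 0.005, 0.02],
            sim_factory=fac, obs_values=obs)
        assert res.u_hat == pytest.approx(0.10, abs=1e-9)
        assert res.D_hat == pytest.approx(0.005, abs=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_refinement_resolves_off_grid_truth(self):
        days = np.arange(1.0, 25.0)
        fac = calibrate.analytic_sim_factory(days)
        obs = fac(0.117, 0.0063)
        res = calibrate.calibrate_stage(days, sim_factory=fac, obs_values=obs)
        assert res.u_hat == pytest.approx(0.117, abs=2e-4)
        assert res.D_hat == pytest.approx(0.0063, abs=2e-4)
        assert res.refined

    def test_single_point_grid(self):
        days = np.arange(1.0, 10.0)
        fac = calibrate.analytic_sim_factory(days)
        obs = fac(0.2, 0.01)
        res = calibrate.calibrate_stage(days, grid_u=[0.15], grid_D=[0.01],
                                        sim_factory=fac, refine=False,
                                        obs_values=obs)
        assert (res.u_hat, res.D_hat) == (0.15, 0.01)

    def test_argmax_property_by_reevaluation(self):
        days = np.arange(1.0, 21.0)
        fac = calibrate.analytic_sim_factory(days)
        obs = fac(0.09, 0.004) + np.sin(days)        # deliberately imperfect
        obs = np.clip(obs, 0, 100)
        gu, gD = [0.05, 0.08, 0.1, 0.15], [0.002, 0.005, 0.01]
        res = calibrate.calibrate_stage(days, grid_u=gu, grid_D=gD,
                                        sim_factory=fac, refine=False,
                                        obs_values=obs)
        scores = [calibrate.r_squared(obs, fac(u, D)) for u in gu for D in gD]
        assert res.r2 == pytest.approx(max(scores))

    def test_deterministic_tie_breaks_to_smaller_parameters(self):
        days = np.arange(1.0, 10.0)
        obs = np.linspace(0, 90, 9)

        def flat_factory(u, D):     # every pair scores identically
            return obs

        res = calibrate.calibrate_stage(days, grid_u=[0.1, 0.2],
                                        grid_D=[0.01, 0.02],
                                        sim_factory=flat_factory, refine=False,
                                        obs_values=obs)
        assert (res.u_hat, res.D_hat) == (0.1, 0.01)

    def test_failing_grid_points_are_skipped(self):
        days = np.arange(1.0, 10.0)
        fac = calibrate.analytic_sim_factory(days)
        obs = fac(0.1, 0.005)

        def flaky(u, D):
            if u > 0.15:
                raise RuntimeError("boom")
            return fac(u, D)

        with pytest.warns(UserWarning, match="boom"):
            res = calibrate.calibrate_stage(days, grid_u=[0.1, 0.2],
                                            grid_D=[0.005], sim_factory=flaky,
                                            refine=False, obs_values=obs)
        assert res.u_hat == 0.1

    def test_binomial_noise_recovery_of_speed(self, rng):
        # daily counts of 100 seeds: median |u_hat - u| well inside 0.005
        devs = []
        days = np.arange(1.0, 21.0)
        for _ in range(20):
            obs = synthetic.generate_observations(
                days, 0.10, 0.005, 100, seed=int(rng.integers(2 ** 31)))
            res = calibrate.calibrate_stage(obs)
            devs.append(abs(res.u_hat - 0.10))
        assert np.median(devs) < 0.005

    def test_fit_quality_under_binomial_noise(self, rng):
        # the synthetic analogue of reported field fit quality: R^2 >= 0.95
        # in at least 90% of replicates at n=100 seeds, daily counts
        days = np.arange(1.0, 21.0)
        r2s = []
        for _ in range(20):
            obs = synthetic.generate_observations(
                days, 0.10, 0.005, 100, seed=int(rng.integers(2 ** 31)))
            r2s.append(calibrate.calibrate_stage(obs).r2)
        assert np.mean(np.asarray(r2s) >= 0.95) >= 0.9


class TestTillerFactory:
    def test_convolution_matches_coupled_finite_volume(self):
        u_G, D_G, u_T, D_T, gamma = 0.1, 0.005, 0.04, 0.002, 5.0
        dom = PhysioDomain(dx=0.005)
        tr = simulate(StageParams(u_G, D_G), StageParams(u_T, D_T),
                      SeedLot(1.0, gamma), dom,
                      SolverSettings(dx=0.005, t_end=120, record_every=1))
        fac = calibrate.tiller_sim_factory(tr.t[1:], u_G, D_G, gamma, scale=1.0)
        conv = fac(u_T, D_T)
        assert np.max(np.abs(conv - tr.tillers_done[1:])) / gamma < 0.01

    def test_tillering_round_trip(self):
        days = np.arange(7.0, 121.0, 7.0)
        fac = calibrate.tiller_sim_factory(days, 0.1, 0.005, 4.0, scale=100.0)
        obs = fac(0.04, 0.002)
        res = calibrate.calibrate_stage(
            days, grid_u=np.geomspace(0.01, 0.2, 12),
            grid_D=np.geomspace(5e-4, 2e-2, 12), sim_factory=fac,
            obs_values=obs)
        assert res.u_hat == pytest.approx(0.04, abs=2e-4)
        assert res.D_hat == pytest.approx(0.002, abs=2e-4)
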
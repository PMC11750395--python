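import numpy as np
import pytest

from germflow import analytic
from germflow.solver import SolverSettings, choose_steps, simulate, step
from germflow.types import (InvariantError, PhysioDomain, SeedLot,
                            StageParams, StateProfile)


class TestChooseSteps:
    @pytest.mark.parametrize("u,D", [(0.1, 0.001), (0.1, 0.005),
                                     (0.3, 0.01), (0.02, 1e-4)])
    def test_postconditions(self, u, D):
        dx, dt = choose_steps(u, D)
        assert dx > u * dt
        assert u * dx / D < 2.0
        assert D * dt / dx ** 2 <= 0.4 + 1e-12
        assert round(1.0 / dx) == pytest.approx(1.0 / dx)

    def test_pure_dispersion_defaults(self):
        dx, dt = choose_steps(0.0, 0.005)
        assert dx == pytest.approx(0.01)       # L0/100
        assert dt == pytest.approx(0.4 * dx ** 2 / 0.005)

    def test_infeasible_constraint_set_raises(self):
        with pytest.raises(ValueError, match="Peclet"):
            choose_steps(10.0, 1e-9)

    def test_peclet_constraint_drives_dx(self):
        dx, _ = choose_steps(0.1, 0.001)
        assert dx < 0.02                        # 2 D / u


class TestStep:
    def test_zero_flux_limit_leaves_state_unchanged(self, domain, seedlot):
        n = np.zeros(domain.n_germ)
        n[0] = 1.0 / domain.dx
        state = StateProfile(t=0.0, n=n, N=np.zeros(0))
        germ = StageParams(u=0.0, D=1e-16)
        out = step(state, germ, None, seedlot, domain, dt=1e-3)
        assert np.allclose(out.n, state.n, atol=1e-12 * n[0])
        assert out.emerged == 0.0

    def test_single_step_conserves_mass_exactly(self, domain, seedlot):
        n = np.zeros(domain.n_germ)
        n[0] = 1.0 / domain.dx
        state = StateProfile(t=0.0, n=n, N=np.zeros(0))
        out = step(state, StageParams(0.1, 0.005), None, seedlot, domain,
                   dt=1e-3)
        assert np.sum(out.n) * domain.dx + out.emerged == pytest.approx(1.0, abs=1e-14)
        # mass leaves cell 1 only via its east face
        assert out.n[0] < n[0]
        assert out.n[1] > 0
        assert np.all(out.n[2:] == 0)

    def test_stability_violation_is_hard_error(self, domain, seedlot):
        n = np.zeros(domain.n_germ)
        n[0] = 1.0 / domain.dx
        state = StateProfile(t=0.0, n=n, N=np.zeros(0))
        with pytest.raises(InvariantError, match="CFL|diffusion"):
            step(state, StageParams(0.1, 0.005), None, seedlot, domain, dt=1.0)


class TestSimulate:
    def test_germination_mass_conservation_at_every_time(self, domain, seedlot,
                                                         germ_params):
        tr = simulate(germ_params, None, seedlot, domain,
                      SolverSettings(dx=domain.dx, t_end=40, record_every=1))
        tr.final_state.check_conservation(domain, seedlot)
        # emerged + leftover mass is N0 at the end, and emerged is monotone
        assert np.all(np.diff(tr.emerged) >= 0)
        assert tr.emerged[-1] <= seedlot.N0 * (1 + 1e-12)

    def test_emergence_matches_analytic_curve(self, domain, seedlot, germ_params):
        tr = simulate(germ_params, None, seedlot, domain,
                      SolverSettings(dx=domain.dx, t_end=40, record_every=1))
        ana = analytic.emerged_fraction(tr.t[1:], 0.1, 0.005,
                                        with_correction=True)
        assert np.max(np.abs(ana - tr.emerged[1:])) < 0.01
        assert tr.emerged[-1] > 0.999

    def test_junction_conservation_with_gamma_multiplier(self, domain):
        lot = SeedLot(N0=1.0, gamma=3.0)
        tr = simulate(StageParams(0.1, 0.005), StageParams(0.05, 0.002), lot,
                      domain, SolverSettings(dx=domain.dx, t_end=60,
                                             record_every=1))
        # in-stage + completed tillers = gamma * emerged, at all times
        lhs = tr.tillers_in_stage + tr.tillers_done
        assert np.max(np.abs(lhs - lot.gamma * tr.emerged)) <= 1e-8 * lot.gamma

    def test_long_run_tillers_approach_gamma_times_seeds(self):
        dom = PhysioDomain(dx=0.01)
        lot = SeedLot(N0=1.0, gamma=5.0)
        tr = simulate(StageParams(0.1, 0.005), StageParams(0.05, 0.002), lot,
                      dom, SolverSettings(dx=0.01, t_end=150, record_every=5))
        assert tr.tillers_done[-1] / tr.emerged[-1] == pytest.approx(5.0, abs=1e-3)
        # tillering lags germination
        i = np.searchsorted(tr.t, 20.0)
        assert tr.tillers_done[i] / (lot.gamma * lot.N0) < tr.emerged[i] / lot.N0

    def test_grid_convergence(self, seedlot, germ_params):
        curves = {}
        for dx in (0.01, 0.005):
            dom = PhysioDomain(dx=dx)
            tr = simulate(germ_params, None, seedlot, dom,
                          SolverSettings(dx=dx, t_end=30, record_every=1))
            curves[dx] = tr.emerged
        assert np.max(np.abs(curves[0.01] - curves[0.005])) < 0.005 * seedlot.N0

    def test_constant_driver_series_equals_constant_run(self, domain, seedlot):
        settings = SolverSettings(dx=domain.dx, t_end=20, record_every=1)
        base = simulate(StageParams(0.1, 0.005), None, seedlot, domain, settings)
        driven = simulate(StageParams(0.1, 0.005), None, seedlot, domain,
                          settings,
                          drivers=(np.arange(0.0, 21.0),
                                   np.full(21, 0.1), np.full(21, 0.005)))
        assert np.array_equal(base.emerged, driven.emerged)

    def test_varying_speed_slows_emergence(self, domain, seedlot):
        settings = SolverSettings(dx=domain.dx, t_end=30, record_every=1)
        fast = simulate(StageParams(0.1, 0.005), None, seedlot, domain, settings)
        # speed halves after day 5: emergence must fall behind
        slowed = simulate(StageParams(0.1, 0.005), None, seedlot, domain,
                          settings,
                          drivers=(np.array([0.0, 5.0, 30.0]),
                                   np.array([0.1, 0.05, 0.05]),
                                   np.array([0.005, 0.005, 0.005])))
        assert slowed.emerged[-1] < fast.emerged[-1]
        assert np.all(slowed.emerged <= fast.emerged + 1e-12)

    def test_driver_series_shorter_than_horizon_raises(self, domain, seedlot):
        with pytest.raises(InvariantError, match="horizon"):
            simulate(StageParams(0.1, 0.005), None, seedlot, domain,
                     SolverSettings(dx=domain.dx, t_end=30, record_every=1),
                     drivers=(np.arange(0.0, 10.0), np.full(10, 0.1),
                              np.full(10, 0.005)))
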
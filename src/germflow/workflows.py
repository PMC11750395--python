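"""End-to-end analysis pipelines used by the examples, tests and the
reproduction script.

These are thin orchestrations of the public API: generate synthetic inputs
at the study's conditions, run the calibration machinery, and return the
headline quantities.
"""

from __future__ import annotations

import numpy as np

from . import calibrate, environment, synthetic
from .solver import SolverSettings, simulate
from .types import Env41Params, PhysioDomain, SeedLot, StageParams

__all__ = ["env_response_roundtrip", "noisy_calibration_study",
           "porosity_contrast"]

_DEFAULT_REL = environment.DispersionRelation("power", (0.05, 1.0))


def env_response_roundtrip(temps=(14.0, 15.0, 16.0, 17.0, 18.0),
                           thetas=(0.55, 0.65, 0.75),
                           env41: Env41Params | None = None,
                           dispersion_rel=_DEFAULT_REL,
                           dx: float = 0.005, t_end: float = 35.0,
                           refine: bool = True) -> dict:
    """Noise-free end-to-end identifiability check of the environmental
    response.

    For each temperature x moisture combination: compute the generating
    germination speed from the environmental response, its dispersion from
    the speed-dispersion power law, integrate the emergence curve with the
    finite-volume solver, calibrate ``(u_G, D_G)`` back from the daily curve
    by grid search with refinement, and finally fit the environmental
    response to the recovered speeds.  Returns the recovered coefficients
    and the per-combination recovery table.
    """
    truth = env41 or Env41Params()
    dom = PhysioDomain(dx=dx)
    days = np.arange(1.0, t_end + 1e-9)
    points, table = [], []
    for T in temps:
        for th in thetas:
            u = environment.germination_speed(T, th, truth)
            if u <= 0:
                raise ValueError(f"(T={T}, theta={th}) gives zero germination speed")
            D = dispersion_rel.predict(u)
            tr = simulate(StageParams(u, D), None, SeedLot(1.0, 1.0), dom,
                          SolverSettings(dx=dx, t_end=t_end, record_every=1.0))
            obs = 100.0 * tr.emerged[1:]
            res = calibrate.calibrate_stage(
                days, sim_factory=calibrate.analytic_sim_factory(days),
                refine=refine, obs_values=obs)
            points.append((T, th, res.u_hat))
            table.append({"T": T, "theta": th, "u_true": u,
                          "u_hat": res.u_hat, "D_hat": res.D_hat, "r2": res.r2})
    fitted, rss = environment.fit_env41(points, init=None)
    return {"a": fitted.a, "T0": fitted.T0, "b": fitted.b, "beta": fitted.beta,
            "rss": rss, "n": len(points), "table": table, "truth": truth}


def noisy_calibration_study(n_replicates: int = 20, u_G: float = 0.10,
                            D_G: float = 0.005, n_seeds: int = 100,
                            seed: int = 0) -> dict:
    """Fit quality under binomial observation noise.

    Generates ``n_replicates`` seeded emergence series (daily counts of
    ``n_seeds`` seeds until 99% emergence) from the stated truth, calibrates
    each with the default grids plus refinement, and reports the R^2 of each
    best fit against its own observations.
    """
    from . import analytic
    t99 = analytic.germination_time_quantile(0.99, u_G, D_G,
                                             with_correction=True)
    days = np.arange(1.0, np.ceil(t99) + 1.0)
    rng = np.random.default_rng(seed)
    r2s, u_hats = [], []
    for _ in range(n_replicates):
        obs = synthetic.generate_observations(
            days, u_G, D_G, n_seeds, seed=int(rng.integers(2 ** 31)))
        res = calibrate.calibrate_stage(obs)
        r2s.append(res.r2)
        u_hats.append(res.u_hat)
    return {"median_r2": float(np.median(r2s)), "r2": r2s, "u_hat": u_hats,
            "n": n_replicates, "days": days}


def porosity_contrast(bulk_chamber: float = 1.1, bulk_field: float = 1.45,
                      particle_density: float = 2.67,
                      exponent: float = 10.0 / 3.0) -> dict:
    """Porosity of the chamber soil layer vs the field soil and the implied
    relative O2 diffusivity (power law in porosity)."""
    phi_c = environment.porosity(bulk_chamber, particle_density)
    phi_f = environment.porosity(bulk_field, particle_density)
    fold = environment.gas_diffusivity_ratio(phi_c, phi_f, exponent)
    return {"porosity_chamber_pct": 100.0 * phi_c,
            "porosity_field_pct": 100.0 * phi_f,
            "o2_diffusivity_fold": fold}
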
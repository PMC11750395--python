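"""Synthetic field-trial generator.

Everything the toolkit needs to exercise itself without field data: weather
and soil-moisture driver series, binomially noised observation series, full
sowing-date x soil-moisture factorial studies, and the random-walk
micro-simulator whose continuum limit is the advection-dispersion model.

The default study design emulates a winter-wheat drilling trial: three
October sowing dates (a temperature gradient), three soil-moisture regimes
held at 75 / 65 / 55% of field capacity by top-up irrigation, three
replicate plots per treatment, daily emergence counts on a fixed row
section, and weekly tiller counts.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analytic, environment
from .calibrate import tiller_sim_factory
from .types import Env41Params, ObservationSeries, TreatmentEnv

__all__ = [
    "StudyDesign", "Treatment", "StudyBundle",
    "generate_env", "generate_observations", "generate_study",
    "random_walk_germination",
]


@dataclass
class StudyDesign:
    """Factorial layout of a synthetic sowing trial."""

    sowing_dates: list = field(default_factory=lambda: [
        _dt.date(2018, 10, 5), _dt.date(2018, 10, 10), _dt.date(2018, 10, 15)])
    moisture_levels: list = field(default_factory=lambda: [0.75, 0.65, 0.55])
    n_seeds_per_plot: int = 100       # seeds in the observed 1 m row section
    replicate_count: int = 3
    germ_cadence_days: float = 1.0
    tiller_cadence_days: float = 7.0
    rng_seed: int = 0

    def __post_init__(self):
        if not self.sowing_dates or not self.moisture_levels:
            raise ValueError("design lists must be nonempty")
        if self.n_seeds_per_plot <= 0:
            raise ValueError("n_seeds_per_plot must be > 0")


def generate_env(sowing_date: _dt.date, target_theta: float, seed: int,
                 days: int = 60, temp_at_sowing: float = 17.0,
                 trend_per_day: float = -0.10, diurnal_amp: float = 4.0,
                 ar1_rho: float = 0.95, ar1_sd: float = 0.4,
                 drydown_per_day: float = 0.02,
                 swc_band: float = 0.05) -> TreatmentEnv:
    """Hourly driver series for one treatment.

    Temperature is a cooling autumn trend plus a diurnal sinusoid (peak at
    15:00) plus AR(1) noise.  Soil water content follows irrigation-managed
    sawtooth cycles: it dries down at ``drydown_per_day`` and is topped up
    when it falls ``swc_band`` below the target, so it oscillates in
    ``[target - swc_band, min(target + swc_band, 0.85)]`` with mean close to
    the target level.  Deterministic per ``seed``.
    """
    if not 0 < target_theta <= 1:
        raise ValueError("target_theta must be in (0, 1]")
    rng = np.random.default_rng(seed)
    hours = np.arange(days * 24)
    t_days = hours / 24.0
    diurnal = diurnal_amp * np.sin(2 * np.pi * (hours % 24 - 9) / 24.0)
    noise = np.zeros(len(hours))
    eps = rng.normal(0.0, ar1_sd, size=len(hours))
    for i in range(1, len(hours)):
        noise[i] = ar1_rho * noise[i - 1] + eps[i]
    temps = temp_at_sowing + trend_per_day * t_days + diurnal + noise

    hi = min(target_theta + swc_band, 0.85)
    lo = target_theta - swc_band
    period = max((hi - lo) / drydown_per_day, 1e-6)
    swc = hi - (t_days % period) * drydown_per_day
    swc = np.clip(swc, lo, hi)

    index = pd.date_range(pd.Timestamp(sowing_date), periods=len(hours), freq="h")
    return TreatmentEnv(sowing_date=sowing_date,
                        temps=pd.Series(temps, index=index),
                        swc=pd.Series(swc, index=index))


def generate_observations(days, u_G: float, D_G: float, n_seeds: int | None,
                          seed: int, viable_frac: float = 1.0,
                          gamma: float | None = None, u_T: float | None = None,
                          D_T: float | None = None, tiller_days=None,
                          with_correction: bool = True,
                          allow_decreases: bool = False) -> ObservationSeries:
    """Noisy observation series from known stage parameters.

    Emergence counts use a binomial observation model with monotone
    coupling: each of the ``n_seeds`` seeds carries one uniform draw and is
    counted from the first day the model emergence probability exceeds it,
    so cumulative counts never decrease (field counting of cumulative
    emergence).  ``n_seeds=None`` returns the noise-free model curve.
    Tiller counts are Poisson around the model tiller curve (per metre of
    row, treating ``n_seeds`` as the seeds in the counted section).

    ``allow_decreases`` adds independent counting error (e.g. bird
    predation) on top; off by default.
    """
    days = np.asarray(days, dtype=float)
    rng = np.random.default_rng(seed)
    frac = viable_frac * analytic.emerged_fraction(days, u_G, D_G, 1.0,
                                                   with_correction)
    if n_seeds is None:
        pct = 100.0 * frac
    else:
        draws = rng.uniform(size=n_seeds)
        counts = (draws[None, :] <= frac[:, None]).sum(axis=1)
        if allow_decreases:
            counts = np.maximum(0, counts - rng.poisson(0.5, size=len(days)))
        pct = 100.0 * counts / n_seeds

    tillers = None
    if gamma is not None and u_T is not None and D_T is not None:
        tdays = days if tiller_days is None else np.asarray(tiller_days, dtype=float)
        sim = tiller_sim_factory(tdays, u_G, D_G, gamma,
                                 scale=(n_seeds or 100) * viable_frac,
                                 with_correction=with_correction)
        lam = sim(u_T, D_T)
        tillers = rng.poisson(lam) if n_seeds is not None else lam
        if tiller_days is not None:
            return ObservationSeries(days=tdays, tillers_per_m=tillers)
    return ObservationSeries(days=days, emerged_pct=pct, tillers_per_m=tillers)


@dataclass
class Treatment:
    """One cell of the factorial: drivers, generating truth, observations."""

    treatment_id: str
    sowing_date: _dt.date
    moisture_level: float
    env: TreatmentEnv
    truth: dict
    emergence_obs: list      # one ObservationSeries per replicate plot
    tiller_obs: list         # one ObservationSeries per replicate plot


@dataclass
class StudyBundle:
    design: StudyDesign
    env41: Env41Params
    dispersion_rel: environment.DispersionRelation
    treatments: list


def generate_study(design: StudyDesign, env41: Env41Params | None = None,
                   dispersion_rel: environment.DispersionRelation | None = None,
                   gamma: float = 4.0, till_speed_factor: float = 0.35,
                   noise_free: bool = False, t_end_germ: float = 40.0,
                   t_end_till: float = 120.0,
                   averaging_window_days: float = 30.0) -> StudyBundle:
    """Full synthetic factorial study.

    For each treatment: drivers are generated, their time averages mapped to
    a germination speed through the environmental response, the dispersion
    coefficient through the speed-dispersion relation, and noisy replicate
    observation series drawn from the resulting curves.  The tillering truth
    is ``u_T = till_speed_factor * u_G`` with ``D_T`` from the same
    dispersion relation.  All generating parameters are recorded in
    ``truth`` for recovery tests.
    """
    env41 = env41 or Env41Params()
    rel = dispersion_rel or environment.DispersionRelation("power", (0.05, 1.0))
    rng = np.random.default_rng(design.rng_seed)
    germ_days = np.arange(design.germ_cadence_days, t_end_germ + 1e-9,
                          design.germ_cadence_days)
    till_days = np.arange(design.tiller_cadence_days, t_end_till + 1e-9,
                          design.tiller_cadence_days)
    treatments = []
    for sow in design.sowing_dates:
        for theta in design.moisture_levels:
            env_seed = int(rng.integers(2 ** 31))
            env = generate_env(sow, theta, seed=env_seed)
            T_bar, theta_bar = environment.time_average_drivers(
                env, window_end_rule=averaging_window_days)
            u_G = environment.germination_speed(T_bar, theta_bar, env41)
            tid = f"{sow.isoformat()}_theta{int(round(theta * 100))}"
            if u_G <= 0:
                import warnings
                warnings.warn(f"treatment {tid}: germination speed clamps to 0; "
                              "no emergence will be generated")
                treatments.append(Treatment(tid, sow, theta, env,
                                            {"T_bar": T_bar, "theta_bar": theta_bar,
                                             "u_G": 0.0}, [], []))
                continue
            D_G = rel.predict(u_G)
            u_T = till_speed_factor * u_G
            D_T = rel.predict(u_T)
            truth = {"T_bar": T_bar, "theta_bar": theta_bar, "u_G": u_G,
                     "D_G": D_G, "u_T": u_T, "D_T": D_T, "gamma": gamma,
                     "viable_frac": 1.0}
            em_obs, ti_obs = [], []
            for _ in range(design.replicate_count):
                obs_seed = int(rng.integers(2 ** 31))
                n_seeds = None if noise_free else design.n_seeds_per_plot
                em = generate_observations(germ_days, u_G, D_G, n_seeds,
                                           seed=obs_seed)
                ti = generate_observations(
                    germ_days, u_G, D_G, n_seeds, seed=obs_seed + 1,
                    gamma=gamma, u_T=u_T, D_T=D_T, tiller_days=till_days)
                em_obs.append(em)
                ti_obs.append(ti)
            treatments.append(Treatment(tid, sow, theta, env, truth,
                                        em_obs, ti_obs))
    return StudyBundle(design=design, env41=env41, dispersion_rel=rel,
                       treatments=treatments)


def random_walk_germination(n_walkers: int, u: float, D: float,
                            L0: float = 1.0, dt_micro: float = 1e-3,
                            step_distribution: str = "gamma",
                            seed: int = 0) -> np.ndarray:
    """Empirical emergence-time sample from the jump-process picture.

    Each walker makes i.i.d. positive physiological advancements per micro
    step, drawn from a distribution with mean ``u * dt_micro`` and variance
    ``2 * D * dt_micro`` (Gamma by default, which can match any such moment
    pair on positive support).  Emergence time is the first crossing of
    ``L0``.  Returns the sorted sample; deterministic per seed.

    The Kramers-Moyal truncation behind the continuum model keeps only these
    two moments, so the sample converges to the model's emergence curve in
    the advection-dominated regime ``u * L0 / D >> 1`` (the mismatch is set
    by the walk's skewness ``2 / sqrt(u L0 / 2D)``, not by ``dt_micro``).
    """
    if n_walkers <= 0 or u <= 0 or D <= 0 or dt_micro <= 0:
        raise ValueError("n_walkers, u, D and dt_micro must be > 0")
    mean = u * dt_micro
    var = 2.0 * D * dt_micro
    if step_distribution == "gamma":
        shape = mean ** 2 / var
        scale = var / mean

        def draw(rng, size):
            return rng.gamma(shape, scale, size=size)
    elif step_distribution == "lognormal":
        sigma2 = np.log(1.0 + var / mean ** 2)
        mu = np.log(mean) - 0.5 * sigma2

        def draw(rng, size):
            return rng.lognormal(mu, np.sqrt(sigma2), size=size)
    else:
        raise ValueError(f"unknown step distribution: {step_distribution!r}")

    rng = np.random.default_rng(seed)
    pos = np.zeros(n_walkers)
    alive = np.arange(n_walkers)
    times = np.full(n_walkers, np.nan)
    block = max(1, int(2e7 / max(len(alive), 1)))
    step0 = 0
    max_steps = int(50 * L0 / (u * dt_micro))
    while len(alive) and step0 < max_steps:
        b = min(block, max_steps - step0)
        inc = draw(rng, (len(alive), b))
        paths = pos[alive, None] + np.cumsum(inc, axis=1)
        crossed = paths >= L0
        any_cross = crossed.any(axis=1)
        first = np.where(any_cross, crossed.argmax(axis=1), b - 1)
        times[alive[any_cross]] = (step0 + first[any_cross] + 1) * dt_micro
        pos[alive] = paths[np.arange(len(alive)), b - 1]
        alive = alive[~any_cross]
        step0 += b
        block = max(1, int(2e7 / max(len(alive), 1)))
    return np.sort(times[~np.isnan(times)])
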
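"""Explicit second-order finite-volume solver for the coupled germination
and tillering advection-dispersion equations on the physiological axis.

The scheme is forward-Euler in time with central (arithmetic-mean) advective
face fluxes and two-point diffusive fluxes:

    m_i(t + dt) = m_i(t) + dt/dx * (q_west - q_east)

with boundary fluxes: zero inflow at ``x = 0`` (the initial seed pulse is
placed in the first cell at t = 0), a purely advective outflux ``u * m`` at
the stage ends ``x = L0`` and ``x = L1``, and a junction inflow
``gamma * u_G * n(L0)`` into the first tillering cell so that each emerged
seedling seeds ``gamma`` potential tillers.

Three step constraints are enforced as hard errors, not warnings:

* advective CFL, ``dx > u * dt``;
* cell Peclet, ``u * dx / D < 2`` (keeps the central flux non-oscillatory);
* explicit diffusion, ``D * dt / dx^2 <= 0.4`` (forward-Euler stability;
  implied but not stated by the scheme's derivation).

:func:`choose_steps` picks ``(dx, dt)`` satisfying all three with a safety
factor on ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (InvariantError, PhysioDomain, SeedLot, StageParams,
                    StateProfile, _is_integer_multiple)

__all__ = ["SolverSettings", "Trajectory", "choose_steps", "step", "simulate"]

_DIFF_NUMBER = 0.4   # D*dt/dx^2 bound for the explicit diffusion update
_PECLET_FRAC = 0.9   # target u*dx/D = _PECLET_FRAC * 2 when choosing dx
_MAX_CELLS = 200_000


@dataclass
class SolverSettings:
    """Grid spacing, time step (``None`` selects it automatically from the
    stability constraints), horizon and output cadence, all in days except
    ``dx`` (physiological units)."""

    dx: float = 0.01
    dt: float | None = None
    t_end: float = 60.0
    record_every: float = 1.0

    def __post_init__(self):
        if not (self.dx > 0 and self.t_end > 0 and self.record_every > 0):
            raise InvariantError("dx, t_end and record_every must be > 0")
        if self.dt is not None and not self.dt > 0:
            raise InvariantError("dt must be > 0 when given")


def choose_steps(u_max: float, D: float, L0: float = 1.0,
                 L1: float | None = 2.0, safety: float = 0.5) -> tuple[float, float]:
    """Select ``(dx, dt)`` satisfying the three stability constraints.

    ``dx`` is the coarsest spacing that divides both stages evenly, keeps at
    least 10 cells in the germination stage and keeps the cell Peclet number
    ``u_max * dx / D`` below 2 (with margin).  ``dt`` is the diffusive limit
    ``0.4 dx^2 / D``, additionally capped by the advective CFL limit and
    scaled by ``safety`` when ``u_max > 0``.
    """
    if not (np.isfinite(u_max) and np.isfinite(D)):
        raise ValueError("u_max and D must be finite")
    if u_max < 0 or D <= 0:
        raise ValueError("require u_max >= 0 and D > 0")
    if u_max > 0:
        dx_target = min(L0 / 10.0, _PECLET_FRAC * 2.0 * D / u_max)
    else:
        dx_target = L0 / 100.0
    k = int(np.ceil(L0 / dx_target - 1e-12))
    if L1 is not None:
        while k <= _MAX_CELLS and not _is_integer_multiple(L1 - L0, L0 / k):
            k += 1
    if k > _MAX_CELLS:
        raise ValueError(
            "cannot satisfy the cell-Peclet constraint u*dx/D < 2 with a "
            f"tractable grid (would need more than {_MAX_CELLS} cells); "
            "u is too large relative to D")
    dx = L0 / k
    dt_diff = _DIFF_NUMBER * dx ** 2 / D
    if u_max > 0:
        # the last cap keeps the scheme's anti-diffusion -u^2 dt/2 below 10% of D
        dt = safety * min(dx / u_max, dt_diff, 0.2 * D / u_max ** 2)
    else:
        dt = dt_diff
    assert dx > u_max * dt and u_max * dx / D < 2.0 and D * dt / dx ** 2 <= _DIFF_NUMBER
    return dx, dt


def _check_stability(u: float, D: float, dx: float, dt: float, stage: str) -> None:
    if u > 0 and not dx > u * dt:
        raise InvariantError(
            f"{stage}: advective CFL violated (dx={dx} <= u*dt={u * dt})")
    if u * dx / D >= 2.0:
        raise InvariantError(
            f"{stage}: cell Peclet u*dx/D = {u * dx / D:.3f} >= 2; refine dx")
    if D * dt / dx ** 2 > _DIFF_NUMBER + 1e-12:
        raise InvariantError(
            f"{stage}: explicit diffusion limit violated "
            f"(D*dt/dx^2 = {D * dt / dx ** 2:.3f} > {_DIFF_NUMBER})")


def _fluxes(m: np.ndarray, u: float, D: float, dx: float,
            q_in: float, out: np.ndarray) -> np.ndarray:
    """Face fluxes for one stage; ``out`` has length len(m)+1."""
    out[0] = q_in
    out[1:-1] = D * (m[:-1] - m[1:]) / dx + u * (m[:-1] + m[1:]) / 2.0
    out[-1] = u * m[-1]
    return out


def step(state: StateProfile, germ: StageParams, till: StageParams | None,
         lot: SeedLot, dom: PhysioDomain, dt: float) -> StateProfile:
    """Advance the coupled state by one explicit step of length ``dt``.

    Returns a new :class:`~germflow.types.StateProfile`; the input is not
    modified.  Stability violations and negative densities beyond round-off
    raise :class:`~germflow.types.InvariantError`.
    """
    uG, DG = germ.u_at(state.t), germ.D_at(state.t)
    _check_stability(uG, DG, dom.dx, dt, "germination")
    n = state.n.copy()
    qg = np.empty(len(n) + 1)
    _fluxes(n, uG, DG, dom.dx, 0.0, qg)
    emergence_flux = qg[-1]
    new_n = n + dt / dom.dx * (qg[:-1] - qg[1:])

    Nt = state.N.copy()
    new_emerged = state.emerged + emergence_flux * dt
    new_done = state.tillers_done
    if till is not None and len(Nt):
        uT, DT = till.u_at(state.t), till.D_at(state.t)
        _check_stability(uT, DT, dom.dx, dt, "tillering")
        qt = np.empty(len(Nt) + 1)
        _fluxes(Nt, uT, DT, dom.dx, lot.gamma * emergence_flux, qt)
        new_done = state.tillers_done + qt[-1] * dt
        Nt = Nt + dt / dom.dx * (qt[:-1] - qt[1:])

    floor = -1e-12 * lot.N0 / dom.dx
    if np.any(new_n < floor) or np.any(Nt < floor * lot.gamma):
        raise InvariantError("negative density produced; step is unstable")
    return StateProfile(t=state.t + dt, n=np.maximum(new_n, 0.0),
                        N=np.maximum(Nt, 0.0), emerged=new_emerged,
                        tillers_done=new_done)


@dataclass
class Trajectory:
    """Recorded output of a simulation: times (days), cumulative emerged
    seedlings, cumulative completed tillers, and the tiller density still in
    transit through the tillering stage (integrated over ``(L0, L1]``)."""

    t: np.ndarray
    emerged: np.ndarray
    tillers_done: np.ndarray
    tillers_in_stage: np.ndarray
    N0: float
    final_state: StateProfile

    @property
    def emerged_pct(self) -> np.ndarray:
        return 100.0 * self.emerged / self.N0

    @property
    def tillers(self) -> np.ndarray:
        """Default field observable: cumulative tillers past ``x = L1``."""
        return self.tillers_done

    @property
    def tillers_visible(self) -> np.ndarray:
        """Alternative observable: every tiller initiated (in transit or
        completed), for studies where field counts see immature tillers."""
        return self.tillers_done + self.tillers_in_stage

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"t_days": self.t, "emerged_pct": self.emerged_pct,
                             "tillers": self.tillers})


def simulate(germ: StageParams, till: StageParams | None, lot: SeedLot,
             dom: PhysioDomain, settings: SolverSettings,
             drivers: tuple | None = None) -> Trajectory:
    """Integrate the coupled system from the initial seed pulse.

    The initial condition places all ``N0`` seeds in the first cell of the
    germination stage at t = 0; thereafter the inlet flux is zero.  When
    ``drivers`` is given as ``(times_days, u_G_values, D_G_values)`` the
    germination-stage parameters follow that step function (evaluated at the
    beginning of each step), overriding ``germ``; the series must cover
    ``[0, t_end]``.
    """
    if drivers is not None:
        times = np.asarray(drivers[0], dtype=float)
        if times[0] > 1e-12:
            raise InvariantError("driver series must start at t=0")
        if len(times) > 1 and times[-1] < settings.t_end - 1e-9:
            raise InvariantError(
                f"driver series ends at t={times[-1]} but the horizon is "
                f"t_end={settings.t_end}")
        germ = StageParams(u=(times, np.asarray(drivers[1], dtype=float)),
                           D=(times, np.asarray(drivers[2], dtype=float)))

    dx = settings.dx
    if not (_is_integer_multiple(dom.L0, dx)
            and _is_integer_multiple(dom.L1 - dom.L0, dx)):
        raise InvariantError("settings.dx must divide both stages evenly")
    u_hi = germ.u_max() if till is None else max(germ.u_max(), till.u_max())
    D_hi = germ.D_max() if till is None else max(germ.D_max(), till.D_max())
    if settings.dt is None:
        dt_diff = _DIFF_NUMBER * dx ** 2 / D_hi
        if u_hi > 0:
            # third cap: forward-Euler advection carries an anti-diffusion
            # -u^2 dt/2; keep it below 10% of the smallest physical D
            D_lo = germ.D_min() if till is None else min(germ.D_min(), till.D_min())
            dt = 0.5 * min(dx / u_hi, dt_diff, 0.2 * D_lo / u_hi ** 2)
        else:
            dt = dt_diff
    else:
        dt = settings.dt
    # align dt so recording times are hit exactly
    n_sub = max(1, int(np.ceil(settings.record_every / dt - 1e-12)))
    dt = settings.record_every / n_sub

    stages = [("germination", germ)] + ([("tillering", till)] if till is not None else [])
    for name, sp in stages:
        _check_stability(sp.u_max(), sp.D_min(), dx, dt, name)   # CFL + Peclet worst case
        if sp.D_max() * dt / dx ** 2 > _DIFF_NUMBER + 1e-12:
            raise InvariantError(f"{name}: explicit diffusion limit violated")

    Mg = round(dom.L0 / dx)
    Mt = round((dom.L1 - dom.L0) / dx) if till is not None else 0
    n = np.zeros(Mg)
    n[0] = lot.N0 / dx          # discrete Dirac pulse at x = 0+
    Nt = np.zeros(Mt)
    emerged = 0.0
    done = 0.0
    qg = np.empty(Mg + 1)
    qt = np.empty(Mt + 1)

    n_rec = int(np.floor(settings.t_end / settings.record_every + 1e-9)) + 1
    rec_t = np.empty(n_rec)
    rec_e = np.empty(n_rec)
    rec_d = np.empty(n_rec)
    rec_s = np.empty(n_rec)
    rec_t[0], rec_e[0], rec_d[0], rec_s[0] = 0.0, 0.0, 0.0, 0.0

    constant = germ.is_constant and (till is None or till.is_constant)
    if constant:
        uG, DG = germ.u_at(0.0), germ.D_at(0.0)
        if till is not None:
            uT, DT = till.u_at(0.0), till.D_at(0.0)
    t = 0.0
    for rec in range(1, n_rec):
        for _ in range(n_sub):
            if not constant:
                uG, DG = germ.u_at(t), germ.D_at(t)
                if till is not None:
                    uT, DT = till.u_at(t), till.D_at(t)
            _fluxes(n, uG, DG, dx, 0.0, qg)
            if till is not None:
                _fluxes(Nt, uT, DT, dx, lot.gamma * qg[-1], qt)
                done += qt[-1] * dt
                Nt += dt / dx * (qt[:-1] - qt[1:])
            emerged += qg[-1] * dt
            n += dt / dx * (qg[:-1] - qg[1:])
            t += dt
        if n[0] < -1e-12 * lot.N0 / dx or (Mt and Nt[0] < -1e-12 * lot.N0 / dx):
            raise InvariantError("negative density produced; step is unstable")
        rec_t[rec] = rec * settings.record_every
        rec_e[rec] = emerged
        rec_d[rec] = done
        rec_s[rec] = float(np.sum(Nt)) * dx

    final = StateProfile(t=t, n=np.maximum(n, 0.0), N=np.maximum(Nt, 0.0),
                         emerged=emerged, tillers_done=done)
    return Trajectory(t=rec_t, emerged=rec_e, tillers_done=rec_d,
                      tillers_in_stage=rec_s, N0=lot.N0, final_state=final)
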
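"""Shared domain types for the physiological-dimension germination model.

Development from seed imbibition to seedling emergence is mapped onto an
abstract physiological axis ``x``: a seed starts at ``x = 0``, emerges as a
seedling when it reaches ``x = L0``, and each emerged seedling then advances
through a tillering stage ending at ``x = L1``.  Both stages are modelled as
advection-dispersion transport, with a stage speed ``u`` (mean physiological
advancement per day) and a dispersion coefficient ``D`` (variance rate,
capturing seed heterogeneity and environmental fluctuation).

All types validate their invariants on construction; :func:`validate` re-runs
the checks on demand.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "InvariantError",
    "PhysioDomain",
    "StageParams",
    "SeedLot",
    "StateProfile",
    "DimensionlessGroups",
    "Env41Params",
    "TreatmentEnv",
    "ObservationSeries",
    "HydrotimeParams",
    "CalibResult",
    "validate",
]


class InvariantError(ValueError):
    """Raised when a domain type violates one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvariantError(msg)


def _finite(name: str, *vals) -> None:
    for v in vals:
        if v is None:
            continue
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise InvariantError(f"{name} must be finite")


def _is_integer_multiple(span: float, dx: float, rtol: float = 1e-9) -> bool:
    k = span / dx
    return abs(k - round(k)) <= rtol * max(1.0, abs(k))


@dataclass(frozen=True)
class PhysioDomain:
    """The physiological axis: germination span ``(0, L0]``, tillering span
    ``(L0, L1]``, and the cell-centred grid spacing ``dx``.

    By convention the germination stage is one physiological unit (``L0 = 1``)
    and the tillering stage a second unit (``L1 = 2``).
    """

    L0: float = 1.0
    L1: float = 2.0
    dx: float = 0.01

    def __post_init__(self):
        _finite("PhysioDomain", self.L0, self.L1, self.dx)
        _require(0 < self.L0 < self.L1, "PhysioDomain requires 0 < L0 < L1")
        _require(0 < self.dx <= self.L0 / 10 + 1e-15,
                 "dx must satisfy 0 < dx <= L0/10 (at least 10 cells per stage)")
        _require(_is_integer_multiple(self.L0, self.dx),
                 "dx must divide L0 into a whole number of cells")
        _require(_is_integer_multiple(self.L1 - self.L0, self.dx),
                 "dx must divide L1 - L0 into a whole number of cells")

    @property
    def n_germ(self) -> int:
        """Number of cells in the germination stage."""
        return round(self.L0 / self.dx)

    @property
    def n_till(self) -> int:
        """Number of cells in the tillering stage."""
        return round((self.L1 - self.L0) / self.dx)

    def germ_centers(self) -> np.ndarray:
        return (np.arange(self.n_germ) + 0.5) * self.dx

    def till_centers(self) -> np.ndarray:
        return self.L0 + (np.arange(self.n_till) + 0.5) * self.dx


@dataclass(frozen=True)
class StageParams:
    """Speed and dispersion of one physiological stage.

    ``u`` is in physiological units per day (>= 0), ``D`` in physiological
    units squared per day (> 0).  Either may be a scalar or a step-function
    time series given as ``(times_days, values)`` arrays; series must cover
    the whole simulated horizon (checked by the solver).
    """

    u: float | tuple = 0.1
    D: float | tuple = 0.005

    def __post_init__(self):
        for name, val, lower_ok in (("u", self.u, True), ("D", self.D, False)):
            arr = np.asarray(val[1] if isinstance(val, tuple) else val, dtype=float)
            _finite(f"StageParams.{name}", arr)
            if name == "u":
                _require(np.all(arr >= 0), "u must be >= 0")
            else:
                _require(np.all(arr > 0), "D must be > 0")

    @property
    def is_constant(self) -> bool:
        return not (isinstance(self.u, tuple) or isinstance(self.D, tuple))

    def u_at(self, t: float) -> float:
        return _step_eval(self.u, t)

    def D_at(self, t: float) -> float:
        return _step_eval(self.D, t)

    def u_max(self) -> float:
        return float(np.max(self.u[1])) if isinstance(self.u, tuple) else float(self.u)

    def D_max(self) -> float:
        return float(np.max(self.D[1])) if isinstance(self.D, tuple) else float(self.D)

    def D_min(self) -> float:
        return float(np.min(self.D[1])) if isinstance(self.D, tuple) else float(self.D)


def _step_eval(val, t: float) -> float:
    """Previous-value (step function) interpolation for time-indexed parameters."""
    if not isinstance(val, tuple):
        return float(val)
    times, values = (np.asarray(v, dtype=float) for v in val)
    idx = int(np.searchsorted(times, t, side="right")) - 1
    if idx < 0:
        raise InvariantError(f"time-indexed parameter not defined at t={t}")
    return float(values[idx])


@dataclass(frozen=True)
class SeedLot:
    """Initial seed count and tiller potential.

    ``N0`` may be an absolute count or a relative viable fraction in (0, 1]
    after cross-treatment normalisation.  ``gamma`` is the mean number of
    tillers each emerged seedling can develop.
    """

    N0: float = 1.0
    gamma: float = 3.0

    def __post_init__(self):
        _finite("SeedLot", self.N0, self.gamma)
        _require(self.N0 > 0, "N0 must be > 0")
        _require(self.gamma > 0, "gamma must be > 0")


@dataclass
class StateProfile:
    """Discretised density over the physiological axis at one time point.

    ``n`` is the seed density per cell over ``(0, L0]``, ``N`` the potential
    tiller density over ``(L0, L1]``.  ``emerged`` and ``tillers_done`` are
    the cumulative advective outfluxes across ``x = L0`` and ``x = L1``, so
    the conservation balance ``sum(n) * dx + emerged = N0`` can be checked
    without re-integration.
    """

    t: float
    n: np.ndarray
    N: np.ndarray
    emerged: float = 0.0
    tillers_done: float = 0.0

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        _finite("StateProfile", self.n, self.N, self.emerged, self.tillers_done)
        _require(self.t >= 0, "t must be >= 0")
        tol = 1e-12 * (float(np.sum(self.n)) + float(np.sum(self.N)) + 1.0)
        _require(np.all(self.n >= -tol) and np.all(self.N >= -tol),
                 "densities must be nonnegative")
        _require(self.emerged >= -tol and self.tillers_done >= -tol,
                 "cumulative outfluxes must be nonnegative")

    def check_conservation(self, dom: PhysioDomain, lot: SeedLot,
                           rtol: float = 1e-8) -> None:
        """Verify mass balances of both stages; raises on violation."""
        germ = float(np.sum(self.n)) * dom.dx + self.emerged
        _require(abs(germ - lot.N0) <= rtol * lot.N0,
                 f"germination mass balance violated: {germ} != N0={lot.N0}")
        if self.N.size:   # junction balance only applies to coupled states
            till = float(np.sum(self.N)) * dom.dx + self.tillers_done
            _require(abs(till - lot.gamma * self.emerged)
                     <= rtol * max(lot.gamma * lot.N0, 1e-300),
                     "tillering junction mass balance violated")


@dataclass(frozen=True)
class DimensionlessGroups:
    """alpha = D/(u*L0) (inverse Peclet), tau = u*t/L0, X = x/L0."""

    alpha: float
    tau: float
    X: float

    def __post_init__(self):
        _finite("DimensionlessGroups", self.alpha, self.tau, self.X)
        _require(self.alpha > 0, "alpha must be > 0")
        _require(self.tau >= 0, "tau must be >= 0")
        _require(0 <= self.X <= 1, "X must be in [0, 1]")

    @classmethod
    def from_params(cls, x: float, t: float, u: float, D: float, L0: float = 1.0):
        return cls(alpha=D / (u * L0), tau=u * t / L0, X=x / L0)


@dataclass(frozen=True)
class Env41Params:
    """Coefficients of the environmental germination-speed response

    ``u_G = [a (T - T0) - b (T - T0)^2] * Theta^beta * (Theta - Theta_r) * (Theta_0 - Theta)^beta``

    with air temperature ``T`` (deg C) and soil water content ``Theta``
    expressed as a fraction of field capacity.  ``T0`` is the base
    temperature below which seeds stay dormant; ``theta_r`` and ``theta0``
    are the residual and upper-critical water contents (the latter marking
    oxygen limitation in wet soil).
    """

    a: float = 1.42       # day^-1 degC^-1
    T0: float = 12.6      # deg C
    b: float = 0.23       # day^-1 degC^-2
    beta: float = 1.2
    theta0: float = 1.0   # fraction of field capacity
    thetar: float = 0.05  # fraction of field capacity

    def __post_init__(self):
        _finite("Env41Params", self.a, self.T0, self.b, self.beta,
                self.theta0, self.thetar)
        _require(self.a > 0, "a must be > 0")
        _require(self.b >= 0, "b must be >= 0")
        _require(0 <= self.thetar < self.theta0 <= 1.2,
                 "require 0 <= thetar < theta0 <= 1.2")
        _require(self.beta > 0, "beta must be > 0")


@dataclass
class TreatmentEnv:
    """Driver series for one treatment: air temperature (deg C) and soil
    water content (fraction of field capacity), both indexed by timestamp,
    plus the sowing date."""

    sowing_date: _dt.date
    temps: pd.Series
    swc: pd.Series

    def __post_init__(self):
        _require(isinstance(self.temps, pd.Series) and isinstance(self.swc, pd.Series),
                 "temps and swc must be pandas Series with a datetime index")
        for name, s in (("temps", self.temps), ("swc", self.swc)):
            _require(len(s) > 0, f"{name} must be nonempty")
            _require(isinstance(s.index, pd.DatetimeIndex),
                     f"{name} must have a DatetimeIndex")
            _require(s.index.is_monotonic_increasing, f"{name} index must increase")
            _finite(name, s.to_numpy())
            diffs = np.diff(s.index.view("int64"))
            if len(diffs) > 1:
                _require(np.allclose(diffs, diffs[0]),
                         f"{name} cadence must be uniform")
            start = pd.Timestamp(self.sowing_date)
            _require(s.index[0] <= start + pd.Timedelta(days=1),
                     f"{name} must cover the sowing date onward")
        _require(bool(np.all(self.swc.to_numpy() >= 0))
                 and bool(np.all(self.swc.to_numpy() <= 1.2)),
                 "swc must lie in [0, 1.2] (fraction of field capacity)")

    def days_after_sowing(self, series: pd.Series) -> np.ndarray:
        t0 = pd.Timestamp(self.sowing_date)
        return (series.index - t0) / pd.Timedelta(days=1)


@dataclass
class ObservationSeries:
    """Dated observations of one treatment: cumulative emergence percentage
    and/or tiller counts per metre of row, on days after sowing."""

    days: np.ndarray
    emerged_pct: np.ndarray | None = None
    tillers_per_m: np.ndarray | None = None

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        _finite("ObservationSeries.days", self.days)
        _require(np.all(self.days >= 0), "days must be nonnegative")
        _require(np.all(np.diff(self.days) > 0), "days must be strictly increasing")
        _require(self.emerged_pct is not None or self.tillers_per_m is not None,
                 "at least one of emerged_pct / tillers_per_m must be present")
        if self.emerged_pct is not None:
            self.emerged_pct = np.asarray(self.emerged_pct, dtype=float)
            _finite("emerged_pct", self.emerged_pct)
            _require(len(self.emerged_pct) == len(self.days),
                     "emerged_pct length must match days")
            _require(np.all((self.emerged_pct >= 0) & (self.emerged_pct <= 100)),
                     "emerged_pct must lie in [0, 100]")
        if self.tillers_per_m is not None:
            self.tillers_per_m = np.asarray(self.tillers_per_m, dtype=float)
            _finite("tillers_per_m", self.tillers_per_m)
            _require(len(self.tillers_per_m) == len(self.days),
                     "tillers_per_m length must match days")
            _require(np.all(self.tillers_per_m >= 0), "tillers_per_m must be >= 0")


@dataclass(frozen=True)
class HydrotimeParams:
    """Hydrotime model parameters: hydrotime constant ``thetaH`` (MPa day)
    and the three-parameter Weibull distribution of the base water potential
    psi_b across the seed lot (shape, scale in MPa, location in MPa)."""

    thetaH: float
    wb_shape: float
    wb_scale: float
    wb_location: float

    def __post_init__(self):
        _finite("HydrotimeParams", self.thetaH, self.wb_shape,
                self.wb_scale, self.wb_location)
        _require(self.thetaH > 0, "thetaH must be > 0")
        _require(self.wb_shape > 0, "wb_shape must be > 0")
        _require(self.wb_scale > 0, "wb_scale must be > 0")


@dataclass
class CalibResult:
    """Outcome of a grid-search calibration of one stage."""

    u_hat: float
    D_hat: float
    r2: float
    grid_u: np.ndarray = field(default_factory=lambda: np.array([]))
    grid_D: np.ndarray = field(default_factory=lambda: np.array([]))
    refined: bool = False

    def __post_init__(self):
        _finite("CalibResult", self.u_hat, self.D_hat)
        _require(self.r2 <= 1 + 1e-12, "r2 cannot exceed 1")


_VALIDATABLE = (PhysioDomain, StageParams, SeedLot, StateProfile,
                DimensionlessGroups, Env41Params, TreatmentEnv,
                ObservationSeries, HydrotimeParams, CalibResult)


def validate(value):
    """Re-run a typed value's invariant checks; returns it unchanged.

    Raises :class:`InvariantError` naming the offending field otherwise.
    """
    if not isinstance(value, _VALIDATABLE):
        raise TypeError(f"cannot validate object of type {type(value).__name__}")
    value.__post_init__()
    return value
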
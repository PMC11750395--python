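"""Environmental driver functions.

Links weather and soil moisture to the germination-stage parameters:

* :func:`germination_speed` — the empirical response
  ``u_G = [a(T - T0) - b(T - T0)^2] * Theta^beta (Theta - Theta_r) (Theta_0 - Theta)^beta``,
  a suboptimal-range temperature quadratic times a hump-shaped moisture
  factor expressing the trade-off between water supply (rising with Theta)
  and oxygen bioavailability (falling as Theta approaches Theta_0);
* :class:`DispersionRelation` — the observed tight correlation between a
  stage's speed and its dispersion coefficient, so D can be predicted from u;
* :func:`time_average_drivers` — treatments are summarised by the time
  averages of temperature and soil water over the germination window;
* :func:`porosity` / :func:`gas_diffusivity_ratio` — the soil-physics
  arithmetic connecting bulk density to porosity and porosity to relative
  O2 diffusivity (power law with exponent ~10/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .types import Env41Params, InvariantError, ObservationSeries, TreatmentEnv

__all__ = [
    "germination_speed", "DispersionRelation", "fit_dispersion_relation",
    "time_average_drivers", "fit_env41", "porosity", "gas_diffusivity_ratio",
]


def germination_speed(T, theta, p: Env41Params):
    """Germination speed (day^-1) from air temperature (deg C) and soil water
    content (fraction of field capacity).

    Clamped to zero outside the admissible ranges: at ``T <= T0`` (and on the
    supra-optimal branch where the quadratic goes negative) and outside
    ``theta_r < theta < theta_0``.  Vectorised over ``T`` and ``theta``.
    """
    T = np.asarray(T, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (np.all(np.isfinite(T)) and np.all(np.isfinite(theta))):
        raise ValueError("T and theta must be finite")
    dT = T - p.T0
    temp = np.maximum(0.0, p.a * dT - p.b * dT ** 2)
    inside = (theta > p.thetar) & (theta < p.theta0)
    th = np.where(inside, theta, 0.5 * (p.thetar + p.theta0))
    moist = np.where(
        inside,
        th ** p.beta * (th - p.thetar) * (p.theta0 - th) ** p.beta,
        0.0)
    out = temp * moist
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DispersionRelation:
    """Predicts a stage's dispersion coefficient from its speed.

    ``power``: D = c * u^d (default; simplest monotone positive family).
    ``linear``: D = c0 + c1 * u.
    """

    form: str = "power"
    coeffs: tuple = (0.05, 1.0)

    def __post_init__(self):
        if self.form not in ("power", "linear"):
            raise InvariantError("form must be 'power' or 'linear'")
        if self.form == "power" and not (self.coeffs[0] > 0):
            raise InvariantError("power form requires c > 0")

    def predict(self, u):
        """Dispersion D (> 0) for speed ``u`` (>= 0)."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("u must be >= 0")
        if self.form == "power":
            c, d = self.coeffs
            out = c * u ** d
        else:
            c0, c1 = self.coeffs
            out = c0 + c1 * u
        if np.any(np.asarray(out) <= 0):
            raise InvariantError("predicted D must be > 0 over the u range")
        return out if np.ndim(out) else float(out)


def dispersion_from_speed(u, rel: DispersionRelation):
    """Functional alias for ``rel.predict(u)``."""
    return rel.predict(u)


def fit_dispersion_relation(u, D, form: str = "power") -> DispersionRelation:
    """Least-squares fit of the D-u relation.

    The power form is fitted in log space (exact round-trip on noise-free
    power-law pairs); the linear form by ordinary least squares.
    """
    u = np.asarray(u, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(u <= 0) or np.any(D <= 0):
        raise ValueError("fitting requires positive u and D values")
    if form == "power":
        d, logc = np.polyfit(np.log(u), np.log(D), 1)
        return DispersionRelation("power", (float(np.exp(logc)), float(d)))
    coef = np.polyfit(u, D, 1)
    return DispersionRelation("linear", (float(coef[1]), float(coef[0])))


def time_average_drivers(env: TreatmentEnv, window_end_rule="fixed:30",
                         obs: ObservationSeries | None = None) -> tuple[float, float]:
    """Arithmetic means of temperature and soil water over the germination
    window starting at sowing.

    ``window_end_rule`` is either ``"fixed:<days>"`` (or a plain number of
    days) for prediction mode, or ``"emergence90"``, which ends the window on
    the first observed day reaching 90% of the final observed emergence
    (requires ``obs``).
    """
    if isinstance(window_end_rule, (int, float)):
        end_day = float(window_end_rule)
    elif isinstance(window_end_rule, str) and window_end_rule.startswith("fixed:"):
        end_day = float(window_end_rule.split(":", 1)[1])
    elif window_end_rule == "emergence90":
        if obs is None or obs.emerged_pct is None:
            raise ValueError("emergence90 window rule needs emergence observations")
        target = 0.9 * obs.emerged_pct[-1]
        end_day = float(obs.days[np.argmax(obs.emerged_pct >= target)])
    else:
        raise ValueError(f"unknown window_end_rule: {window_end_rule!r}")
    if end_day <= 0:
        raise ValueError("averaging window is empty")
    start = pd.Timestamp(env.sowing_date)
    end = start + pd.Timedelta(days=end_day)
    means = []
    for s in (env.temps, env.swc):
        window = s[(s.index >= start) & (s.index <= end)]
        if len(window) == 0:
            raise ValueError("driver series has no samples in the averaging window")
        means.append(float(window.mean()))
    return means[0], means[1]


def fit_env41(points, init: Env41Params | None = None,
              free_all: bool = False) -> tuple[Env41Params, float]:
    """Least-squares fit of the germination-speed response to estimated
    speeds.

    Parameters
    ----------
    points : iterable of (T_bar, theta_bar, u_hat)
        Per-treatment mean temperature, mean soil water content (fraction of
        field capacity) and calibrated germination speed.
    init : Env41Params, optional
        Starting parameter set (defaults to a neutral guess).
    free_all : bool
        By default the critical water contents ``theta0`` and ``thetar`` are
        held fixed at their ``init`` values and only ``(a, T0, b, beta)`` are
        fitted: on a factorial design with a handful of moisture levels the
        six-parameter problem is rank-deficient (the moisture-shape
        parameters and the overall scale are confounded).  Set
        ``free_all=True`` to fit all six.

    Returns ``(params, rss)``; exact round-trip (rss < 1e-10) on noise-free
    generated points.
    """
    pts = np.asarray([(float(T), float(th), float(u)) for T, th, u in points])
    if len(pts) < 6:
        raise ValueError("need at least 6 points to fit the response")
    T, th, u = pts[:, 0], pts[:, 1], pts[:, 2]
    if np.allclose(T, T[0]) or np.allclose(th, th[0]):
        raise ValueError("rank-deficient design: need variation in both T and theta")
    if init is None:
        init = Env41Params(a=1.0, T0=float(T.min()) - 2.0, b=0.1, beta=1.0,
                           theta0=1.0, thetar=0.05)

    if free_all:
        x0 = [init.a, init.T0, init.b, init.beta, init.theta0, init.thetar]
        lo = [1e-6, -50.0, 0.0, 1e-3, float(th.max()) + 1e-3, 0.0]
        hi = [100.0, float(T.min()) - 1e-6, 10.0, 10.0, 1.2, float(th.min()) - 1e-3]

        def unpack(x):
            return Env41Params(a=x[0], T0=x[1], b=x[2], beta=x[3],
                               theta0=x[4], thetar=x[5])
    else:
        x0 = [init.a, init.T0, init.b, init.beta]
        lo = [1e-6, -50.0, 0.0, 1e-3]
        hi = [100.0, float(T.min()) - 1e-6, 10.0, 10.0]

        def unpack(x):
            return Env41Params(a=x[0], T0=x[1], b=x[2], beta=x[3],
                               theta0=init.theta0, thetar=init.thetar)

    def resid(x):
        return germination_speed(T, th, unpack(x)) - u

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15,
                                 ftol=1e-15, gtol=1e-15)
    rss = float(np.sum(sol.fun ** 2))
    return unpack(sol.x), rss


def porosity(bulk_density: float, particle_density: float = 2.67) -> float:
    """Total porosity ``phi = 1 - rho_bulk / rho_particle`` (fraction)."""
    if not (np.isfinite(bulk_density) and np.isfinite(particle_density)):
        raise ValueError("densities must be finite")
    if not 0 < bulk_density < particle_density:
        raise ValueError("require 0 < bulk_density < particle_density")
    return 1.0 - bulk_density / particle_density


def gas_diffusivity_ratio(phi_1: float, phi_2: float,
                          exponent: float = 10.0 / 3.0) -> float:
    """Relative gas diffusivity of two soils, ``(phi_1/phi_2)**exponent``.

    Soil O2 diffusivity scales with porosity as a power law with exponent
    close to 10/3 (Millington-Quirk-type behaviour).
    """
    if not (0 < phi_1 < 1 and 0 < phi_2 < 1):
        raise ValueError("porosities must lie in (0, 1)")
    return float((phi_1 / phi_2) ** exponent)
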
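"""Hydrotime comparison model.

The classical hydrotime description of germination at fixed temperature: the
seed fraction ``g`` germinates at time ``t_g`` satisfying

    (psi - psi_b(g)) * t_g = theta_H

where ``psi`` is the medium water potential (MPa), ``theta_H`` the hydrotime
constant (MPa day), and the base water potential ``psi_b`` varies across the
seed lot.  Here ``psi_b`` follows a three-parameter Weibull distribution
(shape, scale, location), so the germinated fraction at time ``t`` is

    G(t, psi) = F_Weibull(psi - theta_H / t)

This module exists so the physiological-dimension model can be scored
head-to-head against the hydrotime model on the same water-potential
germination curves (both are fitted by least squares and compared by R^2).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .calibrate import r_squared
from .types import HydrotimeParams

__all__ = ["htt_fraction", "fit_htt", "sample_base_potentials"]


def _weibull(p: HydrotimeParams):
    return stats.weibull_min(c=p.wb_shape, loc=p.wb_location, scale=p.wb_scale)


def htt_fraction(t, psi, p: HydrotimeParams):
    """Germinated fraction at time ``t`` (days) and water potential ``psi``
    (MPa).  Nondecreasing in both; tends to ``F_psi_b(psi)`` as t -> inf."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("t must be finite and > 0")
    out = _weibull(p).cdf(np.asarray(psi, dtype=float) - p.thetaH / t)
    return out if np.ndim(out) else float(out)


def sample_base_potentials(p: HydrotimeParams, n: int, seed: int) -> np.ndarray:
    """Monte-Carlo draws of the base water potential (oracle for tests)."""
    rng = np.random.default_rng(seed)
    return _weibull(p).rvs(size=n, random_state=rng)


# Documented multi-start list: (thetaH, shape, scale, -location) multipliers
# applied to a moment-based initial guess, to escape local minima.
_STARTS = [
    (1.0, 1.0, 1.0, 1.0),
    (0.3, 1.0, 1.0, 1.0),
    (3.0, 1.0, 1.0, 1.0),
    (1.0, 2.0, 0.5, 1.5),
    (1.0, 0.7, 2.0, 0.7),
]


def fit_htt(curves) -> tuple[HydrotimeParams, float]:
    """Joint least-squares fit of ``(theta_H, shape, scale, location)``
    across germination curves observed at several water potentials.

    Parameters
    ----------
    curves : mapping psi -> (days, fractions) or iterable of
        ``(psi, days, fractions)`` triples; at least 3 distinct psi levels
        with >= 4 time points each.

    Returns ``(params, r2)`` where R^2 pools all curves.  Deterministic: the
    documented 5-point multi-start list is tried and the best sum of squares
    kept.
    """
    if hasattr(curves, "items"):
        triples = [(psi, d, f) for psi, (d, f) in curves.items()]
    else:
        triples = [(psi, d, f) for psi, d, f in curves]
    psis = sorted({float(psi) for psi, _, _ in triples})
    if len(psis) < 3:
        raise ValueError("need >= 3 distinct water-potential levels")
    rows = []
    for psi, days, fracs in triples:
        days = np.asarray(days, dtype=float)
        fracs = np.asarray(fracs, dtype=float)
        if len(days) < 4:
            raise ValueError("each curve needs >= 4 time points")
        if np.any(days <= 0):
            raise ValueError("observation days must be > 0")
        if np.any((fracs < 0) | (fracs > 1)):
            raise ValueError("germinated fractions must lie in [0, 1]")
        rows.append(np.column_stack([np.full(len(days), float(psi)), days, fracs]))
    data = np.vstack(rows)
    psi_v, t_v, g_v = data[:, 0], data[:, 1], data[:, 2]

    # moment-based anchor: median base potential near the potential at which
    # half the seeds eventually germinate, spread from the psi range
    base0 = min(psis) - 0.5
    scale0 = max(0.2, (max(psis) - min(psis)) / 2 + 0.2)
    theta0 = max(0.5, float(np.median((psi_v - base0) * t_v)) / 4)

    def resid(x):
        thetaH, shape, scale, loc = x
        p = HydrotimeParams(thetaH=thetaH, wb_shape=shape, wb_scale=scale,
                            wb_location=loc)
        return htt_fraction(t_v, psi_v, p) - g_v

    lo = [1e-4, 0.05, 1e-3, -20.0]
    hi = [100.0, 50.0, 20.0, max(psis)]
    best = None
    for m_th, m_sh, m_sc, m_lo in _STARTS:
        x0 = [np.clip(theta0 * m_th, lo[0], hi[0]),
              np.clip(2.0 * m_sh, lo[1], hi[1]),
              np.clip(scale0 * m_sc, lo[2], hi[2]),
              np.clip(base0 * m_lo, lo[3], hi[3])]
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:   # noqa: BLE001 - a start may fail; others proceed
            continue
        ssr = float(np.sum(sol.fun ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        raise RuntimeError("hydrotime fit failed from every start")
    x = best[1]
    params = HydrotimeParams(thetaH=float(x[0]), wb_shape=float(x[1]),
                             wb_scale=float(x[2]), wb_location=float(x[3]))
    r2 = r_squared(g_v, htt_fraction(t_v, psi_v, params))
    return params, r2
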
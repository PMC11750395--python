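"""Model/Results interface over the calibration engine.

Each model class is built from data, and ``fit()`` returns a results object
carrying the estimates, fit diagnostics and a ``summary()`` table, in the
style of statistical modelling packages:

* :class:`GerminationModel` — (u_G, D_G) from cumulative emergence counts;
* :class:`TilleringModel` — (u_T, D_T) from tiller counts, with the
  germination stage frozen;
* :class:`StudyModel` — the sequential two-stage calibration across all
  treatments of a factorial study;
* :class:`EnvResponseModel` — the temperature x moisture germination-speed
  response fitted to per-treatment calibrated speeds;
* :class:`HydrotimeModel` — the hydrotime comparison model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analytic, calibrate, environment, hydrotime
from .types import CalibResult, Env41Params, HydrotimeParams, ObservationSeries

__all__ = [
    "GerminationModel", "GerminationResults",
    "TilleringModel", "TilleringResults",
    "StudyModel", "StudyResults",
    "EnvResponseModel", "EnvResponseResults",
    "HydrotimeModel", "HydrotimeResults",
]


def _pool(series_list, attr):
    """Pool replicate observation series into concatenated (day, value) points."""
    days, vals = [], []
    for s in series_list:
        v = getattr(s, attr)
        if v is None:
            continue
        days.append(s.days)
        vals.append(v)
    if not days:
        raise ValueError(f"no {attr} observations to pool")
    days = np.concatenate(days)
    vals = np.concatenate(vals)
    order = np.argsort(days, kind="stable")
    return days[order], vals[order]


class GerminationModel:
    """Grid-search calibration of the germination stage.

    Parameters
    ----------
    obs : ObservationSeries or list of ObservationSeries
        Emergence observations; replicates are pooled before fitting.
    viable_frac : float
        Relative viable-seed fraction of this treatment (from
        :func:`germflow.calibrate.normalize_viable`); the simulated curve
        plateaus at ``100 * viable_frac`` percent.
    grid_u, grid_D : array_like, optional
        Candidate grids (defaults are the module-level log-spaced grids).
    with_correction : bool
        Use the boundary-corrected analytic emergence curve (recommended;
        matches the finite-volume solution to <= 0.01).
    """

    def __init__(self, obs, viable_frac: float = 1.0, grid_u=None, grid_D=None,
                 L0: float = 1.0, with_correction: bool = True):
        if isinstance(obs, ObservationSeries):
            obs = [obs]
        self.obs = obs
        self.days, self.values = _pool(obs, "emerged_pct")
        self.viable_frac = float(viable_frac)
        self.grid_u = grid_u
        self.grid_D = grid_D
        self.L0 = L0
        self.with_correction = with_correction

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, day_col: str = "day",
                       value_col: str = "emerged_pct", **kwargs):
        obs = ObservationSeries(days=df[day_col].to_numpy(),
                                emerged_pct=df[value_col].to_numpy())
        return cls(obs, **kwargs)

    def _factory(self):
        return calibrate.analytic_sim_factory(
            self.days, amplitude=100.0 * self.viable_frac, L0=self.L0,
            with_correction=self.with_correction)

    def fit(self, refine: bool = True) -> "GerminationResults":
        res = calibrate.calibrate_stage(
            self.days, grid_u=self.grid_u, grid_D=self.grid_D,
            sim_factory=self._factory(), refine=refine,
            obs_values=self.values)
        return GerminationResults(model=self, calib=res)


@dataclass
class GerminationResults:
    model: GerminationModel
    calib: CalibResult

    @property
    def u_G(self) -> float:
        return self.calib.u_hat

    @property
    def D_G(self) -> float:
        return self.calib.D_hat

    @property
    def r2(self) -> float:
        return self.calib.r2

    @property
    def params(self) -> pd.Series:
        return pd.Series({"u_G": self.u_G, "D_G": self.D_G})

    def predict(self, days) -> np.ndarray:
        """Fitted cumulative emergence (percent) at the given days."""
        days = np.asarray(days, dtype=float)
        return 100.0 * self.model.viable_frac * analytic.emerged_fraction(
            days, self.u_G, self.D_G, self.model.L0, self.model.with_correction)

    def emergence_time(self, q: float = 0.5) -> float:
        """Day on which fraction ``q`` of viable seeds has emerged."""
        return analytic.germination_time_quantile(
            q, self.u_G, self.D_G, self.model.L0, self.model.with_correction)

    def summary(self) -> str:
        peclet = self.u_G * self.model.L0 / self.D_G
        lines = [
            "Germination stage calibration (grid search, R^2)",
            "=" * 48,
            f"observations        {len(self.model.days):>10d}",
            f"u_G  [units/day]    {self.u_G:>10.4f}",
            f"D_G  [units^2/day]  {self.D_G:>10.5f}",
            f"Peclet u*L0/D       {peclet:>10.1f}",
            f"R^2                 {self.r2:>10.4f}",
            f"median emergence    {self.emergence_time(0.5):>10.2f} days",
            f"refined             {str(self.calib.refined):>10}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.days, self.model.values, "o", label="observed")
        t = np.linspace(0, float(self.model.days.max()), 200)
        ax.plot(t, self.predict(t), "-", label="fitted")
        ax.set_xlabel("days after sowing")
        ax.set_ylabel("emerged (%)")
        ax.legend()
        return ax


class TilleringModel:
    """Grid-search calibration of the tillering stage with the germination
    parameters frozen.

    ``scale`` converts the per-seed-lot tiller curve into observed units:
    for counts on a 1 m row section it is the number of viable seeds in that
    section.  ``gamma`` is the tiller potential per emerged seedling,
    normally estimated from the final counts
    (:func:`germflow.calibrate.estimate_gamma`).
    """

    def __init__(self, obs, u_G: float, D_G: float, gamma: float,
                 scale: float = 100.0, grid_u=None, grid_D=None,
                 L0: float = 1.0, L1: float = 2.0, with_correction: bool = True):
        if isinstance(obs, ObservationSeries):
            obs = [obs]
        self.obs = obs
        self.days, self.values = _pool(obs, "tillers_per_m")
        self.u_G, self.D_G, self.gamma = float(u_G), float(D_G), float(gamma)
        self.scale = float(scale)
        self.grid_u = grid_u
        self.grid_D = grid_D
        self.L0, self.L1 = L0, L1
        self.with_correction = with_correction

    def _factory(self):
        return calibrate.tiller_sim_factory(
            self.days, self.u_G, self.D_G, self.gamma, scale=self.scale,
            L0=self.L0, L1=self.L1, with_correction=self.with_correction)

    def fit(self, refine: bool = True) -> "TilleringResults":
        res = calibrate.calibrate_stage(
            self.days, grid_u=self.grid_u, grid_D=self.grid_D,
            sim_factory=self._factory(), refine=refine, obs_values=self.values)
        return TilleringResults(model=self, calib=res)


@dataclass
class TilleringResults:
    model: TilleringModel
    calib: CalibResult

    @property
    def u_T(self) -> float:
        return self.calib.u_hat

    @property
    def D_T(self) -> float:
        return self.calib.D_hat

    @property
    def r2(self) -> float:
        return self.calib.r2

    def predict(self, days) -> np.ndarray:
        fac = calibrate.tiller_sim_factory(
            np.asarray(days, dtype=float), self.model.u_G, self.model.D_G,
            self.model.gamma, scale=self.model.scale, L0=self.model.L0,
            L1=self.model.L1, with_correction=self.model.with_correction)
        return fac(self.u_T, self.D_T)

    def summary(self) -> str:
        lines = [
            "Tillering stage calibration (grid search, R^2)",
            "=" * 48,
            f"observations        {len(self.model.days):>10d}",
            f"u_T  [units/day]    {self.u_T:>10.4f}",
            f"D_T  [units^2/day]  {self.D_T:>10.5f}",
            f"gamma (fixed)       {self.model.gamma:>10.2f}",
            f"R^2                 {self.r2:>10.4f}",
        ]
        return "\n".join(lines)


class StudyModel:
    """Sequential two-stage calibration of a whole factorial study.

    Built from per-treatment pooled observations.  Germination is calibrated
    first for every treatment; gamma is then estimated from the final counts
    and the tillering stage calibrated with the germination parameters
    frozen.  Treatments without tiller observations get a germination-only
    row.
    """

    def __init__(self, treatments: dict, n_seeds_per_plot: int = 100,
                 grid_u=None, grid_D=None, grid_u_till=None, grid_D_till=None,
                 global_gamma: bool = False):
        """``treatments`` maps treatment_id -> dict with keys
        ``emergence_obs`` (list of ObservationSeries) and optionally
        ``tiller_obs`` (list of ObservationSeries)."""
        if not treatments:
            raise ValueError("no treatments")
        self.treatments = treatments
        self.n_seeds = n_seeds_per_plot
        self.grid_u, self.grid_D = grid_u, grid_D
        self.grid_u_till, self.grid_D_till = grid_u_till, grid_D_till
        self.global_gamma = global_gamma

    @classmethod
    def from_bundle(cls, bundle, **kwargs):
        treatments = {
            tr.treatment_id: {"emergence_obs": tr.emergence_obs,
                              "tiller_obs": tr.tiller_obs}
            for tr in bundle.treatments if tr.emergence_obs}
        kwargs.setdefault("n_seeds_per_plot", bundle.design.n_seeds_per_plot)
        return cls(treatments, **kwargs)

    def fit(self, refine: bool = True) -> "StudyResults":
        # viable-seed normalisation across treatments
        ids = list(self.treatments)
        finals = []
        for tid in ids:
            _, vals = _pool(self.treatments[tid]["emergence_obs"], "emerged_pct")
            days, _ = _pool(self.treatments[tid]["emergence_obs"], "emerged_pct")
            last_day = days.max()
            finals.append(float(np.mean(vals[days == last_day])) / 100.0 * self.n_seeds)
        viable = calibrate.normalize_viable(finals)

        rows, germ_results, till_results = [], {}, {}
        gammas = {}
        for tid, frac, final_emerged in zip(ids, viable, finals):
            germ = GerminationModel(self.treatments[tid]["emergence_obs"],
                                    viable_frac=frac, grid_u=self.grid_u,
                                    grid_D=self.grid_D).fit(refine=refine)
            germ_results[tid] = germ
            till_obs = self.treatments[tid].get("tiller_obs") or []
            has_tillers = any(o.tillers_per_m is not None for o in till_obs)
            if has_tillers:
                _, tvals = _pool(till_obs, "tillers_per_m")
                tdays, _ = _pool(till_obs, "tillers_per_m")
                final_tillers = float(np.mean(tvals[tdays == tdays.max()]))
                gammas[tid] = calibrate.estimate_gamma(final_tillers, final_emerged)
        if self.global_gamma and gammas:
            g_all = float(np.mean(list(gammas.values())))
            gammas = {tid: g_all for tid in gammas}

        for tid, frac in zip(ids, viable):
            germ = germ_results[tid]
            row = {"treatment_id": tid, "viable_frac": frac,
                   "u_G": germ.u_G, "D_G": germ.D_G, "r2_germ": germ.r2,
                   "u_T": np.nan, "D_T": np.nan, "r2_till": np.nan,
                   "gamma": np.nan}
            if tid in gammas:
                till = TilleringModel(
                    self.treatments[tid]["tiller_obs"], u_G=germ.u_G,
                    D_G=germ.D_G, gamma=gammas[tid],
                    scale=frac * self.n_seeds, grid_u=self.grid_u_till,
                    grid_D=self.grid_D_till).fit(refine=refine)
                till_results[tid] = till
                row.update({"u_T": till.u_T, "D_T": till.D_T,
                            "r2_till": till.r2, "gamma": gammas[tid]})
            rows.append(row)
        return StudyResults(model=self, table=pd.DataFrame(rows),
                            germination=germ_results, tillering=till_results)


@dataclass
class StudyResults:
    model: StudyModel
    table: pd.DataFrame
    germination: dict = field(default_factory=dict)
    tillering: dict = field(default_factory=dict)

    def summary(self) -> str:
        cols = ["treatment_id", "u_G", "D_G", "r2_germ", "u_T", "D_T",
                "r2_till", "gamma"]
        return ("Study calibration (sequential two-stage grid search)\n"
                + "=" * 56 + "\n"
                + self.table[cols].to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


class EnvResponseModel:
    """Temperature x moisture germination-speed response fitted to
    per-treatment calibrated speeds; see
    :func:`germflow.environment.fit_env41`."""

    def __init__(self, points, init: Env41Params | None = None,
                 free_all: bool = False):
        self.points = [(float(T), float(th), float(u)) for T, th, u in points]
        self.init = init
        self.free_all = free_all

    @classmethod
    def from_study(cls, study_results: StudyResults, env_means: dict, **kwargs):
        """``env_means`` maps treatment_id -> (T_bar, theta_bar)."""
        pts = [(env_means[tid][0], env_means[tid][1], u)
               for tid, u in zip(study_results.table["treatment_id"],
                                 study_results.table["u_G"])]
        return cls(pts, **kwargs)

    def fit(self) -> "EnvResponseResults":
        params, rss = environment.fit_env41(self.points, init=self.init,
                                            free_all=self.free_all)
        return EnvResponseResults(model=self, params=params, rss=rss)


@dataclass
class EnvResponseResults:
    model: EnvResponseModel
    params: Env41Params
    rss: float

    def predict(self, T, theta):
        return environment.germination_speed(T, theta, self.params)

    @property
    def r2(self) -> float:
        u = np.array([p[2] for p in self.model.points])
        return calibrate.r_squared(u, self.predict(
            np.array([p[0] for p in self.model.points]),
            np.array([p[1] for p in self.model.points])))

    def summary(self) -> str:
        p = self.params
        fitted = "a T0 b beta theta0 thetar" if self.model.free_all else "a T0 b beta"
        lines = [
            "Environmental germination-speed response",
            "=" * 48,
            f"points              {len(self.model.points):>10d}",
            f"fitted parameters   {fitted:>22}",
            f"a      [1/day/degC] {p.a:>10.4f}",
            f"T0     [degC]       {p.T0:>10.2f}",
            f"b      [1/day/degC^2]{p.b:>9.4f}",
            f"beta                {p.beta:>10.3f}",
            f"theta0 [frac FC]    {p.theta0:>10.3f}",
            f"thetar [frac FC]    {p.thetar:>10.3f}",
            f"RSS                 {self.rss:>10.3e}",
            f"R^2                 {self.r2:>10.4f}",
        ]
        return "\n".join(lines)


class HydrotimeModel:
    """Hydrotime model with Weibull base water potential, fitted jointly
    across germination curves at several water potentials; see
    :func:`germflow.hydrotime.fit_htt`."""

    def __init__(self, curves):
        self.curves = curves

    def fit(self) -> "HydrotimeResults":
        params, r2 = hydrotime.fit_htt(self.curves)
        return HydrotimeResults(model=self, params=params, r2=r2)


@dataclass
class HydrotimeResults:
    model: HydrotimeModel
    params: HydrotimeParams
    r2: float

    def predict(self, t, psi):
        return hydrotime.htt_fraction(t, psi, self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Hydrotime model (Weibull base water potential)",
            "=" * 48,
            f"theta_H [MPa day]   {p.thetaH:>10.3f}",
            f"psi_b shape         {p.wb_shape:>10.3f}",
            f"psi_b scale [MPa]   {p.wb_scale:>10.3f}",
            f"psi_b location [MPa]{p.wb_location:>10.3f}",
            f"R^2                 {self.r2:>10.4f}",
        ]
        return "\n".join(lines)
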
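"""CSV/YAML readers and writers for the toolkit's file formats.

Schemas
-------
observations : columns ``day``, optional ``emerged_pct``, optional
    ``tillers_per_m``.  Percentages are validated to [0, 100].
drivers : columns ``datetime`` (ISO-8601), ``air_temp_C``, ``swc_frac_fc``.
    Soil water content is a fraction of field capacity; a series whose
    values exceed 1.2 is taken to be in percent of field capacity and is
    divided by 100 (with a logged notice).
trajectory : columns ``t_days``, ``emerged_pct``, ``tillers``.
parameters table : columns ``treatment_id``, ``u_G``, ``D_G``, ``r2_germ``,
    ``u_T``, ``D_T``, ``r2_till``, ``gamma``.
hydrotime curves : columns ``psi_MPa``, ``day``, ``fraction``.
config : YAML mapping; see :class:`RunConfig`.

All floats are written with 10 significant digits so write-then-read
round-trips are lossless at that precision.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import Env41Params, ObservationSeries, TreatmentEnv

__all__ = [
    "RunConfig", "read_config", "write_config",
    "read_observations", "write_observations",
    "read_drivers", "write_drivers",
    "read_trajectory", "write_trajectory",
    "read_params_table", "write_params_table",
    "read_env41", "write_env41",
    "read_hydrotime_curves", "write_hydrotime_curves",
    "write_bundle", "read_bundle",
]

log = logging.getLogger("germflow")
_FLOAT_FMT = "%.10g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------- observations

def write_observations(obs: ObservationSeries, path) -> None:
    data = {"day": obs.days}
    if obs.emerged_pct is not None:
        data["emerged_pct"] = obs.emerged_pct
    if obs.tillers_per_m is not None:
        data["tillers_per_m"] = obs.tillers_per_m
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_observations(path) -> ObservationSeries:
    df = pd.read_csv(path)
    _require_columns(df, ["day"], path)
    if "emerged_pct" not in df.columns and "tillers_per_m" not in df.columns:
        raise ValueError(f"{path}: need emerged_pct and/or tillers_per_m column")
    kw = {}
    if "emerged_pct" in df.columns:
        pct = df["emerged_pct"].to_numpy(dtype=float)
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError(f"{path}: emerged_pct outside [0, 100]")
        kw["emerged_pct"] = pct
    if "tillers_per_m" in df.columns:
        kw["tillers_per_m"] = df["tillers_per_m"].to_numpy(dtype=float)
    return ObservationSeries(days=df["day"].to_numpy(dtype=float), **kw)


# -------------------------------------------------------------------- drivers

def write_drivers(env: TreatmentEnv, path) -> None:
    df = pd.DataFrame({"datetime": env.temps.index,
                       "air_temp_C": env.temps.to_numpy(),
                       "swc_frac_fc": env.swc.to_numpy()})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_drivers(path, sowing_date: _dt.date | None = None) -> TreatmentEnv:
    df = pd.read_csv(path, parse_dates=["datetime"])
    _require_columns(df, ["datetime", "air_temp_C", "swc_frac_fc"], path)
    swc = df["swc_frac_fc"].to_numpy(dtype=float)
    if np.nanmax(swc) > 1.2:
        log.info("%s: swc_frac_fc exceeds 1.2; interpreting as percent of "
                 "field capacity and dividing by 100", path)
        swc = swc / 100.0
    idx = pd.DatetimeIndex(df["datetime"])
    if sowing_date is None:
        sowing_date = idx[0].date()
    return TreatmentEnv(sowing_date=sowing_date,
                        temps=pd.Series(df["air_temp_C"].to_numpy(dtype=float), index=idx),
                        swc=pd.Series(swc, index=idx))


# ----------------------------------------------------------------- trajectory

def write_trajectory(traj, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["t_days", "emerged_pct"], path)
    return df


# ----------------------------------------------------------- parameter tables

_PARAM_COLS = ["treatment_id", "u_G", "D_G", "r2_germ", "u_T", "D_T",
               "r2_till", "gamma"]


def write_params_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in _PARAM_COLS if c in df.columns] + \
        [c for c in df.columns if c not in _PARAM_COLS]
    df[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_params_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["treatment_id", "u_G", "D_G"], path)
    return df


# -------------------------------------------------------------- Env41 / config

def write_env41(p: Env41Params, path) -> None:
    doc = {k: float(v) for k, v in asdict(p).items()}
    with open(path, "w") as fh:
        yaml.safe_dump({"env41": doc}, fh, sort_keys=False)


def read_env41(path) -> Env41Params:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "env41" not in doc:
        raise ValueError(f"{path}: expected a mapping with an 'env41' block")
    return Env41Params(**doc["env41"])


@dataclass
class RunConfig:
    """Structured run configuration (YAML).  Command-line flags override
    config values, which override these defaults."""

    L0: float = 1.0
    L1: float = 2.0
    dx: float = 0.01
    t_end: float = 60.0
    record_every: float = 1.0
    u_G: float | None = None
    D_G: float | None = None
    u_T: float | None = None
    D_T: float | None = None
    gamma: float = 4.0
    n_seeds: int = 100
    seed: int = 0
    grid_u: list | None = None
    grid_D: list | None = None
    env41: dict | None = None
    dispersion: dict = field(default_factory=lambda: {"form": "power",
                                                      "coeffs": [0.05, 1.0]})
    outdir: str = "."

    @classmethod
    def fields(cls):
        import dataclasses
        return {f.name for f in dataclasses.fields(cls)}


def read_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(doc) - RunConfig.fields()
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**doc)


def write_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


# -------------------------------------------------------------------- hydrotime

def write_hydrotime_curves(curves, path) -> None:
    """``curves``: mapping psi -> (days, fractions)."""
    rows = []
    for psi, (days, fracs) in curves.items():
        for d, f in zip(days, fracs):
            rows.append({"psi_MPa": psi, "day": d, "fraction": f})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_hydrotime_curves(path) -> dict:
    df = pd.read_csv(path)
    _require_columns(df, ["psi_MPa", "day", "fraction"], path)
    if np.any((df["fraction"] < 0) | (df["fraction"] > 1)):
        raise ValueError(f"{path}: fraction outside [0, 1]")
    out = {}
    for psi, grp in df.groupby("psi_MPa"):
        out[float(psi)] = (grp["day"].to_numpy(dtype=float),
                           grp["fraction"].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------- study bundle

def write_bundle(bundle, outdir) -> None:
    """Write a synthetic study to a directory of CSVs: per-treatment driver
    series, per-plot observation series, and a truth.csv with the generating
    parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for tr in bundle.treatments:
        write_drivers(tr.env, outdir / f"env_{tr.treatment_id}.csv")
        for i, obs in enumerate(tr.emergence_obs):
            write_observations(obs, outdir / f"obs_{tr.treatment_id}_rep{i}.csv")
        for i, obs in enumerate(tr.tiller_obs):
            write_observations(obs, outdir / f"tillers_{tr.treatment_id}_rep{i}.csv")
        truth_rows.append({"treatment_id": tr.treatment_id,
                           "sowing_date": tr.sowing_date.isoformat(),
                           "moisture_level": tr.moisture_level, **tr.truth})
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False,
                                    float_format=_FLOAT_FMT)


def read_bundle(indir) -> dict:
    """Read a study bundle directory back into plain structures:
    ``{"truth": DataFrame, "treatments": {tid: {"env": TreatmentEnv,
    "emergence_obs": [...], "tiller_obs": [...]}}}``."""
    indir = Path(indir)
    truth = pd.read_csv(indir / "truth.csv")
    treatments = {}
    for tid, sow in zip(truth["treatment_id"], truth["sowing_date"]):
        sowing = _dt.date.fromisoformat(str(sow))
        env = read_drivers(indir / f"env_{tid}.csv", sowing_date=sowing)
        em = sorted(indir.glob(f"obs_{tid}_rep*.csv"))
        ti = sorted(indir.glob(f"tillers_{tid}_rep*.csv"))
        treatments[str(tid)] = {
            "env": env,
            "emergence_obs": [read_observations(p) for p in em],
            "tiller_obs": [read_observations(p) for p in ti],
        }
    return {"truth": truth, "treatments": treatments}
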
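"""Readers, writers, run configuration and the end-to-end pipeline.

NetCDF I/O uses xarray's scipy (NetCDF-3) backend; the 365-day calendar is
carried as an integer day index with ``year``/``doy`` coordinates. Files
written by :func:`write_climate_netcdf` round-trip bit-identically through
:func:`read_climate_netcdf`. Real-data files with a datetime axis have 29
Feb dropped on load so that every year is exactly 365 days.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import demand, synthetic, trends
from .season import DAYS_PER_YEAR, DEFINITIONS, PointSeasons
from .synthetic import GeneratorConfig, MetCycle

__all__ = [
    "RunConfig",
    "read_climate_netcdf",
    "write_climate_netcdf",
    "write_point_csv",
    "run_pipeline",
]

log = logging.getLogger("dryseason")

SECONDS_PER_DAY = 86400.0
W_M2_TO_MJ = 0.0864  # W m-2 -> MJ m-2 d-1

SEASON_COLUMNS = ["lat", "lon", "member", "definition", "season_index", "year",
                  "dsa", "dse", "dsl", "wd"]
TREND_COLUMNS = ["lat", "lon", "member", "definition", "season_index", "diagnostic",
                 "slope_per_decade", "p_ols", "mk_s", "p_mk", "n"]
CONSISTENCY_COLUMNS = ["lat", "lon", "definition", "season_index", "diagnostic",
                       "category", "n_sig_pos", "n_sig_neg", "n_nonsig", "excluded"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (synthetic or file-based input)."""

    generator: GeneratorConfig | None = None
    input_path: str | None = None
    var_map: dict = field(default_factory=dict)
    definitions: tuple = DEFINITIONS
    ensemble_seeds: tuple = (0,)
    lats: tuple = (0.0,)
    lons: tuple = (0.0,)
    regions: dict = field(default_factory=dict)  # name -> (south, north, west, east)
    output_dir: str = "results"
    seed: int = 0
    max_missing_frac: float = 0.1
    run_attribution: bool = True
    noise_member_cv: float = 0.0  # extra member-to-member rainfall perturbation

    def __post_init__(self):
        if not self.definitions:
            raise ValueError("at least one dry-season definition must be selected")
        for d in self.definitions:
            if d not in DEFINITIONS:
                raise ValueError(f"unknown definition {d!r}")
        for name, (s, n, w, e) in self.regions.items():
            if not s < n:
                raise ValueError(f"region {name}: require south < north")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        if gen is not None:
            met = gen.pop("met_cycles", None)
            if met is not None:
                gen["met_cycles"] = {k: MetCycle(**v) for k, v in met.items()}
            gen = GeneratorConfig(**gen)
        for key in ("definitions", "ensemble_seeds", "lats", "lons"):
            if key in raw:
                raw[key] = tuple(raw[key])
        regions = {k: tuple(v) for k, v in raw.pop("regions", {}).items()}
        return cls(generator=gen, regions=regions, **raw)

    def hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {"__type__": type(o).__name__, **o.__dict__}
            return str(o)
        blob = json.dumps(self.__dict__, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_climate_netcdf(ds: xr.Dataset, path) -> Path:
    """Write a daily climate dataset as NetCDF-3 (scipy backend)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    enc = ds.copy()
    for c in ("time", "year", "doy"):
        if c in enc.coords:
            enc[c] = enc[c].astype(np.int32)
    enc.to_netcdf(path, engine="scipy")
    return path


def _drop_feb29(ds: xr.Dataset) -> xr.Dataset:
    t = ds["time"]
    if np.issubdtype(t.dtype, np.integer):
        return ds
    tt = pd.DatetimeIndex(t.values)
    keep = ~((tt.month == 2) & (tt.day == 29))
    ds = ds.isel(time=keep)
    tt = tt[keep]
    n = tt.size
    if n % DAYS_PER_YEAR:
        raise ValueError("record does not cover whole years after dropping 29 Feb")
    day = np.arange(n, dtype=np.int32)
    ds = ds.assign_coords(time=("time", day),
                          year=("time", tt.year.values.astype(np.int32)),
                          doy=("time", (day % DAYS_PER_YEAR + 1).astype(np.int32)))
    ds.attrs.setdefault("start_year", int(tt.year[0]))
    ds.attrs.setdefault("calendar", "365_day")
    return ds


def read_climate_netcdf(path, var_map: dict | None = None) -> xr.Dataset:
    """Load a daily climate file, normalizing names, units and calendar.

    ``var_map`` maps file variable names to the canonical P, T, RH, u2, Rn,
    E, p_surf. Unit handling: precipitation flux (kg m-2 s-1) -> mm d-1,
    radiation W m-2 -> MJ m-2 d-1, wind with a ``height`` attribute scaled to
    2 m via the FAO-56 profile, fractional RH -> percent.
    """
    path = Path(path)
    try:
        ds = xr.open_dataset(path, engine="scipy").load()
    except Exception:
        ds = xr.open_dataset(path).load()
    if var_map:
        missing = [v for v in var_map if v not in ds]
        if missing:
            raise ValueError(f"missing variables in {path.name}: {missing}")
        ds = ds.rename(var_map)
    for dim in ("time", "lat", "lon"):
        if dim not in ds.dims:
            raise ValueError(f"input file must have a {dim!r} dimension")
    ds = _drop_feb29(ds)

    if "P" in ds:
        units = str(ds["P"].attrs.get("units", "mm d-1")).lower()
        if "kg" in units and "s-1" in units.replace("/s", "s-1"):
            ds["P"] = ds["P"] * SECONDS_PER_DAY
            ds["P"].attrs["units"] = "mm d-1"
    if "Rn" in ds:
        units = str(ds["Rn"].attrs.get("units", "")).replace("/", " ").lower()
        if units.startswith("w"):
            ds["Rn"] = ds["Rn"] * W_M2_TO_MJ
            ds["Rn"].attrs["units"] = "MJ m-2 d-1"
    if "RH" in ds:
        if str(ds["RH"].attrs.get("units", "%")) in ("1", "fraction"):
            ds["RH"] = ds["RH"] * 100.0
            ds["RH"].attrs["units"] = "%"
    if "u2" in ds:
        h = ds["u2"].attrs.get("height", 2.0)
        if float(h) != 2.0:
            ds["u2"] = xr.DataArray(demand.wind_to_2m(ds["u2"].values, float(h)),
                                    dims=ds["u2"].dims)
            ds["u2"].attrs["height"] = 2.0
    return ds


def write_point_csv(df: pd.DataFrame, path) -> Path:
    """Write a long-format table with a stable float format (determinism)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def _validate_schema(df: pd.DataFrame, columns, name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns {missing}")
    return df[list(columns)]


def _prepare_member(cfg: RunConfig, seed: int) -> xr.Dataset:
    if cfg.input_path is not None:
        grid = read_climate_netcdf(cfg.input_path, cfg.var_map)
    else:
        gen = cfg.generator or GeneratorConfig()
        gen = GeneratorConfig(**{**gen.__dict__, "seed": int(seed)})
        grid = synthetic.generate_daily_climate(gen, cfg.lats, cfg.lons)
    needs_demand = any(d != "P_lt_Pbar" for d in cfg.definitions) or cfg.run_attribution
    if needs_demand and "Ep" not in grid and all(v in grid for v in ("T", "RH", "u2", "Rn")):
        grid = demand.add_ep(grid)
    if "P_lt_E" in cfg.definitions and "E" not in grid and "Ep" in grid:
        gen = cfg.generator or GeneratorConfig()
        grid = synthetic.add_bucket_e(grid, w_max=gen.w_max, w0=gen.w0, ei=gen.ei)
    for d in cfg.definitions:
        if d == "P_lt_Ep" and "Ep" not in grid:
            raise ValueError("definition P_lt_Ep requested but Ep is unavailable")
        if d == "P_lt_E" and "E" not in grid:
            raise ValueError("definition P_lt_E requested but E is unavailable")
    return grid


def _missing_year_mask(p: np.ndarray, max_frac: float) -> np.ndarray:
    frac = np.isnan(p).reshape(-1, DAYS_PER_YEAR).mean(axis=1)
    return frac > max_frac


def _detect_member(cfg: RunConfig, grid: xr.Dataset, member: int):
    start_year = int(grid.attrs.get("start_year", 1983))
    season_rows, clim_rows = [], []
    for i, lat in enumerate(np.atleast_1d(grid["lat"].values)):
        for j, lon in enumerate(np.atleast_1d(grid["lon"].values)):
            p = grid["P"].values[:, i, j]
            bad_years = _missing_year_mask(p, cfg.max_missing_frac)
            if np.isnan(p).any():
                doy = np.arange(p.size) % DAYS_PER_YEAR
                clim_fill = np.nanmean(p.reshape(-1, DAYS_PER_YEAR), axis=0)
                p = np.where(np.isnan(p), clim_fill[doy], p)
            ep = grid["Ep"].values[:, i, j] if "Ep" in grid else None
            e = grid["E"].values[:, i, j] if "E" in grid else None
            ps = PointSeasons(p, ep, e, start_year=start_year)
            for d in cfg.definitions:
                cl = ps.climatological(d)
                for st in cl:
                    clim_rows.append({"lat": lat, "lon": lon, "member": member,
                                      "definition": d, "season_index": st.season_index,
                                      "modality": ps.modality,
                                      "ratio": ps.clim.seasonality.ratio,
                                      "dsa": st.dsa, "dse": st.dse,
                                      "dsl": st.dsl, "wd": st.wd})
                if not cl:
                    clim_rows.append({"lat": lat, "lon": lon, "member": member,
                                      "definition": d, "season_index": 0,
                                      "modality": ps.modality,
                                      "ratio": ps.clim.seasonality.ratio,
                                      "dsa": np.nan, "dse": np.nan,
                                      "dsl": np.nan, "wd": np.nan})
                for st in ps.annual(d):
                    iy = int(st.year) - start_year
                    if bad_years[iy]:
                        continue
                    season_rows.append({"lat": lat, "lon": lon, "member": member,
                                        "definition": d, "season_index": st.season_index,
                                        "year": st.year, "dsa": st.dsa, "dse": st.dse,
                                        "dsl": st.dsl, "wd": st.wd})
    return pd.DataFrame(clim_rows), pd.DataFrame(season_rows, columns=SEASON_COLUMNS)


def _trend_table(seasons: pd.DataFrame) -> pd.DataFrame:
    rows = []
    keys = ["lat", "lon", "member", "definition", "season_index"]
    for key, grp in seasons.groupby(keys, sort=True):
        grp = grp.sort_values("year")
        for diag in ("dsl", "dsa", "dse", "wd"):
            y = grp[diag].values.astype(float)
            if y.size < 4:
                continue
            tr = trends.trend(y)
            rows.append(dict(zip(keys, key)) | {
                "diagnostic": diag, "slope_per_decade": tr.slope_per_decade,
                "p_ols": tr.p_ols, "mk_s": tr.mk_s, "p_mk": tr.p_mk, "n": tr.n})
    return pd.DataFrame(rows, columns=TREND_COLUMNS)


def _consistency_table(trend_df: pd.DataFrame, clim_df: pd.DataFrame) -> pd.DataFrame:
    excluded_keys = set()
    for _, r in clim_df[clim_df["season_index"] == 0].iterrows():
        excluded_keys.add((r["lat"], r["lon"], r["definition"]))
    rows = []
    keys = ["lat", "lon", "definition", "season_index", "diagnostic"]
    for key, grp in trend_df.groupby(keys, sort=True):
        label = trends.consistency_classify(
            [(np.sign(s), p < trends.ALPHA)
             for s, p in zip(grp["slope_per_decade"], grp["p_ols"])])
        rows.append(dict(zip(keys, key)) | {
            "category": label.category, "n_sig_pos": label.n_sig_pos,
            "n_sig_neg": label.n_sig_neg, "n_nonsig": label.n_nonsig,
            "excluded": (key[0], key[1], key[2]) in excluded_keys})
    return pd.DataFrame(rows, columns=CONSISTENCY_COLUMNS)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run climatology -> modality -> seasons -> trends -> consistency (-> attribution).

    Returns the output tables and writes them (plus a machine-readable run
    manifest) under ``cfg.output_dir``. Deterministic given config + seed.
    """
    t0 = _time.time()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}

    clim_parts, season_parts = [], []
    grids = {}
    for member, seed in enumerate(cfg.ensemble_seeds):
        grid = _prepare_member(cfg, int(cfg.seed) + int(seed))
        grids[member] = grid
        cl, se = _detect_member(cfg, grid, member)
        clim_parts.append(cl)
        season_parts.append(se)
        log.info("member %d: %d point-year seasons", member, len(se))
    clim_df = pd.concat(clim_parts, ignore_index=True)
    seasons = pd.concat(season_parts, ignore_index=True)
    timings["detect_s"] = round(_time.time() - t0, 3)

    trend_df = _trend_table(seasons)
    cons_df = _consistency_table(trend_df, clim_df)
    timings["trend_s"] = round(_time.time() - t0 - timings["detect_s"], 3)

    outputs = {"climatology": clim_df, "seasons": seasons,
               "trends": trend_df, "consistency": cons_df}

    if cfg.run_attribution:
        from . import attribution as attrib
        grid = grids[0]
        if all(v in grid for v in attrib.DRIVERS):
            lat = np.atleast_1d(grid["lat"].values)
            w = np.cos(np.deg2rad(lat))
            met = {v: np.tensordot(
                       grid[v].values.mean(axis=2), w / w.sum(), axes=([1], [0]))
                   for v in attrib.DRIVERS}
            res = attrib.attribute_ep_trend(met)
            att_rows = [{"driver": d, "slope_per_decade": tr.slope_per_decade,
                         "p_ols": tr.p_ols}
                        for d, tr in res.contribution_trends.items()]
            att_rows.append({"driver": "Ep_all",
                             "slope_per_decade": res.ep_trend.slope_per_decade,
                             "p_ols": res.ep_trend.p_ols})
            att_rows.append({"driver": "residual",
                             "slope_per_decade": 10.0 * res.residual_trend,
                             "p_ols": np.nan})
            outputs["attribution"] = pd.DataFrame(att_rows)

    write_point_csv(_validate_schema(seasons, SEASON_COLUMNS, "seasons"),
                    out_dir / "seasons.csv")
    write_point_csv(_validate_schema(trend_df, TREND_COLUMNS, "trends"),
                    out_dir / "trends.csv")
    write_point_csv(_validate_schema(cons_df, CONSISTENCY_COLUMNS, "consistency"),
                    out_dir / "consistency.csv")
    write_point_csv(clim_df, out_dir / "climatology.csv")
    if "attribution" in outputs:
        write_point_csv(outputs["attribution"], out_dir / "attribution.csv")

    manifest = {"config_hash": cfg.hash(), "n_members": len(cfg.ensemble_seeds),
                "definitions": list(cfg.definitions),
                "timings": timings | {"total_s": round(_time.time() - t0, 3)},
                "package": "dryseason 0.1.0"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    outputs["manifest"] = manifest
    return outputs
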
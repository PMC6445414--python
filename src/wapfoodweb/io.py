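"""CSV/TOML loading, validation and result writing.

All tabular interfaces are headered UTF-8 CSV; dates are ``YYYY-MM``; unknown
values are empty cells.  Loaders aggregate every validation problem into a
single :class:`InputError` so a malformed file is reported in one pass.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import FitReport, MCResult, ObservationSet
from .ecopath import DietMatrix, EcopathResults, GroupSpec, Stanza, StanzaSet
from .ecosim import ForcingApplication, Scenario, SimResult
from .forcing import MonthlyTimeSeries, ResponseCurve

__all__ = [
    "InputError",
    "load_groups",
    "load_diet",
    "load_stanzas",
    "load_timeseries",
    "load_observations",
    "load_scenario",
    "write_balanced",
    "write_trajectories",
    "read_trajectories",
    "write_fit_report",
    "write_mc",
    "write_manifest",
]


class InputError(ValueError):
    """Aggregated schema violations for one input file."""

    def __init__(self, path, problems: list[str]) -> None:
        self.problems = problems
        msg = f"{path}: {len(problems)} problem(s)\n" + "\n".join(f"  - {p}" for p in problems)
        super().__init__(msg)


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise InputError(path, ["no rows"])
    missing = required - set(df.columns)
    if missing:
        raise InputError(path, [f"missing columns: {sorted(missing)}"])
    return df


def load_groups(path) -> list[GroupSpec]:
    df = _read_csv(path, {"name", "role", "biomass", "pb", "ee"})
    problems, out = [], []
    for _, row in df.iterrows():
        kw = {
            k: row.get(k)
            for k in ("name", "role", "biomass", "pb", "qb", "pq", "ee", "ba_rate",
                      "landings", "unassim")
            if k in df.columns
        }
        for k in ("ba_rate", "landings"):
            if k in kw and (kw[k] is None or (isinstance(kw[k], float) and np.isnan(kw[k]))):
                kw[k] = 0.0
        if "unassim" in kw and isinstance(kw["unassim"], float) and np.isnan(kw["unassim"]):
            kw["unassim"] = None
        try:
            out.append(GroupSpec(**kw))
        except (ValueError, TypeError) as exc:
            problems.append(str(exc))
    if problems:
        raise InputError(path, problems)
    return out


def load_diet(path) -> DietMatrix:
    df = _read_csv(path, {"predator", "prey", "fraction"})
    if "trace" not in df.columns:
        df["trace"] = 0
    try:
        return DietMatrix.from_frame(df)
    except ValueError as exc:
        raise InputError(path, [str(exc)]) from exc


def load_stanzas(path) -> list[StanzaSet]:
    df = _read_csv(path, {"species", "group", "start_age_months", "z", "vbk", "leading"})
    problems, out = [], []
    for species, sub in df.groupby("species", sort=False):
        sub = sub.sort_values("start_age_months")
        stanzas = [
            Stanza(str(r.group), int(r.start_age_months), float(r.z))
            for r in sub.itertuples()
        ]
        leading = np.flatnonzero(sub["leading"].to_numpy())
        if len(leading) != 1:
            problems.append(f"{species}: exactly one leading stanza required")
            continue
        try:
            out.append(StanzaSet(str(species), stanzas, float(sub["vbk"].iloc[0]), int(leading[0])))
        except ValueError as exc:
            problems.append(str(exc))
    if problems:
        raise InputError(path, problems)
    return out


def load_timeseries(path) -> dict[str, MonthlyTimeSeries]:
    """Long-format series file: date (YYYY-MM), series_id, value, units."""
    df = _read_csv(path, {"date", "series_id", "value"})
    out = {}
    for sid, sub in df.groupby("series_id"):
        ser = pd.Series(
            sub["value"].to_numpy(dtype=float),
            index=pd.PeriodIndex(sub["date"], freq="M"),
        ).sort_index()
        units = str(sub["units"].iloc[0]) if "units" in sub.columns else ""
        out[str(sid)] = MonthlyTimeSeries(ser, units)
    return out


def write_timeseries(series: dict[str, MonthlyTimeSeries], path) -> None:
    rows = []
    for sid, ts in series.items():
        for p, v in ts.values.items():
            rows.append({"date": str(p), "series_id": sid, "value": v, "units": ts.units})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def load_observations(path) -> ObservationSet:
    df = _read_csv(path, {"time", "group", "value"})
    return ObservationSet(df)


def write_observations(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


def _curve_from_dict(d: dict) -> ResponseCurve:
    return ResponseCurve(
        shape=d["shape"],
        params={k: v for k, v in d.items() if k not in ("shape", "domain", "baseline_x")},
        domain=tuple(d.get("domain", (0.0, 2.0))),
        baseline_x=float(d.get("baseline_x", 1.0)),
    )


def load_scenario(path) -> Scenario:
    """Scenario config (TOML): horizon, series file, effort, applications."""
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    sc = cfg.get("scenario", {})
    series_file = sc.get("timeseries")
    series = {}
    if series_file:
        series = load_timeseries(path.parent / series_file)
    effort = None
    if sc.get("effort_series"):
        effort = series[sc["effort_series"]]
    apps = []
    for a in cfg.get("application", []):
        curve = _curve_from_dict(a["curve"]) if "curve" in a else None
        apps.append(
            ForcingApplication(
                series_id=a["series"],
                mode=a["mode"],
                predator=a.get("predator"),
                prey=a.get("prey"),
                group=a.get("group"),
                curve=curve,
                normalize=a.get("normalize", "mean"),
            )
        )
    return Scenario(
        applications=apps,
        series=series,
        effort=effort,
        start=sc.get("start", "1996-01"),
        months=int(sc.get("months", 204)),
    )


def write_balanced(res: EcopathResults, path) -> None:
    df = res.to_frame()
    if res.detritus_flows:
        df = df.assign(
            detritus_inflow=np.nan, detritus_consumption=np.nan, detritus_export=np.nan
        )
        det = res.model.detritus
        for k, v in res.detritus_flows.items():
            df.loc[det, f"detritus_{k}"] = v
    df.index.name = "group"
    df.to_csv(path)


def write_trajectories(sim: SimResult, path) -> None:
    long = (
        sim.biomass.stack()
        .rename("biomass")
        .reset_index()
        .rename(columns={"level_0": "date", "level_1": "group"})
    )
    rel = sim.relative.stack().rename("relative_biomass").reset_index(drop=True)
    long["relative_biomass"] = rel
    long["date"] = long["date"].astype(str)
    long.to_csv(path, index=False, float_format="%.10g")


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["date"] = pd.PeriodIndex(df["date"], freq="M")
    return df


def write_fit_report(rep: FitReport, path) -> None:
    payload = {
        "total_ss": rep.total_ss,
        "per_series": {
            g: {"ss": float(r["ss"]), "q": float(r["q"]), "n": int(r["n"])}
            for g, r in rep.per_series.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_mc(mc: MCResult, path) -> None:
    mc.trials.to_csv(path, index=False)


def write_manifest(path, *, inputs: dict[str, Path | str], seed=None, config: dict | None = None):
    """Run manifest: input hashes, seed and package version for provenance."""
    from . import __version__

    hashes = {}
    for label, p in inputs.items():
        p = Path(p)
        hashes[label] = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
    payload = {"version": __version__, "seed": seed, "inputs": hashes, "config": config or {}}
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
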
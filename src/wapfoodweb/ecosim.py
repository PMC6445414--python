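"""Time-dynamic food-web simulation with foraging-arena consumption.

Biomass dynamics follow

    dB_i/dt = g_i * sum_j Q_ji - sum_j Q_ij - (M0_i + F_i) * B_i

with consumption on each predator-prey link computed from the foraging-arena
closed form: prey enter a vulnerable pool at exchange rate ``v`` and are
consumed there at rate ``a * B_pred``, giving

    Q = a * v * B_prey * B_pred / (v + a * B_pred).

Link parameters are calibrated so that, at the mass-balance base state with
all forcing multipliers equal to one, every link reproduces its base
consumption exactly -- the unforced simulation therefore preserves the
Ecopath equilibrium.  Large ``v`` recovers Lotka-Volterra dynamics; ``v``
near its base value gives donor control.  Environmental forcing multiplies
``v`` and/or ``a`` per link, producer production rates, or the production
term of a driven group; the multi-stanza krill group is propagated by
monthly age-class bookkeeping (survival, graduation at the stanza boundary,
recruitment proportional to adult biomass).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ecopath import EcopathResults
from .forcing import MonthlyTimeSeries, ResponseCurve

__all__ = [
    "SimOptions",
    "SimParams",
    "ForcingApplication",
    "Scenario",
    "SimResult",
    "Ecosim",
    "SimulationError",
    "derive_sim_parameters",
    "compute_consumption",
]

LINK_MODES = ("vulnerability", "search_rate", "arena_area", "vulnerability_and_arena")
GROUP_MODES = ("production_rate", "biomass_driver")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimOptions:
    """Integrator and closure options.

    ``substeps``: RK4 sub-steps per monthly step; ``producer_max_pb``: ratio
    of the maximum to the base producer P/B in the saturating production
    curve; ``biomass_floor``: state floor as a fraction of base biomass;
    ``handling`` (D) and ``feeding_time`` (T) are retained as hooks and
    default to 1 (off).
    """

    substeps: int = 4
    producer_max_pb: float = 2.0
    biomass_floor: float = 1e-6
    handling: float = 1.0
    feeding_time: float = 1.0
    max_excursion: float = 1e6
    stanza_max_age: int = 600  # months kept in the krill age vector
    #: pools whose base loss rate exceeds this (per year) are too stiff for
    #: the explicit monthly integrator and track their moving equilibrium
    #: instead (detritus, microzooplankton, phytoplankton in the WAP model)
    fast_turnover: float = 20.0
    fast_sweeps: int = 3


@dataclass
class SimParams:
    """Derived per-link and per-group simulation parameters."""

    names: list[str]
    prey_ix: np.ndarray  # link -> prey index
    pred_ix: np.ndarray  # link -> predator index
    q0: np.ndarray  # base consumption per link
    a: np.ndarray  # effective search rate per link
    v: np.ndarray  # vulnerability exchange rate per link
    xv: np.ndarray  # vulnerability multiplier per link
    g: np.ndarray  # net growth efficiency per group (P/Q)
    m0: np.ndarray  # other mortality per group, /yr
    f0: np.ndarray  # base fishing mortality per group, /yr
    b0: np.ndarray  # base biomass
    unassim: np.ndarray
    is_producer: np.ndarray
    is_detritus: np.ndarray
    prod_r: np.ndarray  # producer production curve P(B) = r B / (1 + b B)
    prod_b: np.ndarray
    det_export: float  # detritus export rate, /yr

    def link_index(self, prey: str, pred: str) -> int:
        i, j = self.names.index(prey), self.names.index(pred)
        hits = np.where((self.prey_ix == i) & (self.pred_ix == j))[0]
        if len(hits) == 0:
            raise KeyError(f"no trophic link {prey!r} -> {pred!r}")
        return int(hits[0])


def derive_sim_parameters(
    res: EcopathResults,
    xv: float | Mapping[tuple[str, str], float] = 2.0,
    options: SimOptions = SimOptions(),
) -> SimParams:
    """Calibrate foraging-arena parameters against the base state.

    Per link, ``v = xv * q0 / B_prey`` and the search rate ``a`` is solved so
    the base-state consumption equals ``q0``; per group ``g = P/Q``,
    ``M0 = (1 - EE) * P/B`` and ``F0 = landings / B``.  ``xv`` must exceed 1
    (at 1 the arena flux cannot supply the base consumption).
    """
    names = res.names
    n = len(names)
    roles = res.roles.to_numpy()
    b0 = res.biomass.to_numpy(dtype=float)
    q0m = res.q0.to_numpy()
    prey_ix, pred_ix, q0l, xvl = [], [], [], []
    for j in range(n):
        for i in range(n):
            if q0m[i, j] <= 0:
                continue
            key = (names[i], names[j])
            x = float(xv.get(key, 2.0)) if isinstance(xv, Mapping) else float(xv)
            if x <= 1.0:
                raise ValueError(f"vulnerability multiplier must exceed 1 (link {key}: {x})")
            prey_ix.append(i)
            pred_ix.append(j)
            q0l.append(q0m[i, j])
            xvl.append(x)
    prey_ix = np.array(prey_ix, dtype=int)
    pred_ix = np.array(pred_ix, dtype=int)
    q0l = np.array(q0l)
    xvl = np.array(xvl)
    v = xvl * q0l / b0[prey_ix]
    # q0 = a v Bi Bj / (v + a Bj)  =>  a = v / (Bj (xv - 1))
    a = v / (b0[pred_ix] * (xvl - 1.0))

    pb = np.nan_to_num(res.pb.to_numpy(dtype=float))
    qb = np.nan_to_num(res.qb.to_numpy(dtype=float))
    ee = res.ee.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(qb > 0, pb / qb, 0.0)
    m0 = np.where(roles == "detritus", 0.0, (1.0 - ee) * pb)
    f0 = res.landings.to_numpy() / b0
    is_prod = roles == "producer"
    is_det = roles == "detritus"
    # saturating producer production: P(B) = r B / (1 + c B), P(B0) = pb B0
    mp = options.producer_max_pb
    prod_r = np.where(is_prod, pb * mp, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prod_b = np.where(is_prod, (mp - 1.0) / b0, 0.0)
    det_export = 0.0
    if res.detritus_flows:
        det_ix = int(np.where(is_det)[0][0])
        exp_flow = res.detritus_flows.get("export", 0.0)
        if exp_flow < 0:
            warnings.warn("detritus export is negative at base; clamped to zero")
            exp_flow = 0.0
        det_export = exp_flow / b0[det_ix]
    return SimParams(
        names=list(names),
        prey_ix=prey_ix,
        pred_ix=pred_ix,
        q0=q0l,
        a=a,
        v=v,
        xv=xvl,
        g=g,
        m0=m0,
        f0=f0,
        b0=b0,
        unassim=res.unassim.to_numpy(),
        is_producer=is_prod,
        is_detritus=is_det,
        prod_r=prod_r,
        prod_b=prod_b,
        det_export=det_export,
    )


def compute_consumption(
    biomass: np.ndarray | pd.Series,
    params: SimParams,
    fv: np.ndarray | float = 1.0,
    fa: np.ndarray | float = 1.0,
) -> pd.Series:
    """Per-link consumption at the given state under multipliers on v and a."""
    b = np.asarray(biomass, dtype=float)
    if np.any(b <= 0):
        raise ValueError("biomasses must be positive")
    v = params.v * fv
    a = params.a * fa
    bi, bj = b[params.prey_ix], b[params.pred_ix]
    q = a * v * bi * bj / (v + a * bj)
    idx = pd.MultiIndex.from_arrays(
        [np.array(params.names)[params.prey_ix], np.array(params.names)[params.pred_ix]],
        names=["prey", "predator"],
    )
    return pd.Series(q, index=idx, name="consumption")


@dataclass
class ForcingApplication:
    """One forcing series applied to a trophic link or a group.

    Link modes multiply the vulnerability exchange rate and/or search rate;
    ``production_rate`` scales a producer's production; ``biomass_driver``
    scales the production term of a consumer group (for the multi-stanza
    krill group: its recruitment flux).  Without a response curve the series
    is normalised per ``normalize`` ('mean' over the horizon, or 'none').
    """

    series_id: str
    mode: str
    predator: str | None = None
    prey: str | None = None
    group: str | None = None
    curve: ResponseCurve | None = None
    normalize: str = "mean"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.mode in LINK_MODES:
            if not (self.predator and self.prey):
                raise ValueError(f"mode {self.mode!r} targets a predator-prey link")
        elif self.mode in GROUP_MODES:
            if not self.group:
                raise ValueError(f"mode {self.mode!r} targets a group")
        else:
            raise ValueError(f"unknown forcing mode {self.mode!r}")
        if self.normalize not in ("mean", "none"):
            raise ValueError("normalize must be 'mean' or 'none'")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        tgt = self.group if self.group else f"{self.prey}->{self.predator}"
        return f"{tgt}:{self.mode}:{self.series_id}"


@dataclass
class Scenario:
    """Forcing applications, their series, fishing effort and the horizon."""

    applications: list[ForcingApplication] = field(default_factory=list)
    series: dict[str, MonthlyTimeSeries] = field(default_factory=dict)
    effort: MonthlyTimeSeries | None = None
    start: str = "1996-01"
    months: int = 204

    def without(self, app: ForcingApplication) -> "Scenario":
        return replace(self, applications=[a for a in self.applications if a is not app])

    def with_curve(self, group: str, curve: ResponseCurve | None) -> "Scenario":
        """Replace (or drop, if None) the biomass-driver curve of ``group``."""
        apps = []
        for a in self.applications:
            if a.mode == "biomass_driver" and a.group == group:
                if curve is not None:
                    apps.append(replace(a, curve=curve))
            else:
                apps.append(a)
        return replace(self, applications=apps)


@dataclass
class SimResult:
    """Monthly trajectories.  Row ``t`` is the state at the start of month
    ``t``; the first row is the base state, so relative biomass starts at 1."""

    biomass: pd.DataFrame
    relative: pd.DataFrame
    catch: pd.DataFrame
    consumption: pd.DataFrame | None = None

    @property
    def index(self) -> pd.PeriodIndex:
        return self.biomass.index

    def annual_mean_relative(self) -> pd.DataFrame:
        rel = self.relative
        return rel.groupby(rel.index.year).mean()

    def plot(self, groups: Sequence[str] | None = None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 5))
        cols = list(groups) if groups else list(self.relative.columns[:8])
        ts = self.relative[cols]
        ts.index = ts.index.to_timestamp()
        ts.plot(ax=ax)
        ax.set_ylabel("relative biomass B(t)/B(0)")
        return ax


class Ecosim:
    """Time-dynamic simulator over a solved mass balance.

    ``Ecosim(results).run(scenario)`` integrates the monthly dynamics with
    fixed-step RK4; without a scenario it runs unforced at constant effort.
    """

    def __init__(
        self,
        res: EcopathResults,
        xv: float | Mapping[tuple[str, str], float] = 2.0,
        options: SimOptions = SimOptions(),
    ) -> None:
        self.results = res
        self.options = options
        self.params = derive_sim_parameters(res, xv, options)
        self._setup_stanzas()

    # -- stanza bookkeeping -------------------------------------------------
    def _setup_stanzas(self) -> None:
        self.stanza_sets = []
        p = self.params
        for ss in self.results.model.stanzas:
            amax = self.options.stanza_max_age
            ages = np.arange(amax)
            z = np.empty(amax)
            memb = np.empty(amax, dtype=int)  # stanza index per age class
            for s_i, st in enumerate(ss.stanzas):
                nxt = ss.stanzas[s_i + 1].start_age if s_i + 1 < len(ss.stanzas) else amax
                memb[st.start_age : nxt] = s_i
                z[st.start_age : nxt] = st.z
            # survivorship on the truncated grid
            l = np.concatenate([[1.0], np.exp(-np.cumsum(z[:-1] / 12.0))])
            w = (1.0 - np.exp(-ss.vbk * ages / 12.0)) ** 3
            gix = np.array([p.names.index(st.name) for st in ss.stanzas])
            adult = memb == len(ss.stanzas) - 1
            lead_b = p.b0[gix[ss.leading]]
            lead_mask = memb == ss.leading
            scale = lead_b / float((l * w)[lead_mask].sum())
            n_at_age = scale * l
            rho = n_at_age[0] / float((n_at_age * w)[adult].sum())
            self.stanza_sets.append(
                {
                    "set": ss,
                    "ages": ages,
                    "w": w,
                    "memb": memb,
                    "group_ix": gix,
                    "n0": n_at_age,  # base-state age structure; runs start here
                    "n": n_at_age.copy(),
                    "rho": rho,
                    "adult": adult,
                }
            )

    # -- forcing ------------------------------------------------------------
    def _compile_forcing(self, scenario: Scenario | None, months: int, start: pd.Period):
        p = self.params
        nl, n = len(p.q0), len(p.names)
        fv = np.ones((months, nl))
        fa = np.ones((months, nl))
        prod = np.ones((months, n))
        drv = np.ones((months, n))
        effort = np.ones(months)
        idx = pd.period_range(start, periods=months, freq="M")
        if scenario is None:
            return fv, fa, prod, drv, effort
        if scenario.effort is not None:
            e = scenario.effort.aligned(idx)
            if e[0] <= 0:
                raise SimulationError("effort in the first month must be positive")
            effort = e / e[0]
        for app in scenario.applications:
            if app.series_id not in scenario.series:
                raise SimulationError(f"scenario lacks series {app.series_id!r}")
            vals = scenario.series[app.series_id].aligned(idx)
            if app.curve is not None:
                mult = app.curve.evaluate(vals)
            elif app.normalize == "mean":
                m = float(np.nanmean(vals))
                if m <= 0:
                    raise SimulationError(f"series {app.series_id!r} has non-positive mean")
                mult = vals / m
            else:
                mult = vals.astype(float)
            if np.any(mult < 0):
                raise SimulationError(f"negative multiplier from {app.name}")
            if app.mode in LINK_MODES:
                try:
                    l = p.link_index(app.prey, app.predator)
                except KeyError as exc:
                    warnings.warn(f"{exc}; forcing application skipped")
                    continue
                if app.mode == "vulnerability":
                    fv[:, l] *= mult
                elif app.mode == "search_rate":
                    fa[:, l] *= mult
                elif app.mode == "arena_area":
                    fv[:, l] *= mult
                    fa[:, l] *= mult
                else:  # vulnerability_and_arena
                    fv[:, l] *= mult * mult
                    fa[:, l] *= mult
            else:
                gi = p.names.index(app.group)
                if app.mode == "production_rate":
                    if not p.is_producer[gi]:
                        raise SimulationError(
                            f"production_rate targets a producer, got {app.group!r}"
                        )
                    prod[:, gi] *= mult
                else:
                    drv[:, gi] *= mult
        return fv, fa, prod, drv, effort

    # -- dynamics -----------------------------------------------------------
    def _rhs(self, b, fv, fa, prodm, drvm, eff, frozen):
        p = self.params
        bc = np.maximum(b, p.b0 * self.options.biomass_floor)
        v = p.v * fv
        a = p.a * fa
        bi, bj = bc[p.prey_ix], bc[p.pred_ix]
        q = a * v * bi * bj / (v + a * bj)
        intake = np.bincount(p.pred_ix, weights=q, minlength=len(bc))
        loss = np.bincount(p.prey_ix, weights=q, minlength=len(bc))
        f = p.f0 * eff
        db = p.g * intake * drvm - loss - (p.m0 + f) * bc
        prod_flux = p.prod_r * bc / (1.0 + p.prod_b * bc) * prodm
        db = np.where(p.is_producer, prod_flux - loss - p.m0 * bc, db)
        if p.is_detritus.any():
            inflow = float((p.unassim * intake).sum() + (p.m0 * bc)[~p.is_detritus].sum())
            det = p.is_detritus
            db = np.where(det, inflow - loss - p.det_export * bc, db)
        db[frozen] = 0.0
        return db, q, loss

    def _fast_mask(self) -> np.ndarray:
        """Groups updated at moving equilibrium instead of integrated."""
        p = self.params
        m2_0 = np.bincount(p.prey_ix, weights=p.q0, minlength=len(p.b0)) / p.b0
        loss0 = m2_0 + p.m0 + p.f0 + np.where(p.is_detritus, p.det_export, 0.0)
        fast = loss0 > self.options.fast_turnover
        for sd in self.stanza_sets:
            fast[sd["group_ix"]] = False
        return fast

    def _fast_update(self, b, fv, fa, prodm, drvm, eff, fast_ix) -> None:
        """Set fast-turnover pools to the equilibrium of their rate equation.

        Producers and detritus have closed forms; fast consumers are solved
        by fixed-point iteration of g * intake(B) = loss_rate * B.  At the
        base state with unit multipliers every update reproduces the base
        biomass exactly.
        """
        p, opts = self.params, self.options
        floor = p.b0 * opts.biomass_floor
        v = p.v * fv
        a = p.a * fa
        for _ in range(opts.fast_sweeps):
            bc = np.maximum(b, floor)
            # predation loss per unit prey biomass on every link
            coef = a * v * bc[p.pred_ix] / (v + a * bc[p.pred_ix])
            lp = np.bincount(p.prey_ix, weights=coef, minlength=len(bc))
            for i in fast_ix:
                if p.is_producer[i]:
                    target = lp[i] + p.m0[i] + p.f0[i] * eff
                    r = p.prod_r[i] * prodm[i]
                    if r <= target or p.prod_b[i] <= 0 or target <= 0:
                        b[i] = floor[i] if r <= target else b[i]
                    else:
                        b[i] = max((r / target - 1.0) / p.prod_b[i], floor[i])
                elif p.is_detritus[i]:
                    bc2 = np.maximum(b, floor)
                    q = a * v * bc2[p.prey_ix] * bc2[p.pred_ix] / (v + a * bc2[p.pred_ix])
                    intake = np.bincount(p.pred_ix, weights=q, minlength=len(bc2))
                    inflow = float(
                        (p.unassim * intake).sum() + (p.m0 * bc2)[~p.is_detritus].sum()
                    )
                    denom = lp[i] + p.det_export
                    if denom > 0:
                        b[i] = max(inflow / denom, floor[i])
                else:
                    links = p.pred_ix == i
                    denom = lp[i] + p.m0[i] + p.f0[i] * eff
                    if denom <= 0:
                        continue
                    bprey = np.maximum(b, floor)[p.prey_ix[links]]
                    al, vl = a[links], v[links]
                    x = max(b[i], floor[i])
                    for _ in range(12):
                        q_in = (al * vl * bprey * x / (vl + al * x)).sum()
                        x = max(p.g[i] * drvm[i] * q_in / denom, floor[i])
                    b[i] = x

    def run(
        self,
        scenario: Scenario | None = None,
        months: int | None = None,
        keep_consumption: bool = False,
    ) -> SimResult:
        p = self.params
        opts = self.options
        start = pd.Period(scenario.start if scenario else "1996-01", freq="M")
        months = months if months is not None else (scenario.months if scenario else 204)
        fv, fa, prodm, drvm, effort = self._compile_forcing(scenario, months, start)
        frozen = np.zeros(len(p.names), dtype=bool)
        for sd in self.stanza_sets:
            frozen[sd["group_ix"]] = True
        fast = self._fast_mask()
        fast_ix = np.flatnonzero(fast)
        frozen = frozen | fast
        for sd in self.stanza_sets:
            sd["n"] = sd["n0"].copy()  # every run starts at the base age structure

        b = p.b0.astype(float).copy()
        traj = np.empty((months + 1, len(b)))
        catch = np.empty((months, len(b)))
        cons = np.empty((months, len(p.q0))) if keep_consumption else None
        traj[0] = b
        h = (1.0 / 12.0) / opts.substeps  # years
        for m in range(months):
            args = (fv[m], fa[m], prodm[m], drvm[m], effort[m], frozen)
            self._fast_update(b, fv[m], fa[m], prodm[m], drvm[m], effort[m], fast_ix)
            for _ in range(opts.substeps):
                k1, _, _ = self._rhs(b, *args)
                k2, _, _ = self._rhs(b + 0.5 * h * k1, *args)
                k3, _, _ = self._rhs(b + 0.5 * h * k2, *args)
                k4, _, _ = self._rhs(b + h * k3, *args)
                b = b + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                b = np.maximum(b, p.b0 * opts.biomass_floor)
                self._fast_update(b, fv[m], fa[m], prodm[m], drvm[m], effort[m], fast_ix)
            # monthly stanza bookkeeping at the post-step state
            _, q_now, _ = self._rhs(b, *args)
            for sd in self.stanza_sets:
                self._stanza_step(sd, b, q_now, effort[m], drvm[m])
            catch[m] = p.f0 * effort[m] * b / 12.0
            if keep_consumption:
                cons[m] = q_now
            traj[m + 1] = b
            if np.any(b > opts.max_excursion * p.b0):
                worst = p.names[int(np.argmax(b / p.b0))]
                raise SimulationError(
                    f"integration unstable at month {m}: {worst} exceeded "
                    f"{opts.max_excursion:g} times its base biomass"
                )

        idx = pd.period_range(start, periods=months + 1, freq="M")
        bio = pd.DataFrame(traj, index=idx, columns=p.names)
        rel = bio / p.b0
        cat = pd.DataFrame(catch, index=idx[:-1], columns=p.names)
        consumption = None
        if keep_consumption:
            cols = pd.MultiIndex.from_arrays(
                [np.array(p.names)[p.prey_ix], np.array(p.names)[p.pred_ix]],
                names=["prey", "predator"],
            )
            consumption = pd.DataFrame(cons, index=idx[:-1], columns=cols)
        return SimResult(biomass=bio, relative=rel, catch=cat, consumption=consumption)

    def _stanza_step(self, sd, b, q_link, eff, drvm) -> None:
        """Advance the age vector one month and write stanza biomasses back."""
        p = self.params
        gix = sd["group_ix"]
        n_vec, w, memb = sd["n"], sd["w"], sd["memb"]
        z = np.empty(len(gix))
        for s_i, gi in enumerate(gix):
            bs = max(b[gi], p.b0[gi] * self.options.biomass_floor)
            pred_loss = float(q_link[p.prey_ix == gi].sum())
            z[s_i] = pred_loss / bs + p.m0[gi] + p.f0[gi] * eff
        surv = np.exp(-z[memb] / 12.0)
        adult_b = float((n_vec * w)[sd["adult"]].sum())
        # a biomass driver on any stanza of the species scales recruitment
        recruit = sd["rho"] * adult_b * float(np.prod(drvm[gix]))
        n_new = np.empty_like(n_vec)
        n_new[1:] = n_vec[:-1] * surv[:-1]
        n_new[0] = recruit
        sd["n"] = n_new
        bw = n_new * w
        for s_i, gi in enumerate(gix):
            b[gi] = max(float(bw[memb == s_i].sum()), p.b0[gi] * self.options.biomass_floor)
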
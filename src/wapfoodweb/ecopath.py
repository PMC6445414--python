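"""Static mass-balance food-web model (Ecopath-style solver).

The model describes an ecosystem as a set of biomass pools linked by a diet
matrix.  For every non-detritus group ``i`` the production balance

    B_i * (P/B)_i * EE_i = sum_j B_j * (Q/B)_j * DC_ij + Y_i + BA_i * B_i

must hold, where ``EE`` (ecotrophic efficiency) is the fraction of production
used within the system, ``DC_ij`` is the fraction of predator ``j``'s diet
consisting of prey ``i``, ``Y`` is the fishery landings and ``BA`` the biomass
accumulation of recovering stocks.  Exactly one of ``{B, EE}`` is unknown per
group; the solver treats the unknown biomasses as a simultaneous linear system
and back-fills the unknown efficiencies.

Multi-stanza groups (here: Antarctic krill split at 24 months) are filled from
the stable age distribution implied by a von Bertalanffy growth schedule and a
per-stanza total mortality before the balance is solved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("consumer", "producer", "detritus")

__all__ = [
    "GroupSpec",
    "DietMatrix",
    "Stanza",
    "StanzaSet",
    "Ecopath",
    "EcopathResults",
    "BalanceReport",
    "BalanceError",
    "DietError",
    "complete_diet_matrix",
    "compute_trophic_levels",
    "multistanza_fill",
    "stanza_lw_sums",
    "solve_mass_balance",
    "check_balance",
    "compute_mti",
]


class BalanceError(ValueError):
    """The mass balance cannot be solved (singular, negative, or ill-posed)."""


class DietError(ValueError):
    """The diet matrix violates a structural constraint."""


def _opt(x) -> float | None:
    if x is None:
        return None
    x = float(x)
    return None if math.isnan(x) else x


@dataclass
class GroupSpec:
    """Input parameters of one model group.

    ``biomass`` is in t/100 km^2, ``pb`` and ``qb`` are per-year rates (``pb``
    is total mortality Z for stanza groups), ``ba_rate`` is the biomass
    accumulation as a fraction of B per year, ``landings`` in t/100 km^2/yr,
    ``unassim`` the unassimilated fraction of consumption.  ``None`` marks an
    unknown to be solved (one of ``biomass``/``ee`` per non-detritus group).
    """

    name: str
    role: str = "consumer"
    biomass: float | None = None
    pb: float | None = None
    qb: float | None = None
    pq: float | None = None
    ee: float | None = None
    ba_rate: float = 0.0
    landings: float = 0.0
    unassim: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: role must be one of {ROLES}, got {self.role!r}")
        for f in ("biomass", "pb", "qb", "pq", "ee"):
            setattr(self, f, _opt(getattr(self, f)))
        if self.role != "detritus":
            if self.pb is None or self.pb <= 0:
                raise ValueError(f"{self.name}: pb must be positive")
        if self.role in ("producer", "detritus") and (self.qb is not None or self.pq is not None):
            raise ValueError(f"{self.name}: producers and detritus take no qb/pq")
        if self.role == "consumer" and self.qb is None and self.pq is not None:
            if self.pq <= 0:
                raise ValueError(f"{self.name}: pq must be positive")
            self.qb = self.pb / self.pq
        if self.unassim is None:
            self.unassim = 0.2 if self.role == "consumer" else 0.0
        if not 0.0 <= self.unassim < 1.0:
            raise ValueError(f"{self.name}: unassim must be in [0, 1)")
        if self.landings < 0:
            raise ValueError(f"{self.name}: landings must be non-negative")


class DietMatrix:
    """Predator diet compositions, possibly with unresolved trace entries.

    ``entries`` maps predator -> {prey: fraction}; ``trace`` holds
    (predator, prey) pairs printed as "<1%" whose numeric value is resolved by
    :func:`complete_diet_matrix`.  Cannibalism (a predator preying on itself)
    is rejected outright.
    """

    def __init__(
        self,
        entries: Mapping[str, Mapping[str, float]],
        trace: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.entries: dict[str, dict[str, float]] = {
            p: dict(prey) for p, prey in entries.items()
        }
        self.trace: set[tuple[str, str]] = set(trace)
        for pred, prey in self.entries.items():
            if pred in prey:
                raise DietError(f"cannibalism is not allowed: {pred}")
            for name, frac in prey.items():
                if frac < 0:
                    raise DietError(f"negative diet fraction: {pred} -> {name}")
        for pred, prey in self.trace:
            if pred == prey:
                raise DietError(f"cannibalism is not allowed: {pred}")
            self.entries.setdefault(pred, {})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DietMatrix":
        entries: dict[str, dict[str, float]] = {}
        trace: set[tuple[str, str]] = set()
        for row in df.itertuples(index=False):
            pred, prey = str(row.predator), str(row.prey)
            is_trace = bool(getattr(row, "trace", 0))
            frac = _opt(getattr(row, "fraction", None))
            if is_trace and frac is None:
                trace.add((pred, prey))
                entries.setdefault(pred, {})
            elif frac is None:
                raise DietError(f"missing fraction for {pred} -> {prey}")
            else:
                entries.setdefault(pred, {})[prey] = frac
        return cls(entries, trace)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"predator": p, "prey": q, "fraction": f, "trace": 0}
            for p, prey in sorted(self.entries.items())
            for q, f in sorted(prey.items())
        ]
        rows += [
            {"predator": p, "prey": q, "fraction": np.nan, "trace": 1}
            for p, q in sorted(self.trace)
        ]
        return pd.DataFrame(rows, columns=["predator", "prey", "fraction", "trace"])

    @property
    def predators(self) -> list[str]:
        return sorted(self.entries)

    def prey_of(self, predator: str) -> dict[str, float]:
        return dict(self.entries.get(predator, {}))

    def fraction(self, predator: str, prey: str) -> float:
        return self.entries.get(predator, {}).get(prey, 0.0)

    @property
    def is_complete(self) -> bool:
        if self.trace:
            return False
        return all(
            abs(sum(prey.values()) - 1.0) <= 1e-9 for prey in self.entries.values() if prey
        )

    def to_matrix(self, names: Sequence[str]) -> np.ndarray:
        """DC[i, j] = fraction of predator j's diet made of prey i."""
        idx = {n: k for k, n in enumerate(names)}
        dc = np.zeros((len(names), len(names)))
        for pred, prey in self.entries.items():
            j = idx[pred]
            for name, frac in prey.items():
                dc[idx[name], j] = frac
        return dc


def complete_diet_matrix(
    raw: DietMatrix,
    trace_values: Mapping[tuple[str, str], float] | None = None,
    detritus: str = "Detritus",
    tol: float = 1e-9,
) -> DietMatrix:
    """Resolve "<1%" markers and column shortfalls so every column sums to 1.

    Trace entries default to an equal share of the column shortfall (per-entry
    overrides via ``trace_values``); a shortfall in a column with no trace
    markers is assigned to the detritus pool rather than renormalised, which
    keeps the remaining printed fractions (and hence the dominant consumers'
    efficiencies) untouched.
    """
    trace_values = dict(trace_values or {})
    entries: dict[str, dict[str, float]] = {}
    for pred in raw.entries:
        prey = dict(raw.entries[pred])
        if not prey and not any(p == pred for p, _ in raw.trace):
            continue
        known = sum(prey.values())
        if known > 1.0 + tol:
            raise DietError(f"diet column of {pred!r} sums to {known:.4f} > 1")
        traces = sorted(q for p, q in raw.trace if p == pred)
        shortfall = 1.0 - known
        if traces:
            fixed = {q: trace_values[(pred, q)] for q in traces if (pred, q) in trace_values}
            if any(v < 0 for v in fixed.values()):
                raise DietError(f"negative trace override in column {pred!r}")
            free = [q for q in traces if q not in fixed]
            remaining = shortfall - sum(fixed.values())
            if remaining < -tol:
                raise DietError(f"trace overrides overfill column {pred!r}")
            share = max(remaining, 0.0) / len(free) if free else 0.0
            for q in traces:
                prey[q] = fixed.get(q, share)
        elif shortfall > tol:
            prey[detritus] = prey.get(detritus, 0.0) + shortfall
        total = sum(prey.values())
        if abs(total - 1.0) > 1e-6:
            raise DietError(f"column {pred!r} completes to {total:.6f}, not 1")
        # remove rounding residue exactly
        entries[pred] = {q: f / total for q, f in prey.items() if f > 0.0}
    return DietMatrix(entries, trace=())


# ---------------------------------------------------------------------------
# multi-stanza fill


@dataclass
class Stanza:
    name: str
    start_age: int  # months
    z: float  # total mortality, per year


@dataclass
class StanzaSet:
    """Age-stanza description of one species on a monthly age grid.

    Body weight follows ``w_a = (1 - exp(-K a/12))**3`` and numbers decay with
    the per-stanza total mortality ``Z``; the population is assumed to sit at
    its stable age distribution, so non-leading stanza biomasses are implied
    by the leading (data-rich) stanza.
    """

    species: str
    stanzas: list[Stanza]
    vbk: float
    leading: int

    def __post_init__(self) -> None:
        if self.vbk <= 0:
            raise ValueError(f"{self.species}: vbk must be positive")
        ages = [s.start_age for s in self.stanzas]
        if ages[0] != 0 or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"{self.species}: start ages must be strictly increasing from 0")
        if any(s.z <= 0 for s in self.stanzas):
            raise ValueError(f"{self.species}: Z must be positive")
        if not 0 <= self.leading < len(self.stanzas):
            raise ValueError(f"{self.species}: bad leading stanza index")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stanzas]


_BINOM = {3: (1.0, -3.0, 3.0, -1.0), 2: (1.0, -2.0, 1.0)}


def stanza_lw_sums(ss: StanzaSet, weight_power: int = 3) -> np.ndarray:
    """Per-stanza sums of survivorship times weight, in closed form.

    ``sum_a l_a * w_a^(p/3)`` over the stanza's monthly ages, with
    ``l_a = exp(-Z-integrated age)`` and ``w_a = (1 - exp(-K a/12))^3``; the
    final stanza's infinite tail is summed as a geometric series, not
    truncated.  ``weight_power`` is the binomial power (3 for biomass weight,
    2 for the 2/3-power consumption weight).
    """
    coeffs = _BINOM[weight_power]
    k12 = ss.vbk / 12.0
    out = np.zeros(len(ss.stanzas))
    log_l = 0.0  # log survivorship at the stanza's first age
    for s_i, st in enumerate(ss.stanzas):
        a0 = st.start_age
        nxt = ss.stanzas[s_i + 1].start_age if s_i + 1 < len(ss.stanzas) else None
        total = 0.0
        for k, c in enumerate(coeffs):
            rho = math.exp(-(st.z / 12.0 + k * k12))
            head = math.exp(log_l) * math.exp(-k * k12 * a0)
            if nxt is None:
                geo = 1.0 / (1.0 - rho)
            else:
                geo = (1.0 - rho ** (nxt - a0)) / (1.0 - rho)
            total += c * head * geo
        out[s_i] = total
        if nxt is not None:
            log_l += -st.z / 12.0 * (nxt - a0)
    return out


def multistanza_fill(
    ss: StanzaSet, leading_biomass: float, leading_qb: float | None = None
) -> pd.DataFrame:
    """Biomass (and optionally Q/B) per stanza from the stable age structure.

    Biomass is proportional to ``sum l_a w_a`` per stanza, anchored to the
    leading stanza; Q/B scales with the per-biomass consumption weight
    ``sum l_a w_a^(2/3) / sum l_a w_a`` (metabolic 2/3-power convention).
    """
    if leading_biomass <= 0:
        raise ValueError(f"{ss.species}: leading biomass must be positive")
    bw = stanza_lw_sums(ss, 3)
    b = leading_biomass * bw / bw[ss.leading]
    out = pd.DataFrame({"biomass": b}, index=ss.names)
    if leading_qb is not None:
        qw = stanza_lw_sums(ss, 2)
        ratio = (qw / bw) / (qw[ss.leading] / bw[ss.leading])
        out["qb"] = leading_qb * ratio
    return out


# ---------------------------------------------------------------------------
# trophic levels


def compute_trophic_levels(
    diet: DietMatrix, roles: Mapping[str, str], tol: float = 1e-6
) -> pd.Series:
    """Solve TL_i = 1 + sum_j DC_ji TL_j with producers/detritus fixed at 1."""
    names = list(roles)
    idx = {n: k for k, n in enumerate(names)}
    n = len(names)
    a = np.eye(n)
    b = np.ones(n)
    for i, name in enumerate(names):
        if roles[name] != "consumer":
            continue
        prey = diet.entries.get(name, {})
        if not prey:
            continue
        total = sum(prey.values())
        if abs(total - 1.0) > tol:
            raise DietError(f"diet column of {name!r} is not normalised (sum {total:.4f})")
        for q, f in prey.items():
            a[i, idx[q]] -= f
    return pd.Series(np.linalg.solve(a, b), index=names, name="trophic_level")


# ---------------------------------------------------------------------------
# the model / results pair


class Ecopath:
    """Mass-balance model built from group specs, a diet matrix and stanzas.

    The constructor completes the diet matrix (resolving trace entries and
    shortfalls) and applies the multi-stanza fill; :meth:`fit` solves the
    balance and returns an :class:`EcopathResults`.
    """

    def __init__(
        self,
        groups: Sequence[GroupSpec],
        diet: DietMatrix,
        stanzas: Sequence[StanzaSet] = (),
        trace_values: Mapping[tuple[str, str], float] | None = None,
    ) -> None:
        from dataclasses import replace as _replace

        groups = [_replace(g) for g in groups]  # stanza fill must not mutate caller's specs
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        self.groups = list(groups)
        self.names = names
        self.stanzas = list(stanzas)
        by_name = {g.name: g for g in groups}
        unknown = set(diet.entries) | {q for prey in diet.entries.values() for q in prey}
        unknown |= {n for pair in diet.trace for n in pair}
        unknown -= set(names)
        if unknown:
            raise DietError(f"diet references unknown groups: {sorted(unknown)}")
        detr = [g.name for g in groups if g.role == "detritus"]
        self.detritus = detr[0] if detr else "Detritus"
        self.diet = (
            diet
            if diet.is_complete
            else complete_diet_matrix(diet, trace_values, detritus=self.detritus)
        )
        for ss in self.stanzas:
            lead = by_name[ss.stanzas[ss.leading].name]
            if lead.biomass is None or lead.qb is None:
                raise ValueError(f"{ss.species}: leading stanza needs biomass and qb")
            fill = multistanza_fill(ss, lead.biomass, lead.qb)
            for st in ss.stanzas:
                g = by_name[st.name]
                if g.biomass is None:
                    g.biomass = float(fill.loc[st.name, "biomass"])
                if g.qb is None:
                    g.qb = float(fill.loc[st.name, "qb"])
        for g in self.groups:
            if g.role != "detritus" and (g.biomass is None) == (g.ee is None):
                raise BalanceError(
                    f"{g.name}: exactly one of biomass/ee must be unknown "
                    f"(biomass={g.biomass}, ee={g.ee})"
                )

    @classmethod
    def from_csv(cls, groups_path, diet_path, stanzas_path=None, **kw) -> "Ecopath":
        from . import io

        groups = io.load_groups(groups_path)
        diet = io.load_diet(diet_path)
        stanzas = io.load_stanzas(stanzas_path) if stanzas_path else ()
        return cls(groups, diet, stanzas, **kw)

    def fit(self) -> "EcopathResults":
        groups, names = self.groups, self.names
        n = len(groups)
        idx = {g.name: i for i, g in enumerate(groups)}
        roles = np.array([g.role for g in groups])
        dc = self.diet.to_matrix(names)
        pb = np.array([g.pb if g.pb is not None else 0.0 for g in groups])
        qb = np.array([g.qb if g.qb is not None else 0.0 for g in groups])
        ba = np.array([g.ba_rate for g in groups])
        land = np.array([g.landings for g in groups])
        ua = np.array([g.unassim for g in groups])
        b = np.array([g.biomass if g.biomass is not None else np.nan for g in groups])
        ee = np.array([g.ee if g.ee is not None else np.nan for g in groups])

        unk = [i for i in range(n) if np.isnan(b[i])]
        known = ~np.isnan(b)
        # consumption onto each prey from predators whose biomass is known
        cons_known = (dc * np.where(known, b * qb, 0.0)[None, :]).sum(axis=1)
        if unk:
            m = np.zeros((len(unk), len(unk)))
            r = np.zeros(len(unk))
            for row, i in enumerate(unk):
                if np.isnan(ee[i]):
                    raise BalanceError(f"{names[i]}: both biomass and ee unknown")
                r[row] = cons_known[i] + land[i]
                m[row, row] = pb[i] * ee[i] - ba[i]
                for col, j in enumerate(unk):
                    m[row, col] -= qb[j] * dc[i, j]
            try:
                sol = np.linalg.solve(m, r)
            except np.linalg.LinAlgError as exc:
                raise BalanceError(f"singular mass-balance system: {exc}") from exc
            for val, i in zip(sol, unk):
                if not np.isfinite(val) or val <= 0:
                    raise BalanceError(f"solved biomass for {names[i]!r} is not positive ({val:.4g})")
                b[i] = val

        q0 = dc * (b * qb)[None, :]  # q0[i, j] = B_j QB_j DC_ij
        cons = q0.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ee_calc = (cons + land + ba * b) / (b * pb)
        for i in range(n):
            if roles[i] == "detritus":
                continue
            if np.isnan(ee[i]):
                ee[i] = ee_calc[i]
        m2 = np.where(b > 0, cons / b, 0.0)
        m0 = np.where(roles == "detritus", 0.0, (1.0 - ee) * pb)

        det = idx.get(self.detritus)
        detritus_flows = {}
        if det is not None:
            inflow = float((ua * b * qb).sum())
            inflow += float(sum(m0[i] * b[i] for i in range(n) if i != det))
            outflow = float(cons[det])
            ee[det] = (outflow + land[det]) / inflow if inflow > 0 else 0.0
            detritus_flows = {
                "inflow": inflow,
                "consumption": outflow,
                "export": inflow - outflow - land[det],
            }

        roles_map = {g.name: g.role for g in groups}
        tl = compute_trophic_levels(self.diet, roles_map)

        # residual of the production balance (diagnostic; ~0 by construction)
        resid = b * pb * ee - (cons + land + ba * b)
        resid[roles == "detritus"] = 0.0

        def s(arr, name):
            return pd.Series(arr, index=names, name=name)

        return EcopathResults(
            model=self,
            biomass=s(b, "biomass"),
            pb=s(np.where(roles == "detritus", np.nan, pb), "pb"),
            qb=s(np.where(qb > 0, qb, np.nan), "qb"),
            ee=s(ee, "ee"),
            m2=s(m2, "m2"),
            m0=s(m0, "m0"),
            ba_rate=s(ba, "ba_rate"),
            landings=s(land, "landings"),
            unassim=s(ua, "unassim"),
            trophic_level=tl.reindex(names),
            q0=pd.DataFrame(q0, index=names, columns=names),
            detritus_flows=detritus_flows,
            residual=s(resid, "residual"),
        )


@dataclass
class EcopathResults:
    """Solved mass balance: biomasses, efficiencies, mortalities and flows.

    ``q0.loc[prey, pred]`` is the base consumption (t/100 km^2/yr) of ``prey``
    by ``pred``; ``m2`` the predation mortality, ``m0`` the other mortality.
    """

    model: Ecopath
    biomass: pd.Series
    pb: pd.Series
    qb: pd.Series
    ee: pd.Series
    m2: pd.Series
    m0: pd.Series
    ba_rate: pd.Series
    landings: pd.Series
    unassim: pd.Series
    trophic_level: pd.Series
    q0: pd.DataFrame
    detritus_flows: dict
    residual: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.biomass.index)

    def role(self, name: str) -> str:
        return next(g.role for g in self.model.groups if g.name == name)

    @property
    def roles(self) -> pd.Series:
        return pd.Series({g.name: g.role for g in self.model.groups})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomass": self.biomass,
                "pb": self.pb,
                "qb": self.qb,
                "ee": self.ee,
                "trophic_level": self.trophic_level,
                "m2": self.m2,
                "m0": self.m0,
                "ba_rate": self.ba_rate,
                "landings": self.landings,
            }
        )

    def summary(self) -> str:
        df = self.to_frame()
        rep = check_balance(self)
        lines = [
            "Mass-balance model: %d groups (%d consumers, %d producers)"
            % (
                len(df),
                (self.roles == "consumer").sum(),
                (self.roles == "producer").sum(),
            ),
            df.to_string(float_format=lambda v: f"{v:.3f}"),
            f"balance: {'PASS' if rep.passed else 'FAIL'}",
        ]
        if rep.unbalanced:
            lines.append(
                "unbalanced (EE > 1): "
                + ", ".join(f"{n} ({v:.3f})" for n, v in rep.unbalanced)
            )
        return "\n".join(lines)

    def check_balance(self) -> "BalanceReport":
        return check_balance(self)

    def mti(self) -> pd.DataFrame:
        return compute_mti(self)


def solve_mass_balance(
    groups: Sequence[GroupSpec],
    diet: DietMatrix,
    stanzas: Sequence[StanzaSet] = (),
) -> EcopathResults:
    """Functional wrapper: build an :class:`Ecopath` model and fit it."""
    return Ecopath(groups, diet, stanzas).fit()


@dataclass
class BalanceReport:
    passed: bool
    unbalanced: list[tuple[str, float]] = field(default_factory=list)
    negative: list[tuple[str, float]] = field(default_factory=list)
    respiration_violations: list[tuple[str, float]] = field(default_factory=list)

    def __str__(self) -> str:
        if self.passed:
            return "balance check: PASS"
        parts = ["balance check: FAIL"]
        if self.unbalanced:
            parts.append("EE > 1: " + ", ".join(f"{n}={v:.3f}" for n, v in self.unbalanced))
        if self.negative:
            parts.append("EE < 0: " + ", ".join(f"{n}={v:.3f}" for n, v in self.negative))
        if self.respiration_violations:
            parts.append(
                "negative respiration: "
                + ", ".join(f"{n} ({v:.3f})" for n, v in self.respiration_violations)
            )
        return "; ".join(parts)


def check_balance(res: EcopathResults, tol: float = 1e-6) -> BalanceReport:
    """Diagnostics: EE in [0, 1] for every group and non-negative respiration.

    An EE of exactly 1 (production fully used, e.g. humpback whales with their
    biomass-accumulation term) passes; anything above 1 + tol means predation,
    catch and accumulation together exceed production.
    """
    rep = BalanceReport(passed=True)
    roles = res.roles
    for name in res.names:
        e = res.ee[name]
        if e > 1.0 + tol:
            rep.unbalanced.append((name, float(e)))
        elif e < -tol:
            rep.negative.append((name, float(e)))
        if roles[name] == "consumer":
            # energy balance: assimilated consumption must cover production
            margin = res.qb[name] * (1.0 - res.unassim[name]) - res.pb[name]
            if margin < -tol:
                rep.respiration_violations.append((name, float(margin)))
    rep.passed = not (rep.unbalanced or rep.negative or rep.respiration_violations)
    return rep


def compute_mti(res: EcopathResults) -> pd.DataFrame:
    """Mixed-trophic-impact matrix (net direct + indirect effects).

    The direct impact of group i on group j is the share of j's diet supplied
    by i minus the share of i's total predation exerted by j; net impacts
    propagate through the Leontief inverse (I - Q)^-1 - I.  Detritus "diet"
    is taken as the inflow shares from unassimilated food and other mortality.
    """
    names = res.names
    n = len(names)
    idx = {m: i for i, m in enumerate(names)}
    dc = res.model.diet.to_matrix(names)  # dc[i, j]: prey i in diet of pred j
    det = idx.get(res.model.detritus)
    if det is not None and res.detritus_flows:
        inflow_i = np.array(
            [
                res.unassim[m] * (res.qb[m] if np.isfinite(res.qb[m]) else 0.0) * res.biomass[m]
                + res.m0[m] * res.biomass[m]
                for m in names
            ]
        )
        inflow_i[det] = 0.0
        if inflow_i.sum() > 0:
            dc[:, det] = inflow_i / inflow_i.sum()
    q0 = res.q0.to_numpy()
    tot_pred = q0.sum(axis=1) + res.landings.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        host = np.where(tot_pred[:, None] > 0, q0 / tot_pred[:, None], 0.0)
    direct = dc - host.T  # direct[i, j]: impact of i on j
    try:
        mti = np.linalg.inv(np.eye(n) - direct) - np.eye(n)
    except np.linalg.LinAlgError as exc:
        raise BalanceError(f"mixed-trophic-impact system is singular: {exc}") from exc
    return pd.DataFrame(mti, index=names, columns=names)
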
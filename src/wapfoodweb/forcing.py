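"""Environmental forcing series and functional response curves.

Monthly environmental series (sea-ice area, open-water area, chlorophyll-a)
are reduced to dimensionless multipliers that perturb predator-prey links or
production rates in the dynamic simulation.  The sea-ice index is the annual
summer minimum ice area scaled by its long-term mean, repeated monthly; gaps
in monthly series are filled with the per-calendar-month climatology; annual
rates (leopard-seal predation on fur-seal pups) are expanded to the months of
the breeding season.  Response curves map a forcing value to a multiplier
normalised to 1 at the mass-balance baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyTimeSeries",
    "AnnualIndex",
    "ResponseCurve",
    "ForcingError",
    "build_sea_ice_index",
    "gap_fill_monthly",
    "expand_annual_series",
    "evaluate_response_curve",
]


class ForcingError(ValueError):
    pass


class MonthlyTimeSeries:
    """A contiguous monthly series with units and an implicit missing mask.

    Thin wrapper over a :class:`pandas.Series` with a monthly ``PeriodIndex``;
    missing months are NaN.
    """

    def __init__(self, values: pd.Series, units: str = "") -> None:
        if not isinstance(values.index, pd.PeriodIndex) or values.index.freqstr not in ("M",):
            raise ForcingError("monthly series needs a PeriodIndex with monthly frequency")
        if len(values) == 0:
            raise ForcingError("empty series")
        full = pd.period_range(values.index[0], values.index[-1], freq="M")
        self.values = values.astype(float).reindex(full)
        self.units = units

    @classmethod
    def from_items(cls, items: Mapping[str, float] | list[tuple[str, float]], units: str = ""):
        ser = pd.Series(dict(items))
        ser.index = pd.PeriodIndex(ser.index, freq="M")
        return cls(ser.sort_index(), units)

    @classmethod
    def constant(cls, value: float, start: str, months: int, units: str = ""):
        idx = pd.period_range(start, periods=months, freq="M")
        return cls(pd.Series(value, index=idx), units)

    @property
    def start(self) -> pd.Period:
        return self.values.index[0]

    @property
    def mask(self) -> pd.Series:
        return self.values.isna()

    def __len__(self) -> int:
        return len(self.values)

    def aligned(self, index: pd.PeriodIndex) -> np.ndarray:
        out = self.values.reindex(index)
        if out.isna().any():
            missing = out.index[out.isna()][:3].tolist()
            raise ForcingError(f"series does not cover the horizon (missing {missing}...)")
        return out.to_numpy()


class AnnualIndex:
    """Dimensionless year -> value map, mean 1 over its construction window."""

    def __init__(self, values: pd.Series) -> None:
        self.values = values.astype(float).sort_index()

    def __getitem__(self, year: int) -> float:
        return float(self.values[year])

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.values.index]

    def to_monthly(self, units: str = "") -> MonthlyTimeSeries:
        """Repeat each annual value for the twelve months of that year."""
        idx = pd.period_range(f"{self.years[0]}-01", f"{self.years[-1]}-12", freq="M")
        vals = [self.values[p.year] for p in idx]
        return MonthlyTimeSeries(pd.Series(vals, index=idx), units)


def build_sea_ice_index(
    ice: MonthlyTimeSeries, window: tuple[int, int] | None = None, allow_partial: bool = False
) -> AnnualIndex:
    """Annual minimum ice area scaled by the mean of the minima.

    Each calendar year contributes its minimum monthly ice area (the austral
    summer minimum falls within the calendar year); the minima are divided by
    their mean over ``window`` (inclusive year range, default: all complete
    years), so icier-than-average summers score above one.
    """
    vals = ice.values.dropna()
    grouped = vals.groupby(vals.index.year)
    minima = {}
    for year, g in grouped:
        if len(g) < 12 and not allow_partial:
            raise ForcingError(f"year {year} has only {len(g)} months of ice data")
        minima[int(year)] = float(g.min())
    minima = pd.Series(minima).sort_index()
    if window is not None:
        minima = minima.loc[window[0] : window[1]]
    if minima.empty:
        raise ForcingError("no complete years in the ice series")
    return AnnualIndex(minima / minima.mean())


def gap_fill_monthly(s: MonthlyTimeSeries) -> MonthlyTimeSeries:
    """Fill missing months with the long-term mean for that calendar month."""
    vals = s.values.copy()
    months = vals.index.month
    clim = vals.groupby(months).mean()
    missing_cal = sorted(set(months[vals.isna()]) - set(clim.dropna().index))
    if missing_cal:
        raise ForcingError(
            f"calendar months {missing_cal} have no observations anywhere in the record"
        )
    fill = pd.Series(clim.reindex(months).to_numpy(), index=vals.index)
    return MonthlyTimeSeries(vals.fillna(fill), s.units)


def expand_annual_series(
    annual: AnnualIndex,
    active_months: set[int],
    zero_before: str | pd.Period | None = None,
    season_start: int | None = None,
    units: str = "",
) -> MonthlyTimeSeries:
    """Expand season-year rates into a monthly series.

    The value of season-year ``y`` fills the active months of the season that
    starts in year ``y`` (e.g. an October-May breeding season spills into the
    following calendar year); inactive months and all months before
    ``zero_before`` are zero.  ``season_start`` defaults to the first month of
    the wrap-around block when the active set crosses the new year, else 1.
    """
    bad = [m for m in active_months if not 1 <= m <= 12]
    if bad or not active_months:
        raise ForcingError(f"malformed active month set: {sorted(active_months)}")
    if season_start is None:
        wraps = 12 in active_months and 1 in active_months and len(active_months) < 12
        if wraps:
            # first active month that follows an inactive one (season onset)
            season_start = next(
                m for m in range(1, 13)
                if m in active_months and ((m - 2) % 12 + 1) not in active_months
            )
        else:
            season_start = 1
    years = annual.years
    idx = pd.period_range(f"{years[0]}-01", f"{years[-1] + 1}-12", freq="M")
    zb = pd.Period(zero_before, freq="M") if zero_before is not None else None
    out = []
    for p in idx:
        season_year = p.year if p.month >= season_start else p.year - 1
        if (
            p.month in active_months
            and season_year in years
            and (zb is None or p >= zb)
        ):
            v = annual[season_year]
            if v < 0:
                raise ForcingError(f"annual value for {season_year} is negative")
            out.append(v)
        else:
            out.append(0.0)
    return MonthlyTimeSeries(pd.Series(out, index=idx), units)


@dataclass
class ResponseCurve:
    """Maps a forcing value to a multiplier, normalised to 1 at the baseline.

    Shapes: ``linear`` (params start, end), ``sigmoid`` (y_zero, y_base,
    y_end, steep; the inflection is placed so the raw curve passes through
    y_base at ``baseline_x``) and ``normal`` (sd_left, data_width, sd_right,
    mean, max -- an asymmetric Gaussian whose grid parameters are mapped into
    forcing units via data_width scaling).  Inputs are clamped to ``domain``.
    """

    shape: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (0.0, 2.0)
    baseline_x: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "sigmoid", "normal"):
            raise ForcingError(f"unknown curve shape {self.shape!r}")
        lo, hi = self.domain
        if not hi > lo:
            raise ForcingError("degenerate curve domain")

    def _raw(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.domain
        p = self.params
        if self.shape == "linear":
            return p["start"] + (p["end"] - p["start"]) * (x - lo) / (hi - lo)
        if self.shape == "sigmoid":
            y0, yb, ye, steep = p["y_zero"], p["y_base"], p["y_end"], p["steep"]
            if not y0 < yb < ye:
                raise ForcingError("sigmoid needs y_zero < y_base < y_end")
            x_mid = self.baseline_x + math.log((ye - yb) / (yb - y0)) / steep
            return y0 + (ye - y0) / (1.0 + np.exp(-steep * (x - x_mid)))
        # asymmetric normal: grid parameters scaled into the domain width
        scale = (hi - lo) / p["data_width"]
        mode = lo + p["mean"] * scale
        sd_l = max(p["sd_left"] * scale, 1e-12)
        sd_r = max(p["sd_right"] * scale, 1e-12)
        sd = np.where(x < mode, sd_l, sd_r)
        return p.get("max", 1.0) * np.exp(-((x - mode) ** 2) / (2.0 * sd**2))

    def evaluate(self, x) -> np.ndarray | float:
        """Normalised multiplier; ``evaluate(baseline_x) == 1`` exactly."""
        scalar = np.isscalar(x)
        xa = np.clip(np.atleast_1d(np.asarray(x, dtype=float)), *self.domain)
        base = float(self._raw(np.array([self.baseline_x]))[0])
        if base <= 0:
            raise ForcingError("curve is non-positive at the baseline; cannot normalise")
        out = np.maximum(self._raw(xa), 0.0) / base
        return float(out[0]) if scalar else out


def evaluate_response_curve(curve: ResponseCurve, x) -> float | np.ndarray:
    """Functional wrapper around :meth:`ResponseCurve.evaluate`."""
    return curve.evaluate(x)
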
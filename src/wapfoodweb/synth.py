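"""Synthetic environmental and observation data generators.

The real calibration of the WAP model rests on external monitoring series
(Palmer LTER sea-ice/open-water/chlorophyll, acoustic krill densities,
predator counts, trawl surveys).  This module generates datasets with the
same statistical structure -- a seasonal ice cycle whose summer minima
decline through 1996-2012, complementary open water, chlorophyll with
missing winter months, annual relative-biomass observations with lognormal
noise, and sparse fish surveys -- so every downstream stage (forcing
construction, simulation, fitting, ablation, curve selection, Monte Carlo)
is testable end-to-end without downloads.  Scale is the Palmer-grid scale,
not Subarea 48.1: the forcing pipeline is relative, so only shapes matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .ecopath import Ecopath, EcopathResults
from .ecosim import Ecosim, ForcingApplication, Scenario, SimOptions, SimResult
from .forcing import MonthlyTimeSeries, ResponseCurve, build_sea_ice_index
from .wap import MONITORED_GROUPS, build_wap_inputs

__all__ = [
    "SyntheticScenario",
    "RecoveryBundle",
    "generate_environment",
    "generate_truth_and_observations",
    "make_recovery_scenario",
    "KRILL_SIGMOID",
    "KRILL_LINEAR",
]

#: The evaluated krill driver curves (sea-ice index -> recruitment multiplier).
KRILL_SIGMOID = dict(y_zero=0.0, y_base=1.5, y_end=5.0)
KRILL_LINEAR = dict(start=0.0, end=60.0)

#: observation noise by guild: counts of breeding vertebrates are precise,
#: acoustic krill densities vary by orders of magnitude, trawl surveys sit
#: in between.
DEFAULT_OBS_CV = {
    "Antarctic fur seal": 0.1,
    "Adelie penguin": 0.1,
    "Chinstrap penguin": 0.1,
    "Gentoo penguin": 0.1,
    "Large krill": 0.4,
    "N. rossii": 0.2,
    "C. gunnari": 0.2,
    "G. gibberifrons": 0.2,
}


@dataclass
class SyntheticScenario:
    """Knobs of the synthetic study system (defaults = study conditions)."""

    seed: int = 0
    start_year: int = 1996
    years: int = 17
    area: float = 40000.0  # km^2, Palmer-grid scale; ice + open water = area
    ice_summer_min_frac: float = 0.25  # of area, at the start of the record
    ice_winter_max_frac: float = 0.95
    #: fractional decline of the annual summer minima per year; the observed
    #: record loses roughly half its summer ice over the 17-year window
    ice_trend: float = 0.03
    #: lognormal interannual noise on the summer minima; with the AR(1)
    #: persistence below this gives the few-fold spread between icy and
    #: ice-poor summers seen in the region
    ice_noise_cv: float = 0.35
    ice_noise_phi: float = 0.6  # year-to-year persistence of ice anomalies
    chl_winter: float = 0.5  # mg m^-3
    chl_summer: float = 3.0
    chl_noise_cv: float = 0.3
    chl_missing_frac: float = 0.15
    obs_cv: dict = field(default_factory=lambda: dict(DEFAULT_OBS_CV))
    fish_years: tuple = (1998, 2001, 2003, 2006, 2009, 2012)
    fish_groups: tuple = ("N. rossii", "C. gunnari", "G. gibberifrons")


def generate_environment(
    sc: SyntheticScenario,
) -> tuple[MonthlyTimeSeries, MonthlyTimeSeries, MonthlyTimeSeries]:
    """Monthly (ice, open-water, chlorophyll) series for the scenario.

    Ice follows a sinusoid between a winter maximum and summer minima that
    decline linearly with seeded interannual noise; open water is the exact
    complement within the study area; chlorophyll peaks in austral summer
    with lognormal noise and a random fraction of missing months.
    """
    rng = np.random.default_rng(sc.seed)
    idx = pd.period_range(f"{sc.start_year}-01", periods=12 * sc.years, freq="M")
    ice = np.empty(len(idx))
    max_ice = sc.ice_winter_max_frac * sc.area
    anomaly = 0.0  # AR(1) log-anomaly of the summer minimum
    for k, p in enumerate(idx):
        y = p.year - sc.start_year
        if k % 12 == 0:
            if sc.ice_noise_cv > 0:
                anomaly = sc.ice_noise_phi * anomaly + rng.normal(0.0, sc.ice_noise_cv)
            min_ice = (
                sc.ice_summer_min_frac
                * sc.area
                * max(1.0 - sc.ice_trend * y, 0.0)
                * float(np.exp(anomaly))
            )
        # minimum in February (month 2), maximum in August
        phase = (p.month - 2) / 12.0
        ice[k] = min_ice + (max_ice - min_ice) * (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0
    ice = np.clip(ice, 0.0, sc.area)
    ice_ts = MonthlyTimeSeries(pd.Series(ice, index=idx), units="km^2")
    open_ts = MonthlyTimeSeries(pd.Series(sc.area - ice, index=idx), units="km^2")

    phase = (idx.month.to_numpy() - 1) / 12.0
    chl = sc.chl_winter + (sc.chl_summer - sc.chl_winter) * (1.0 - np.cos(2 * np.pi * phase)) / 2.0
    if sc.chl_noise_cv > 0:
        chl = chl * np.exp(rng.normal(0.0, sc.chl_noise_cv, len(idx)))
    missing = rng.random(len(idx)) < sc.chl_missing_frac
    chl = np.where(missing, np.nan, chl)
    chl_ts = MonthlyTimeSeries(pd.Series(chl, index=idx), units="mg m^-3")
    return ice_ts, open_ts, chl_ts


def generate_truth_and_observations(
    sc: SyntheticScenario,
    res: EcopathResults,
    scenario: Scenario,
    xv: float = 2.0,
    options: SimOptions = SimOptions(),
    groups: tuple = MONITORED_GROUPS,
) -> tuple[ObservationSet, SimResult]:
    """Run the simulator, then sample noisy relative-biomass observations.

    Annual cadence for vertebrates and krill; sparse survey years for the
    fishes; multiplicative lognormal noise with the per-group CV; each series
    rescaled to mean 1 (observations are relative, carrying no scale).
    """
    rng = np.random.default_rng(sc.seed + 1)
    sim = Ecosim(res, xv, options).run(scenario)
    annual = sim.annual_mean_relative()
    rows = []
    for g in groups:
        years = sc.fish_years if g in sc.fish_groups else tuple(annual.index[:-1])
        cv = sc.obs_cv.get(g, 0.1)
        vals = []
        for y in years:
            truth = float(annual.loc[int(y), g])
            noise = float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0
            vals.append(truth * noise)
        vals = np.asarray(vals)
        vals = vals / vals.mean()
        rows += [
            {"time": int(y), "group": g, "value": float(v)} for y, v in zip(years, vals)
        ]
    return ObservationSet(pd.DataFrame(rows)), sim


@dataclass
class RecoveryBundle:
    """A self-consistent ground-truth dataset for curve-recovery tests."""

    scenario: Scenario  # the fitted scenario (true applications + decoys)
    truth_scenario: Scenario  # the generating scenario (no decoys)
    observations: ObservationSet
    truth: SimResult
    candidates: list[ResponseCurve]
    true_curve: ResponseCurve
    true_application: ForcingApplication
    results: EcopathResults
    ice_index_domain: tuple


def _sigmoid(steep: float, domain) -> ResponseCurve:
    return ResponseCurve("sigmoid", dict(KRILL_SIGMOID, steep=steep), domain=domain)


def make_recovery_scenario(
    true_steep: float = 3.0,
    seed: int = 0,
    steep_grid: tuple = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    sc: SyntheticScenario | None = None,
    xv: float = 2.0,
    options: SimOptions = SimOptions(),
    krill_obs_cv: float = 0.15,
) -> RecoveryBundle:
    """Environment + observations generated under a known sigmoid krill
    driver, bundled with the candidate-curve grid and decoy applications.

    The generating scenario drives krill recruitment with a sigmoid of the
    sea-ice index (steepness ``true_steep``) and forces the chinstrap-krill
    link with the same index; the fitted scenario additionally carries two
    open-water decoy applications absent from the truth, so ablation has
    something to reject.

    The bundle is a designed identifiability experiment: distinguishing
    adjacent steepness values on a 17-point annual series requires
    survey-precision krill observations, so the krill noise CV defaults to
    ``krill_obs_cv`` = 0.15 here instead of the acoustic-emulation default
    of 0.4 (pass ``sc`` to override).
    """
    if sc is None:
        sc = SyntheticScenario(
            seed=seed, obs_cv={**DEFAULT_OBS_CV, "Large krill": krill_obs_cv}
        )
    else:
        sc = SyntheticScenario(**{**sc.__dict__, "seed": seed})
    if true_steep not in steep_grid:
        raise ValueError("true_steep must be on the candidate grid")
    ice, open_w, chl = generate_environment(sc)
    index = build_sea_ice_index(ice)
    months = 12 * sc.years
    series = {
        "sea_ice_index": index.to_monthly(),
        "open_water": open_w,
    }
    domain = (0.0, max(2.0, float(index.values.max()) * 1.1))
    true_curve = _sigmoid(true_steep, domain)
    driver = ForcingApplication(
        series_id="sea_ice_index",
        mode="biomass_driver",
        group="Large krill",
        curve=true_curve,
        normalize="none",
        label="krill sea-ice driver",
    )
    true_link = ForcingApplication(
        series_id="sea_ice_index",
        mode="vulnerability_and_arena",
        predator="Chinstrap penguin",
        prey="Large krill",
        label="chinstrap-krill ice forcing",
    )
    decoys = [
        ForcingApplication(
            series_id="open_water",
            mode="vulnerability",
            predator="Gentoo penguin",
            prey="On-shelf fish",
            label="decoy: gentoo-fish open water",
        ),
        ForcingApplication(
            series_id="open_water",
            mode="vulnerability",
            predator="Antarctic fur seal",
            prey="Cephalopods",
            label="decoy: fur seal-cephalopod open water",
        ),
    ]
    start = f"{sc.start_year}-01"
    truth_scenario = Scenario(
        applications=[driver, true_link], series=series, start=start, months=months
    )
    fitted = Scenario(
        applications=[driver, true_link, *decoys], series=series, start=start, months=months
    )
    groups, diet, stanzas = build_wap_inputs()
    res = Ecopath(groups, diet, stanzas).fit()
    obs, truth = generate_truth_and_observations(sc, res, truth_scenario, xv, options)
    return RecoveryBundle(
        scenario=fitted,
        truth_scenario=truth_scenario,
        observations=obs,
        truth=truth,
        candidates=[_sigmoid(s, domain) for s in steep_grid],
        true_curve=true_curve,
        true_application=true_link,
        results=res,
        ice_index_domain=domain,
    )
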
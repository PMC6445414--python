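"""Dynamic engine: base-state calibration, consumption limits, equilibrium
preservation, integrator convergence."""

import numpy as np
import pandas as pd
import pytest

from wapfoodweb import (
    Ecosim,
    ForcingApplication,
    MonthlyTimeSeries,
    Scenario,
    SimOptions,
    build_wap_inputs,
    compute_consumption,
    derive_sim_parameters,
)
from wapfoodweb.ecopath import Ecopath


def test_base_state_reproduces_q0(wap_results):
    p = derive_sim_parameters(wap_results)
    q = compute_consumption(p.b0, p)
    assert np.allclose(q.to_numpy(), p.q0, rtol=1e-9)


def test_lotka_volterra_limit(wap_results):
    """Very large vulnerability multipliers reduce the arena to mass action."""
    p = derive_sim_parameters(wap_results, xv=1e6)
    q = compute_consumption(p.b0, p).to_numpy()
    mass_action = p.a * p.b0[p.prey_ix] * p.b0[p.pred_ix]
    assert np.allclose(q, mass_action, rtol=2e-6)


def test_donor_control_bound(wap_results):
    """Consumption on a link can never exceed the vulnerability flux v*B."""
    p = derive_sim_parameters(wap_results, xv=1.2)
    rng = np.random.default_rng(0)
    for _ in range(5):
        b = p.b0 * rng.uniform(0.2, 5.0, len(p.b0))
        q = compute_consumption(b, p).to_numpy()
        assert (q <= p.v * b[p.prey_ix] * (1 + 1e-12)).all()


def test_vulnerability_multiplier_bounds(wap_results):
    with pytest.raises(ValueError, match="exceed 1"):
        derive_sim_parameters(wap_results, xv=0.9)
    with pytest.raises(ValueError, match="exceed 1"):
        derive_sim_parameters(wap_results, xv=1.0)


def test_base_fishing_mortality(wap_results):
    p = derive_sim_parameters(wap_results)
    f0 = p.f0[p.names.index("Large krill")]
    assert f0 == pytest.approx(8.1 / 8126.0, rel=1e-9)
    assert np.count_nonzero(p.f0) == 1


def test_consumption_vanishes_with_either_side(wap_results):
    p = derive_sim_parameters(wap_results)
    eps = 1e-12
    l = p.link_index("Large krill", "Adelie penguin")
    b = p.b0.copy()
    b[p.names.index("Large krill")] = eps
    assert compute_consumption(b, p).to_numpy()[l] < 1e-6
    b = p.b0.copy()
    b[p.names.index("Adelie penguin")] = eps
    assert compute_consumption(b, p).to_numpy()[l] < 1e-6
    with pytest.raises(ValueError, match="positive"):
        compute_consumption(np.zeros_like(p.b0), p)


def test_saturation_in_predator_linear_in_prey(wap_results):
    """Doubling prey doubles intake (donor-controlled vulnerability flux);
    doubling the predator less than doubles it (arena saturation)."""
    p = derive_sim_parameters(wap_results)
    l = p.link_index("Large krill", "Adelie penguin")
    base = compute_consumption(p.b0, p).to_numpy()[l]
    b = p.b0.copy()
    b[p.names.index("Large krill")] *= 2
    assert compute_consumption(b, p).to_numpy()[l] == pytest.approx(2 * base, rel=1e-9)
    b = p.b0.copy()
    b[p.names.index("Adelie penguin")] *= 2
    ratio = compute_consumption(b, p).to_numpy()[l] / base
    assert 1.0 < ratio < 2.0


def test_monotone_vulnerability_response(wap_results):
    p = derive_sim_parameters(wap_results)
    l = p.link_index("Large krill", "Chinstrap penguin")
    fv = np.ones(len(p.q0))
    prev = 0.0
    for mult in (0.5, 1.0, 2.0, 4.0):
        fv[l] = mult
        q = compute_consumption(p.b0, p, fv=fv).to_numpy()[l]
        assert q > prev
        prev = q


def test_equilibrium_preserved_for_204_months(wap_results_zero_ba):
    sim = Ecosim(wap_results_zero_ba).run(months=204)
    assert ((sim.relative - 1.0).abs().max() < 1e-3).all()


def test_equilibrium_preserved_on_toy_web():
    """Equilibrium preservation holds for arbitrary balanced inputs."""
    from wapfoodweb import DietMatrix, GroupSpec

    groups = [
        GroupSpec("algae", "producer", biomass=None, pb=40.0, ee=0.5),
        GroupSpec("grazer", "consumer", biomass=50.0, pb=2.0, qb=10.0),
        GroupSpec("pred", "consumer", biomass=5.0, pb=0.5, qb=3.0),
        GroupSpec("mud", "detritus", biomass=100.0),
    ]
    dm = DietMatrix({"grazer": {"algae": 0.8, "mud": 0.2}, "pred": {"grazer": 1.0}})
    res = Ecopath(groups, dm).fit()
    sim = Ecosim(res).run(months=120)
    assert ((sim.relative - 1.0).abs().max() < 1e-3).all()


def test_humpback_ba_growth_rate(wap_results):
    """The accumulation surplus built into the balance drives ~3.9 %/yr."""
    sim = Ecosim(wap_results).run(months=13)
    hb = sim.relative["Humpback whale"]
    rate = float(np.log(hb.iloc[12] / hb.iloc[0]))
    assert rate == pytest.approx(0.039, abs=0.005)


def test_step_halving_convergence(recovery_bundle):
    b = recovery_bundle
    s4 = Ecosim(b.results, options=SimOptions(substeps=4)).run(b.scenario)
    s8 = Ecosim(b.results, options=SimOptions(substeps=8)).run(b.scenario)
    rel = ((s4.biomass - s8.biomass).abs() / s8.biomass).max().max()
    assert rel < 1e-4


def test_repeated_runs_are_identical(wap_results):
    model = Ecosim(wap_results)
    a = model.run(months=36).biomass
    b = model.run(months=36).biomass
    pd.testing.assert_frame_equal(a, b)


def test_effort_scales_fishing_mortality(wap_results_zero_ba):
    months = 60
    effort = MonthlyTimeSeries.constant(1.0, "1996-01", months)
    effort.values.iloc[12:] = 3.0  # triple effort after the first year
    scen = Scenario(applications=[], series={}, effort=effort, start="1996-01", months=months)
    sim = Ecosim(wap_results_zero_ba).run(scen)
    unforced = Ecosim(wap_results_zero_ba).run(months=months)
    assert sim.relative["Large krill"].iloc[-1] < unforced.relative["Large krill"].iloc[-1]
    assert sim.catch["Large krill"].iloc[20] > 2.5 * sim.catch["Large krill"].iloc[5]


def test_short_forcing_series_rejected(wap_results):
    short = MonthlyTimeSeries.constant(1.0, "1996-01", 12)
    scen = Scenario(
        applications=[
            ForcingApplication(
                series_id="x",
                mode="vulnerability",
                predator="Adelie penguin",
                prey="Large krill",
            )
        ],
        series={"x": short},
        months=24,
    )
    with pytest.raises(Exception, match="cover|horizon"):
        Ecosim(wap_results).run(scen)


def test_no_op_forcing_changes_nothing(wap_results_zero_ba):
    ones = MonthlyTimeSeries.constant(1.0, "1996-01", 48)
    scen = Scenario(
        applications=[
            ForcingApplication(
                series_id="ones",
                mode="vulnerability_and_arena",
                predator="Chinstrap penguin",
                prey="Large krill",
            )
        ],
        series={"ones": ones},
        months=48,
    )
    forced = Ecosim(wap_results_zero_ba).run(scen)
    plain = Ecosim(wap_results_zero_ba).run(months=48)
    assert np.allclose(forced.biomass.to_numpy(), plain.biomass.to_numpy(), rtol=1e-9)


def test_production_rate_mode_rejects_consumers(wap_results):
    ones = MonthlyTimeSeries.constant(1.0, "1996-01", 12)
    scen = Scenario(
        applications=[
            ForcingApplication(series_id="o", mode="production_rate", group="Myctophids")
        ],
        series={"o": ones},
        months=12,
    )
    with pytest.raises(Exception, match="producer"):
        Ecosim(wap_results).run(scen)


def test_relative_biomass_starts_at_one(wap_results):
    sim = Ecosim(wap_results).run(months=12)
    assert np.allclose(sim.relative.iloc[0].to_numpy(), 1.0)
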
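"""Sum-of-squares fitting, ablation, curve selection and Monte Carlo."""

import math

import numpy as np
import pandas as pd
import pytest

from wapfoodweb import (
    Ecosim,
    ObservationSet,
    Scenario,
    ablation_report,
    compute_ss,
    monte_carlo_sensitivity,
    select_response_curve,
)


@pytest.fixture(scope="module")
def short_sim(wap_results):
    return Ecosim(wap_results).run(months=60)


def obs_from(sim, group, years, transform=lambda v: v):
    annual = sim.annual_mean_relative()
    return [
        {"time": int(y), "group": group, "value": transform(float(annual.loc[y, group]))}
        for y in years
    ]


def test_exact_predictions_give_zero_ss(short_sim):
    rows = obs_from(short_sim, "Adelie penguin", range(1996, 2000))
    rep = compute_ss(short_sim, ObservationSet(pd.DataFrame(rows)))
    assert rep.total_ss == pytest.approx(0.0, abs=1e-20)


def test_scale_invariance_of_relative_series(short_sim):
    rows = obs_from(short_sim, "Large krill", range(1996, 2000), lambda v: 3.0 * v)
    rep = compute_ss(short_sim, ObservationSet(pd.DataFrame(rows)))
    assert rep.total_ss == pytest.approx(0.0, abs=1e-20)
    assert rep.per_series.loc["Large krill", "q"] == pytest.approx(3.0)


def test_symmetric_log_residuals(short_sim):
    """obs/pred = {e, 1/e} gives q = 1 and SS = 2 by hand arithmetic."""
    annual = short_sim.annual_mean_relative()
    rows = [
        {"time": 1996, "group": "Salps", "value": float(annual.loc[1996, "Salps"]) * math.e},
        {"time": 1997, "group": "Salps", "value": float(annual.loc[1997, "Salps"]) / math.e},
    ]
    rep = compute_ss(short_sim, ObservationSet(pd.DataFrame(rows)))
    assert rep.per_series.loc["Salps", "q"] == pytest.approx(1.0)
    assert rep.total_ss == pytest.approx(2.0)


def test_total_ss_sums_series(short_sim):
    rows = obs_from(short_sim, "Salps", range(1996, 2000), lambda v: v * 1.3) + obs_from(
        short_sim, "Myctophids", range(1996, 2000), lambda v: v * 0.7
    )
    rep = compute_ss(short_sim, ObservationSet(pd.DataFrame(rows)))
    assert rep.total_ss == pytest.approx(rep.per_series["ss"].sum())
    assert (rep.per_series["ss"] >= 0).all()


def test_non_positive_observation_rejected(short_sim):
    with pytest.raises(ValueError, match="non-positive"):
        ObservationSet(pd.DataFrame([{"time": 1996, "group": "Salps", "value": 0.0}]))


def test_monthly_observations_match_state(short_sim):
    val = float(short_sim.relative.loc[pd.Period("1998-06", "M"), "Salps"])
    rep = compute_ss(
        short_sim,
        ObservationSet(pd.DataFrame([{"time": "1998-06", "group": "Salps", "value": val},
                                     {"time": "1999-01", "group": "Salps",
                                      "value": float(short_sim.relative.loc[pd.Period("1999-01", "M"), "Salps"])}])),
    )
    assert rep.total_ss == pytest.approx(0.0, abs=1e-20)


# -- ablation ---------------------------------------------------------------


def test_ablation_empty_scenario(recovery_bundle, wap_results):
    empty = Scenario(applications=[], series=recovery_bundle.scenario.series,
                     start="1996-01", months=recovery_bundle.scenario.months)
    table = ablation_report(Ecosim(wap_results), empty, recovery_bundle.observations)
    assert table.empty


def test_ablation_ranks_true_application_highest(recovery_bundle):
    b = recovery_bundle
    table = ablation_report(Ecosim(b.results), b.scenario, b.observations)
    assert len(table) == 4
    top = table.sort_values("delta_ss", ascending=False).iloc[0]["application"]
    true_names = {"krill sea-ice driver", b.true_application.name}
    assert top in true_names
    # decoys must not rank first
    assert not top.startswith("decoy")


# -- curve selection --------------------------------------------------------


def test_selection_recovers_true_steepness(recovery_bundle):
    b = recovery_bundle
    sel = select_response_curve(
        Ecosim(b.results), b.truth_scenario, "Large krill", b.candidates, b.observations
    )
    assert sel.best is not None
    assert sel.best.params["steep"] == pytest.approx(3.0)
    assert len(sel.table) == len(b.candidates) + 1  # control included


def test_selection_is_order_invariant(recovery_bundle):
    b = recovery_bundle
    fwd = select_response_curve(
        Ecosim(b.results), b.truth_scenario, "Large krill", b.candidates, b.observations
    )
    rev = select_response_curve(
        Ecosim(b.results), b.truth_scenario, "Large krill", b.candidates[::-1], b.observations
    )
    assert fwd.best.params == rev.best.params


def test_empty_candidate_list_rejected(recovery_bundle):
    with pytest.raises(ValueError, match="empty"):
        select_response_curve(
            Ecosim(recovery_bundle.results),
            recovery_bundle.truth_scenario,
            "Large krill",
            [],
            recovery_bundle.observations,
        )


# -- Monte Carlo ------------------------------------------------------------


def test_mc_cv_zero_degenerates_to_baseline(recovery_bundle, wap_inputs):
    g, d, s = wap_inputs
    b = recovery_bundle
    mc = monte_carlo_sensitivity(g, d, s, b.scenario, b.observations, n=3, cv=0.0, seed=11)
    assert np.allclose(mc.trials["total_ss"], mc.baseline_ss, rtol=1e-12)


def test_mc_deterministic_under_seed(recovery_bundle, wap_inputs):
    g, d, s = wap_inputs
    b = recovery_bundle
    a = monte_carlo_sensitivity(g, d, s, b.scenario, b.observations, n=5, cv=0.05, seed=11)
    c = monte_carlo_sensitivity(g, d, s, b.scenario, b.observations, n=5, cv=0.05, seed=11)
    pd.testing.assert_frame_equal(a.trials, c.trials)
    assert a.n_rejected == c.n_rejected


def test_mc_only_balanced_draws_are_kept(recovery_bundle, wap_inputs):
    g, d, s = wap_inputs
    b = recovery_bundle
    mc = monte_carlo_sensitivity(g, d, s, b.scenario, b.observations, n=5, cv=0.05, seed=11)
    assert len(mc.trials) == 5
    assert mc.trials["balanced"].all()
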
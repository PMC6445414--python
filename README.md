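# wapfoodweb

Mass-balance and time-dynamic trophic modelling of the Western Antarctic
Peninsula (WAP) pelagic food web — CCAMLR Statistical Subarea 48.1, base year
1996 — for ecosystem modellers and fisheries scientists who want to explore
how the sea-ice regime structures krill (*Euphausia superba*) and its
predators.

The package implements, as reusable Python:

- **A static mass-balance solver** (Ecopath-style). For every group *i* the
  production balance

  `B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC_ij + Y_i + BA_i B_i`

  holds, where `EE` is the ecotrophic efficiency (fraction of production used
  within the system), `DC_ij` the fraction of predator *j*'s diet made of
  prey *i*, `Y` fishery landings and `BA` biomass accumulation. Exactly one
  of `{B, EE}` is unknown per group; unknown biomasses are solved as one
  linear system. Multi-stanza krill (< 24 / ≥ 24 months) is filled from the
  stable age distribution under von Bertalanffy growth (K = 0.440/yr) and
  total mortality Z = 0.8/yr. Trophic levels, predation mortalities, balance
  diagnostics and the mixed-trophic-impact matrix come with the solution.

- **The packaged 35-group WAP parameterisation** (`data/wap48_1/`): group
  rates, the full diet matrix, krill stanzas, efficiencies and a correction
  log. Producer biomasses are solved from EE = 0.5; humpback and fin whales
  carry biomass-accumulation terms (3.9 and 2.9 %/yr); only krill is fished.

- **A foraging-arena simulator** (Ecosim-style). Biomass dynamics follow
  `dB_i/dt = g_i Σ Q_ji − Σ Q_ij − (M0_i + F_i) B_i` with link consumption
  `Q = a v B_prey B_pred / (v + a B_pred)`: prey exchange into a vulnerable
  pool at rate `v` and are searched at rate `a`, calibrated so the unforced
  run preserves the mass-balance equilibrium exactly. Monthly environmental
  forcing (sea-ice index, open water, chlorophyll-a, seasonal predation
  rates) multiplies vulnerabilities, search rates, arena areas, producer
  production, or drives krill recruitment through response curves.

- **Calibration tools**: log-scale sum-of-squares fitting of relative-biomass
  series with maximum-likelihood scaling, per-application ablation tables,
  response-curve selection, and a Monte Carlo sensitivity routine (redraw
  B, P/B, EE at a fixed CV, keep balanced draws, record the total SS).

- **A synthetic-data module** that emulates the monitoring series the real
  calibration rests on (Palmer-style ice/open-water/chlorophyll, annual
  predator counts, sparse trawl surveys), so the whole pipeline is testable
  without external downloads.

## Worked example

```python
from wapfoodweb import build_wap_inputs, Ecopath, Ecosim

groups, diet, stanzas = build_wap_inputs()
res = Ecopath(groups, diet, stanzas).fit()
print(res.to_frame().loc[["Ice algae", "Small phytoplankton", "Small krill",
                          "Large krill", "Humpback whale"],
                         ["biomass", "pb", "qb", "ee", "trophic_level"]].round(3))
print(res.check_balance())

sim = Ecosim(res).run(months=204)   # Jan 1996 - Dec 2012, unforced
print("humpback relative biomass after 17 years:",
      round(float(sim.relative["Humpback whale"].iloc[-1]), 3))
```

prints

```
                       biomass     pb    qb     ee  trophic_level
Ice algae              306.593  50.00   NaN  0.500          1.000
Small phytoplankton  15023.745  75.00   NaN  0.500          1.000
Small krill           2893.091   0.80  6.51  0.355          2.100
Large krill           8126.000   0.80  3.57  0.899          2.103
Humpback whale           8.120   0.04  2.38  1.000          3.304
balance check: FAIL; EE > 1: Fin whale=1.030
humpback relative biomass after 17 years: 1.756
```

The solved producer biomasses and trophic levels reproduce the published
model (ice algae 306.67, small phytoplankton 15023.17, small krill 2893.07
t/100 km²; krill TL 2.10). Humpback whales sit exactly at EE = 1 because
their 3.9 %/yr recovery is built into the balance — the simulator turns that
surplus into ~3.9 %/yr growth (×1.76 over 17 years). The fin-whale flag is
expected: recomputed from inputs printed at two decimals, its efficiency
lands at 1.03 (see `docs/methods.md`).

A command-line interface mirrors the library:

```sh
wapfw balance --out balanced.csv     # solve the packaged WAP model
wapfw tl                             # trophic levels
wapfw synth --seed 3 --out data/     # synthetic environment + observations
wapfw simulate --scenario scenario.toml --out traj.csv
wapfw fit --scenario scenario.toml --obs observations.csv
wapfw mc --scenario scenario.toml --obs observations.csv --n 200 --cv 0.1
```

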
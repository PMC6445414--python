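# Methods

## The static mass balance

Each of the 35 groups is a biomass pool (t/100 km², stored internally per
100 km² as in the source tables). The production balance

    B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC_ij + Y_i + BA_i B_i

is closed by the energy constraint Q = P + respiration + unassimilated food,
checked as `(Q/B)(1 − u) ≥ P/B` per consumer (`u` = unassimilated fraction,
default 0.2 for consumers, 0 for producers/detritus). Net migration is fixed
at zero — the parameterisation includes none — but the field exists on
`GroupSpec` for generality.

Exactly one of `{B, EE}` is unknown per non-detritus group. Groups with
unknown biomass (the three producers, whose EE is fixed at 0.5 for this
strongly seasonal pelagic system) form a linear system because unknown-B
groups may consume each other; it is solved simultaneously
(`numpy.linalg.solve`), then the remaining efficiencies follow directly.
Negative or singular solutions are rejected with the offending group named.

Detritus is a single pool: inflow is unassimilated consumption plus
other-mortality flows of all groups (producers included); its EE is the
consumed fraction of that inflow (computed, not input); the surplus leaves
as export.

### Diet completion

The published diet matrix prints some entries as "<1%" and one column
(macrozooplankton) totals 85%. Completion rules:

- "<1%" markers share their column's shortfall equally, with per-entry
  overrides. The packaged WAP matrix pins the killer-whale and fur-seal
  trace entries (`wap.TRACE_DIET_VALUES`): the equal split would route
  visible predation onto the tiny emperor- and macaroni-penguin stocks and
  push their efficiencies far above the published ones; the pinned values
  keep each column sum unchanged.
- A shortfall in a column without markers goes to detritus rather than being
  renormalised. For macrozooplankton this is the only completion consistent
  with its published trophic level (detritus completion gives 2.56,
  renormalisation 2.66).
- Cannibalism is structurally rejected.

### Multi-stanza krill

Krill is one species in two stanzas split at 24 months, sharing Z = 0.8/yr
and von Bertalanffy K = 0.440/yr. On the monthly age grid, survivorship is
`l_a = exp(−Z a/12)` and body weight `w_a = (1 − exp(−K a/12))³`; stanza
biomass is proportional to `Σ l_a w_a`, anchored to the data-rich adult
stanza (8126 t/100 km²), which puts 2893 t/100 km² in the juvenile stanza.
The sums are evaluated in closed form (each term of the binomial expansion
of `w_a` is a geometric series, the final stanza's tail included exactly);
the test suite checks them against 2000-month brute-force summation at
1e-9. Juvenile Q/B scales with `Σ l w^{2/3} / Σ l w` (metabolic ⅔-power
convention); the packaged table uses the published 6.51 directly, the
scaling remains the default for unparameterised species.

### Known departures from the printed tables

- Other-euphausiid biomass is packaged as 14 800, not the printed 148 000:
  the producer balance reproduces the printed large-phytoplankton biomass
  (13 712) only under the correction (an order-of-magnitude transcription).
  Logged in `data/wap48_1/corrections.csv`; `apply_corrections=False`
  reverts it.
- Fin whales recompute to EE = 1.03 from the two-decimal printed inputs
  (predation 0.0081 + accumulation 0.124 against production 0.1284); the
  published table prints 0.98. The packaged inputs keep the printed values
  and `check_balance` reports the flag honestly rather than hiding it.
- Efficiencies recomputed from rounded inputs can differ from the published
  parenthesised values by a few percent for groups whose predation comes
  mostly from small printed fractions (fur seal 0.75 vs 0.72, large krill
  0.90 vs 0.97); the quantities the package treats as reproducible are the
  solved producer biomasses, the stanza biomass, the trophic levels, and
  efficiencies dominated by fully printed diet fractions.

## Forcing construction

- **Sea-ice index**: minimum monthly ice area per calendar year (the austral
  summer minimum falls inside the calendar year), scaled by the mean of the
  minima, repeated monthly. Mean one by construction; icier-than-average
  summers score above one.
- **Gap filling**: missing months take the long-term mean of that calendar
  month; a calendar month with no observations anywhere is an error.
- **Seasonal expansion**: an annual rate (leopard-seal predation on fur-seal
  pups) fills its season's active months (October–May, spilling into the
  next calendar year), zero elsewhere and before the first recorded season.
- **Response curves**: linear (`start`,`end` over the domain), sigmoid
  (`y_zero`,`y_base`,`y_end`,`steep`; the inflection is placed in closed
  form so the raw curve passes through `y_base` at the baseline), and an
  asymmetric Gaussian whose grid parameters (`sd_left`, `data_width`,
  `sd_right`, `mean`, `max`) are mapped into forcing units by width scaling
  — for the packaged parameters this yields the monotone-decreasing segment
  right of the mode. Every curve is normalised to 1 at the baseline forcing
  value (default 1.0 for mean-scaled indices) so the base year maps to an
  unforced equilibrium; inputs are clamped to the domain.
- Series applied as bare multipliers (no curve) are normalised by their
  horizon mean, since areas in km² are not dimensionless; `normalize='none'`
  passes raw values (used for already-normalised indices and for series with
  structural zeros such as the seasonal predation rate).

## The dynamic simulation

State advances monthly over 204 months (January 1996 anchor) with fixed-step
RK4 at 4 sub-steps per month (checked by step-halving: < 0.01% trajectory
change). Consumption per link is

    Q_ij = a v B_i B_j / (v + a B_j),

with `v = x_v q0 / B_i` and `a = v / (B_j (x_v − 1))` so the base state
reproduces `q0` exactly on every link. The vulnerability multiplier `x_v`
(default 2.0, configurable per link; values ≤ 1 are infeasible because the
vulnerable-pool flux could not supply the base consumption) interpolates
between donor control (`x_v → 1`: Q bounded by `v B_i`) and Lotka–Volterra
mass action (`x_v → ∞`: Q → `a B_i B_j`). Handling-time and feeding-time
factors exist as hooks and default to off. Forcing modes: `vulnerability`
(×v), `search_rate` (×a), `arena_area` (×v and ×a),
`vulnerability_and_arena` (vulnerability channel times the arena channel),
`production_rate` (producer production), `biomass_driver` (the production
term `g ΣQ` of a driven consumer; for the stanza species, its recruitment
flux — the process the ice regime acts on biologically).

Producers follow a saturating production curve `P(B) = r B/(1 + cB)` with
`P(B0) = (P/B) B0` and a maximum production rate of twice the base P/B, so
the unforced equilibrium is preserved and production forcing cannot trigger
unbounded growth. Fishing mortality is `F(t) = (Y/B0) · effort(t)/effort(0)`.

**Fast-turnover pools.** Detritus (~300/yr), microzooplankton (55/yr) and
the phytoplankton groups (50–75/yr) turn over far faster than the monthly
step allows an explicit integrator to follow (the stability limit of RK4 at
the default step is ~130/yr). Pools whose base loss rate exceeds 20/yr are
therefore updated at the moving equilibrium of their rate equation each
sub-step — closed forms for producers and detritus, a short fixed-point
iteration for fast consumers — the standard treatment for high-turnover
groups in this model family. At the base state every update reproduces the
base biomass exactly, so equilibrium preservation is untouched; the price is
that instantaneous budget closure holds only for the integrated (slow)
pools.

**Krill bookkeeping.** The two krill stanzas are advanced by monthly
age-class accounting instead of the ODE: each age class survives
`exp(−Z_s/12)` with `Z_s` the stanza's realised predation + other mortality
+ fishing at the current state, classes graduate at 24 months, and
recruitment is proportional to adult biomass (normalised so the unforced age
structure is stationary). Biomass drivers scale the recruitment flux. Each
run restarts from the base age structure. A floor of 1e-6 × base biomass
protects all states; excursions beyond 1e6 × base abort with a diagnostic.

## Fitting and calibration

Observed series are *relative* biomasses, so residuals are taken on the log
scale after maximum-likelihood scaling:

    r_t = log(obs_t) − log(q · pred_t),   q = exp(mean log(obs/pred)),

making the per-series SS invariant to any constant rescaling (a linear-scale
option exists). Annual observations are matched to the simulated annual mean
of relative biomass; monthly observations to the monthly state. Missing
years contribute nothing.

Ablation reruns the scenario with each forcing application singly removed
and reports `ΔSS = SS_without − SS_with`; applications that worsen the fit
but are retained (as the published model retains two) are flagged, and
additivity of effects is not assumed. Curve selection evaluates each
candidate plus a no-curve control and retains the candidate with the lowest
*total* SS — the retention rule the calibration describes; ranking by the
driven group's own SS is available (`criterion='group'`) but is much weaker
when that group's observations are the noisiest.

Monte Carlo sensitivity redraws biomass, P/B (stanza Z included) and the
input efficiencies from truncated normals (sd = cv × mean, cut at ±2 cv and
at physical bounds), re-solves the balance, rejects draws whose efficiencies
exceed the baseline's envelope `max(1, EE_base)` — without that allowance
the marginal fin-whale efficiency would reject every draw, cv = 0 included —
and records the total SS of each accepted trial's forced run. Deterministic
under a fixed seed; more than 10 n consecutive rejections abort.

## The synthetic data generator

`SyntheticScenario` emulates the structure of the real monitoring series:

- Monthly ice follows a sinusoid between a winter maximum (95% of the study
  area; many real winters saturate the grid) and summer minima that decline
  3 %/yr — roughly halving over 1996–2012 — with lognormal AR(1) anomalies
  (cv 0.35, persistence 0.6) giving the few-fold spread between icy and
  ice-poor summers; open water is the exact complement of a constant study
  area (Palmer-grid scale, 40 000 km²; forcing is relative so scale is
  immaterial). Chlorophyll cycles between 0.5 and 3 mg m⁻³ with lognormal
  noise and 15% missing months.
- Observations sample the simulated annual mean of relative biomass with
  multiplicative lognormal noise: CV 0.1 for counted vertebrates, 0.4 for
  acoustic krill densities (which vary by orders of magnitude), 0.2 for the
  sparse trawl-survey fishes (default survey years 1998–2012, six visits).

What passing tests on these data do show: the forcing machinery, the fit
metric, ablation, curve selection and the Monte Carlo routine behave
correctly on a system whose truth is known. What they do not show: that the
real WAP series are fit this well — the generator has no spatial patchiness,
no fishery concentration on preferred grounds, and its noise is exactly
lognormal and serially independent, none of which holds for the field data.

`make_recovery_scenario` is a designed identifiability experiment: truth is
generated with the published sigmoid krill curve (y_zero 0, y_base 1.5,
y_end 5, steepness on a 1–6 grid) driving recruitment from the sea-ice
index, plus one true link forcing (chinstrap–krill) and two open-water decoy
applications present only in the fitted scenario. Distinguishing adjacent
steepness values from 17 annual points is statistically impossible at the
acoustic krill CV of 0.4 (the noiseless SS gap between neighbours, ~0.1, is
smaller than its own sampling noise), so the bundle defaults to
survey-precision krill observations (CV 0.15, an explicit parameter); under
those conditions the grid search returns the generating steepness in 18 of
20 seeds.

## Problem sizes and numerical choices

Simulations run 35 groups × ~150 links × 204 months (sub-monthly RK4) in
well under a second, so the test suite runs the full calibration horizon
everywhere and the Monte Carlo tests use 12 trials per CV level; the
packaged routines accept the published 200. Balance residuals are enforced
to 1e-6 relative, stanza closed forms to 1e-9 against brute force, the
base-consumption calibration to 1e-9, equilibrium preservation to 0.1% over
204 months, and integrator convergence to 0.01% under step halving.

## Known limitations

- The source program's exact sub-monthly integrator, stanza update and
  internal curve grids are unpublished; trajectory-level agreement with its
  output is not claimed — the package is constrained instead by the
  equilibrium, limit and oracle properties above.
- The published fitted SS values (70.77 → 25.39 etc.) require the external
  observation series and an unpublished residual convention; they are out of
  scope by design.
- Whether "arena area" forcing scales `v` and `a` identically in the source
  program is unknown; here it multiplies both.
- Age structure exists only for krill; fleet dynamics, spatial structure and
  discards are not modelled.
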
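# Methods

## The bioenergetics engine

The engine is a daily-step Wisconsin mass-balance model. State is the fish's
total body energy `E` (J); each day the specific energy budget (J per g
predator per day) is

```
dE = EC − EF − EU − ER − ES
E(t+1) = E(t) + dE · W(t),     W(t+1) = weight_from_energy(E(t+1))
```

Carrying energy (rather than recomputing it from weight every morning) keeps
the daily balance exact to floating-point precision even where the piecewise
energy-density model is slightly discontinuous at its breakpoint; the weight
series is derived from the energy series and feeds only the allometric terms.

### Functional forms

All constants are data, loaded from per-species YAML files; the shipped sets
are the Fish Bioenergetics 4.0 defaults for lake trout (Stewart et al. 1983)
and Chinook salmon (Stewart & Ibarra 1991). Form selectors choose among:

- consumption temperature dependence `f(T)`: CEQ 1 exponential
  `e^(CQ·T)`; CEQ 2 Kitchell dome (exactly 1 at CTO, 0 at CTM, clamped to 0
  above CTM so warm spikes in synthetic series cannot abort a run); CEQ 3
  Thornton–Lessem double sigmoid, whose ascending and descending factors are
  0.98 at CTO and CTM respectively by construction;
- respiration: REQ 1 exponential with a swimming-speed activity multiplier
  (`VEL = ACT·W^RK4·e^(BACT·T)` up to the cutoff RTL, `RK1·W^RK4` above);
  REQ 2 dome with constant activity. Oxygen converts to energy at
  13 560 J/g O₂ (configurable);
- egestion: FEQ 1 proportional, FEQ 2 Elliott, FEQ 3 Elliott with the
  indigestible-prey correction `PE* = ((PE−0.1)/0.9)(1−PFF) + PFF`, where
  `PFF` is the ration-weighted indigestible fraction (0.033 for every prey in
  the shipped diets). `PE*` outside [0, 1] raises a range error rather than
  silently clamping — it flags a physiologically meaningless ration;
- excretion acts on the assimilated ration `C − F`;
- SDA is a fixed fraction of assimilated energy.

The diet enters only through two aggregates: the proportion-weighted mean
prey energy density and the weighted indigestible fraction. Diet is constant
within a run (one schedule per age-year would be the natural extension;
time-varying diet is out of scope). Predator energy density is re-evaluated
every day.

### Energy-density models

`ED(W) = α + β·W` (kJ/g) per weight segment. Body energy per segment is
quadratic, `E = 1000·W·(α + β·W)`, inverted in closed form
(`W = (−α + √(α² + 4βE̅))/(2β)` with `E̅` in J/1000, or `E̅/α` for β = 0).
Segment choice brackets the energy against each segment's energy range; the
adult segment wins ties at the breakpoint.

The printed lake trout equations (juvenile `2.21 + 0.00328·W`, adult
`6.74 + 0.000501·W`, break at 1627 g) are not exactly continuous at the
breakpoint, and freely fitted segments never are. Two consequences are
handled explicitly:

- if the adult segment's energy range starts *above* the juvenile's end (a
  gap, ~14 kJ for the packaged model), energies inside the gap map to the
  breakpoint weight, keeping the inversion continuous and monotone;
- if the fitted segments *overlap* in energy (adult ED lower at the break),
  year-end weight as a function of feeding rate has a genuine upward jump of
  a few grams at the crossing. The fit-to-weight solver detects a collapsed
  bisection bracket there and returns the nearest attainable feeding rate,
  guarded at max(1 g, 1% of target); a larger residual is still an error.

Continuity at the breakpoint is deliberately *not* enforced during fitting —
segments are fit freely and evaluated by weight range, matching how the
calibration data behave.

### Breakpoint regression

`fit_piecewise` profiles the breakpoint over every distinct observed weight
between the 5th and 95th weight percentiles (at least two points per side),
fitting both sides by ordinary least squares via prefix sums (O(n) over all
candidates) and keeping the split with minimal total RSS. Model selection
against the single line uses an F-style comparison with 2 extra parameters at
the chosen significance level (default 0.001); note the profiled maximum
makes this test anti-conservative under the null, which is acceptable here
because the decision defaults to the richer model only at a very small alpha.
The breakpoint's confidence interval is a pairs-bootstrap percentile interval
(default 1000 resamples). On n = 5000 synthetic samples with Gaussian noise
sd 1.76 kJ/g the estimator's bias is below 1% of the true 1627 g and the
99.9% bootstrap interval covers the truth in ≥ 95 of 100 seeded replicates
(both re-verified by the test suite).

## Thermal occupancy scenarios

The year has 365 days; leap days are dropped, and simulation day 1 is the
species' start date (April 1 for lake trout, September 1 for Chinook), with
day-of-year arithmetic wrapping modulo 365. A scenario is 13 node
temperatures at days 1, 31, …, 361, linearly interpolated to a daily cycle
(after day 361 the series runs linearly to the next cycle's first node) and
repeated every simulated year.

- **Observed**: tag records are averaged per individual and date, then across
  individuals per date, then across years per day-of-year (individual-first
  averaging keeps heavily sampled fish from dominating a day). Node k is the
  mean of available daily values within ±10 days of its mark, wrapping
  circularly; an empty window is an error naming the node.
- **Assumed**: node-wise `min(optimum, warmest available)`, where the warmest
  available temperature is an input vector (in practice a satellite surface
  climatology; here the synthetic surface cycle).

Spawning-related weight loss is not modelled.

## Feeding-rate fitting and the comparison

`fit_p_year` bisects the feeding rate on [0, 5] until the simulated end
weight is within 0.005 g of the target; the upper bracket grows geometrically
(1, 2, 4, 5) so the Elliott egestion form is not evaluated at absurd rations
unless the target demands it. A fish that starves to collapse during a
bracket probe counts as "end weight below target". p may exceed 1 (FB4
permits it); 5 is a hard cap. `fit_p_schedule` chains one fit per age-year.

`compare` assembles four result blocks: (a) feeding rates fitted to
weight-at-age under each scenario, paired by age; (b) the observed-fitted
rates projected under the assumed scenario — the final-weight percent bias;
(c) daily consumption for one adult year with fixed endpoints (lake trout
6573→6980 g, Chinook 9742→10 387 g), paired by simulation day over all 365
days; (d) lifetime consumption totals (Σ C·W /1000, kg), paired by per-age
annual totals. Percent bias is `100·(assumed − observed)/observed`; paired
t-tests are two-sided with df = n−1, and a zero-variance difference vector is
reported as degenerate rather than a number.

## Synthetic field data

The generators are pure functions of (parameters, seed) and emulate a large dimictic
temperate lake rather than any archived dataset:

- **Tag temperatures**: per fish, a seasonal sinusoid plus a piecewise-linear
  behavioural occupancy offset plus a per-fish intercept (sd 0.5 °C) plus
  AR(1) noise (day-to-day correlation 0.8, stationary sd 1 °C), truncated to
  [0, 30] °C; default 15 fish per species over 2014–2019. The lake-trout-like
  profile is cold-biased (≈3–7 °C) with a fall spawning excursion toward
  10 °C; the Chinook-like profile tracks near its 14.3 °C optimum with a brief
  summer peak just above it, a warm fall, and winters in ~4–6 °C deep water
  while the surface reads ~2 °C. Profile constants are illustrative.
- **Warmest available surface**: a deterministic asymmetric climatology
  (late-August 23 °C peak, long cold spring) given as control points — a
  symmetric sinusoid would overstate spring warmth and distort the assumed
  scenario.
- **Weight-at-age**: a von-Bertalanffy cube `W = W∞(1−e^(−k(a−t0)))³` with
  constants solved so the curves pass exactly through the survey anchors
  (lake trout 142 g at age 1, 6573/6980 g at 13/14; Chinook 200 g at age 0,
  9742/10 387 g at 3/4), optional Gaussian noise with isotonic repair, and an
  exact first-age anchor.
- **Lipid–weight samples**: log-uniform weights over the ED model's valid
  range, ED = model + Gaussian noise, lipid back-computed through the
  39.5 kJ/g conversion.

What passing tests therefore show: the *mechanics* (energy closure, fitting,
scenario construction, bias direction and machinery) are correct under
realistic, controlled conditions. What they do not show: agreement with any
particular lake's magnitudes — synthetic profiles lack detection gaps,
tag-loss, depth structure, interannual variability and diet seasonality, so
bias magnitudes are profile-dependent even though their signs are structural.

## Numerical choices and defaults

- Feeding-rate tolerance 0.005 g on end weight; ≤ 200 bisection iterations.
- Lipid-based ED estimates are rescaled to calorimetry multiplicatively
  (mean-matching percent), not additively.
- The "lipid × 39.5 kJ/g" conversion treats the measurement as a lipid
  fraction of wet weight; the Trudel form takes mg/g.
- CSV floats are written with 12 significant digits so write∘read is
  value-identical; malformed rows are rejected with 1-based line numbers.
- Energies are J throughout the engine; ED models are kJ/g and converted at
  the boundary. Temperatures °C, weights g, dates ISO-8601.
- Problem sizes in the shipped demo: 6 tag-years × 15 fish per species,
  n = 1200 lipid samples with 200 bootstrap resamples for the fitted
  lake trout ED model (the packaged single-segment model for Chinook,
  mirroring the absence of a meaningful breakpoint there); the
  breakpoint-recovery summary uses n = 5000 per replicate.

## Known limitations

- One individual per species; no population expansion, nutrient submodels,
  or contaminant accumulation.
- Diet and feeding rate are constant within an age-year.
- The assumed scenario depends on the surface-temperature input; with a
  different "warmest available" climatology the bias magnitudes (not the
  machinery) change.
- The F-test for breakpoint existence is anti-conservative after profiling;
  treat a marginal p-value near alpha with suspicion.
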
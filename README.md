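# thermoniche

Wisconsin fish bioenergetics under two thermal occupancy assumptions:
the **assumed** scenario (the species' lab-derived physiological optimum,
capped by the warmest temperature the habitat offers) versus the **observed**
scenario (the realized thermal niche, built from daily temperatures of tagged
fish). The package quantifies how much the choice of temperature input alone
biases lifetime growth and prey-consumption estimates — the quantities
fisheries managers take from bioenergetics models.

## The model

Daily growth follows the Wisconsin mass balance, all terms in J per g of
predator per day:

```
dE = EC − EF − EU − ER − ES
```

- `EC = C · ED_prey` — consumption energy, with realized consumption
  `C = Cmax(W) · p · f(T)`, `Cmax = CA·W^CB` the allometric maximum ration,
  `p` the feeding rate (fraction of maximum) and `f(T)` the temperature
  dependence (exponential, Kitchell dome, or Thornton–Lessem double sigmoid);
- `EF, EU` — egestion and excretion (Elliott forms with an indigestible-prey
  correction);
- `ER` — respiration (allometric, temperature-dependent, with a
  swimming-speed activity multiplier), converted by the oxycalorific
  coefficient 13 560 J/g O₂;
- `ES = SDA·(EC − EF)` — the cost of digestion.

Net energy converts to weight through a piecewise-linear predator
energy-density model `ED(W) = α + β·W` (kJ/g) per segment: body energy
`E(W) = W·ED(W)` is quadratic per segment, so weight is recovered from energy
in closed form. The packaged lake trout model has a juvenile/adult breakpoint
at 1627 g; the Chinook model is a single segment. Such models can also be
calibrated from lipid data: lipid→energy conversions (39.5 kJ/g lipid, or
`ED = 3.60 + 0.047·lipid`), mean-matching rescaling against bomb calorimetry,
and a profiled least-squares breakpoint search with a pairs bootstrap.

**Fit-to-weight** solves, by bisection on the engine, for the constant annual
feeding rate that reproduces survey weight-at-age; **fit-to-feeding-rate**
projects those rates under the other temperature scenario. The difference
between the projection and the weight-at-age reference is the bias induced
purely by the temperature assumption, summarised as percent differences
(positive = assumed exceeds the observed-scenario reference) and two-sided
paired t-tests.

All field inputs (tag temperatures, weight-at-age, lipid–weight data, surface
temperatures) can be generated synthetically with controlled ground truth, so
the full pipeline runs and is testable offline.

## Worked example

```sh
python examples/05_full_comparison.py
```

runs the packaged two-species comparison on synthetic field data
(seed 1) and prints:

```
lake trout
  final weight, observed scenario :      7344 g
  final weight, assumed projection:     12392 g (+68.7%)
  mean fitted p  assumed/observed : 0.442 / 0.504 (paired t=-15.33, p=1.05e-09)
  adult-year daily consumption    : +14.0% (paired t=+11.95)
  lifetime consumption asm/obs    : 153 / 84 kg

chinook salmon
  final weight, observed scenario :     10387 g
  final weight, assumed projection:      8626 g (-17.0%)
  mean fitted p  assumed/observed : 0.621 / 0.579 (paired t=+1.93, p=1.48e-01)
  adult-year daily consumption    : -16.5% (paired t=-17.19)
  lifetime consumption asm/obs    : 73 / 111 kg
```

Reading this: for the slow-growing, cold-dwelling lake trout profile the
optimum-temperature assumption is warmer than the fish's realized niche for
most of the year, so it needs a lower fitted feeding rate (0.442 vs 0.504)
and, holding the observed-fitted rates, projects a final weight 68.7% too
high and inflates consumption. For the fast-growing Chinook profile — which
tracks water warmer than the capped surface in fall and winter — the signs
reverse: the assumed scenario underestimates final weight by 17%.

Other examples cover single runs (`01`), feeding-rate fitting (`02`),
breakpoint calibration (`03`) and scenario construction (`04`). The same
pipeline is scriptable from a shell:

```sh
thermoniche run --seed 1 --out comparison_out
thermoniche synth --profile lake_trout --seed 1 --out data_out
thermoniche edfit --lipid data_out/lake_trout_lipid.csv --out ed.yaml
```

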
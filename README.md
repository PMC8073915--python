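# nightcross

Circadian flight timing and water-barrier crossing decisions in a
diurnally migrating songbird.

Purple martins (*Progne subis*) are fly-and-forage diurnal migrants,
yet their spring routes cross the Caribbean Sea and the Gulf of Mexico —
open-water barriers of up to ~1100 km that cannot be finished within 12
daylight hours. `nightcross` is an analysis pipeline for fixed-schedule
GPS tracking of this problem: it segments tracks into nominal 12-h day
and night flight intervals, measures the daylight available within each
interval, classifies flights over land versus water, builds the
covariates of the coastal route choice, and fits a Bayesian mixed
logistic model of the decision to cross or detour. A synthetic world
with known-truth decisions closes the loop so every stage can be
validated end to end.

## The model

At each coastal departure point (the last over-land fix before a bird
either launches a crossing or reorients), the decision is modelled as

```
logit P(cross_i) = β₀ + β₁·Tailwind_s(i) + β₂·Water:Land_s(i) + β₃·Night(i) + u_b(i)
u_b ~ Normal(0, σ²)
```

where *Tailwind* is the wind vector projected on the assumed optimal
crossing bearing (`u sinθ + v cosθ`, m/s, from 2.5° 6-hourly U/V
reanalysis-style grids), *Water:Land* is the crossing distance divided
by the shortest land-constrained circumnavigation (a visibility-graph
shortest path; values near 1 mean crossing saves little), *Night* flags
a nocturnal launch, and `u_b` is a per-bird random intercept.
Continuous covariates are scaled and centred. Priors are Normal(0, 5²)
on coefficients and half-Student-t(3, 0, 2.5) on σ; sampling is
adaptive Metropolis-within-Gibbs with split-R̂/ESS diagnostics via
ArviZ, and fit quality is summarised with Bayes R²
(`Var(π)/(Var(π)+mean(π(1−π)))` per posterior draw).

The supporting layers are: NOAA-equation sunrise/sunset (zenith
90.833°) with endpoint-based daylight overlap per 12-h segment,
haversine geodesy (R = 6371.0088 km), majority-rule land/water
classification along sampled great circles, and per-bird summary tables
(flight counts, distance and speed by phase × surface, 24-h maxima)
using the population-SD standard-error convention.

## Worked example

Generate a synthetic study system (two water bands of ~1000 and
~890 km, eleven birds on the field schedule mix, AR(1) winds) and run
the full pipeline:

```python
from nightcross import make_world, simulate_tracks, analyze_tracks

world = make_world(seed=1)
fixes, truth = simulate_tracks(world, seed=1)
res = analyze_tracks(fixes, truth["schedules"], world.mask, world.wind, seed=1)
print(res["fit"].summary().round(2))
```

```
            Estimate  Est.Error  l-95% CI  u-95% CI  Rhat  Bulk_ESS  Tail_ESS
Covariate
Intercept       0.86       3.22     -5.17      7.12  1.00    136.23    224.20
Tailwind        0.78       2.16     -3.66      5.09  1.01    175.27    278.44
Water:Land     -9.14       2.90    -15.33     -4.30  1.03    116.94    345.46
DayOrNight      0.38       3.62     -6.79      7.56  1.02    124.70    140.85
sigma_bird      1.58       1.39      0.05      5.05  1.01    534.45    823.61
```

The 22 synthetic departures split into 12 crossings and 10 detours; the
water:land ratio dominates the fitted decision (birds cross when the
crossing saves distance, and the measured ratio also separates the two
outcomes — see the measurement note in `docs/methods.md`), while the
tailwind and night terms straddle zero — the qualitative structure of
the route-choice problem. `truth` carries every generated decision
with its covariates, so recovery can be scored exactly
(`nightcross.simulate.recovery_experiment`).

The same analysis runs from files:

```
nightcross simulate --seed 1 --out fixtures/
nightcross run --fixes fixtures/fixes.csv --schedules fixtures/schedules.yaml \
    --mask fixtures/mask.geojson --wind fixtures/wind.nc --out results/ --seed 1
```

writing `segments.csv`, the three per-bird summary tables,
`departures.csv`, `model_summary.csv`, `bayes_r2.csv`,
`daylight_regression.csv`, `windrose.csv`, `bearings.csv`, posterior
draws and a run manifest. Reruns with the same config and seed are
byte-identical. Published per-bird summary tables for the eleven
tracked martins ship in `nightcross.datasets` for the group-level
arithmetic (e.g. the Florida birds' mean total migration distance,
5530.53 ± 474.66 km, recomputed from per-bird totals).

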
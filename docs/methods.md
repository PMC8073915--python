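# Methods

`nightcross` analyses the circadian structure of songbird migration from
fixed-schedule GPS tags: when birds fly by day versus by night, and what
drives the decision to launch a large open-water crossing rather than
detour around it over land. This note documents the models, the numerical
choices, and what the synthetic-data checks do and do not establish.

## Track model

Tags log 2–3 positions per day at fixed local clock times. Two slots
12 h apart (0600/1800 CDT or 0400/1600 EDT) bound the nominal *day* and
*night* flight intervals; the night interval opens at the evening slot.
Three-slot tags carry one extra fix mid-interval (0000 within the
1800→0600 night interval, or 1000 within the 0400→1600 day interval).
That interior fix refines the segment's path distance — the segment
distance is the great-circle path through recorded waypoints — but never
moves a phase boundary, so three-slot tracks stay comparable with
two-slot ones. Consecutive anchor fixes form a segment only when they
are 12 h ± 1 h apart; the tolerance absorbs fix-acquisition jitter and
is deliberately too narrow to merge two distinct scheduled intervals.
Larger gaps break the chain and are logged, never errors.

All times are UTC internally. Tag schedules use fixed daylight-time
offsets (CDT = UTC−5, EDT = UTC−4); daylight-saving transitions are
ignored because the tags themselves ran on fixed local labels.

Migration-period trimming removes leading and trailing *stationary
runs*: maximal runs in which every fix stays within 30 km of the run's
first fix and that span at least 3 days. Both thresholds are exposed in
the pipeline config. This is a heuristic stand-in for a judgment that
field studies usually make by eye; interior stopovers are never removed.

## Geodesy and solar computation

Distances are haversine great circles on a sphere of radius
6371.0088 km. At continental-migration scale the discrepancy against an
ellipsoidal geodesic is below 0.5%, far under the uncertainty introduced
by 12-h fix spacing, so the simpler spherical model is used everywhere
(including bearings, destination points, and path sampling).

Sunrise and sunset come from the NOAA solar-position equations (Meeus
series for solar longitude, declination and the equation of time) at
the conventional zenith of 90.833° (34′ refraction + 16′ solar
semidiameter), refined by one re-evaluation at the first-pass event
time. Accuracy is a fraction of a minute at mid-latitudes; the test
suite checks ten benchmark locations/dates against an independent
Astronomical Almanac low-precision implementation with bisection on
apparent altitude. Polar day and polar night are flagged explicitly.

Daylight within a 12-h segment is evaluated at the *endpoint* locations
(the only places the bird's position is known): a day segment takes the
overlap of its time span with [sunrise at the start location, sunset at
the end location]; a night segment sums the evening tail after its start
(until sunset at the start location) and the morning head before its end
(after sunrise at the end location), clipped to the segment duration.
Each event is the instance nearest the relevant endpoint time, which
resolves the date ambiguity of night segments spanning midnight. The
alternative reading — integrating daylight along the moving bird — is
not implemented; a minute-grid oracle in the tests quantifies agreement
of the endpoint-based rule with brute-force integration (within 2 min).

## Land/water classification and summaries

Water is a set of named polygons; everything else is land. A segment's
endpoint great circle is sampled every `step_km` (default 1 km) and each
step is attributed to the polygon containing its midpoint; the segment
is a *water flight* when the over-water fraction exceeds 0.5 (the
majority threshold is config-exposed, since whole-segment assignment is
a modelling choice rather than a measurement).

Per-bird summaries report counts, distance means and speeds by
phase × surface cell, plus the maximum distance within any 24-h window
of consecutive segments. **Standard errors use the population-SD
(divisor n) convention**, i.e. `se = sd_pop/sqrt(n)`. This differs from
the common n−1 sample convention; it is the convention under which a
single-flight cell prints "± 0.00", and it is applied uniformly.
Percentages round half away from zero. Speed aggregation over cells is
an unweighted per-segment mean.

## Departure points and route geometry

A *departure* is the last over-land fix before a decision at a water
barrier. Crossings are read off the classified track: each maximal run
of water segments is one crossing event, its departure the run's first
start-fix, its waterbody the polygon holding the majority of the run's
over-water kilometres. Detours are land fixes within 50 km of a water
polygon that blocks the bird's optimal direction for at least 100 km
along the ray, where the realized next bearing deviates from the
optimal by at least 60°. All three thresholds are config-exposed
(detour identification was a manual judgment in the field; these
defaults encode it conservatively). When one fix matches both patterns
the crossing wins — actual water entry dominates.

The crossing distance runs from the departure fix to the first
subsequent land fix on the *far side* of the waterbody — operationally,
the fix whose along-track projection on the optimal bearing reaches past
the barrier's exit edge, and from which the bird keeps moving within 90°
of the optimal bearing. For detours this measures the hypothetical
crossing the bird declined. A departure with no qualifying far-side fix
is excluded from the model with a logged reason, never silently dropped.

The circumnavigation distance is the shortest water-avoiding polyline:
a visibility graph over the two endpoints plus all water-polygon
vertices, with straight lon/lat edges tested against slightly eroded
(10⁻⁹°) polygons so boundary-hugging edges stay legal, weighted by
great-circle length, solved with Dijkstra. The water:land ratio is
crossing distance over circumnavigation distance; values near 1 mean
crossing saves little.

A known measurement property: for *detour* departures the hypothetical
crossing is measured to a realized fix on the bird's circumnavigation
route, which sits laterally off the optimal ray, so the measured
crossing distance (and hence the ratio) is inflated by roughly 10–40%
relative to the coast-to-coast crossing the bird actually declined. The
same inflation affects any fix-based measurement of a route not taken,
including the original manual procedure. Synthetic-world covariate
checks are therefore exact for crossings and looser for detours.

## The crossing model

The decision is modelled as a Bernoulli mixed logistic regression:

    logit P(cross_i) = β₀ + β₁·tailwind_s(i) + β₂·ratio_s(i)
                       + β₃·night(i) + u_bird(i),   u_b ~ Normal(0, σ²)

with tailwind assistance and the water:land ratio scaled and centred
(mean 0, sample SD 1, divisor n−1) before entering the model, and the
random intercept controlling for repeated decisions by the same bird.
Tailwind assistance is `u·sin θ + v·cos θ` with θ the assumed optimal
bearing per waterbody (Caribbean 270°, Gulf of Honduras 315°, Gulf of
Mexico 315°/0°/45° by destination); no airspeed enters the definition.
Winds are interpolated trilinearly (bilinear in space, linear in time)
from a 2.5°, 6-hourly U/V grid.

Priors are weakly informative: Normal(0, 5²) on coefficients and
half-Student-t(3, 0, 2.5) on σ. Genuinely flat coefficient priors are
fragile under the near-separation that a few dozen route choices can
produce; the Normal(0, 5²) prior is inert at plausible effect sizes
while keeping the posterior proper. A flat-coefficient variant
(`flat_priors=True`) is provided as a sensitivity diagnostic.

The sampler is adaptive Metropolis-within-Gibbs in a non-centred
parameterisation (u_b = σ·z_b): fixed effects and log σ move jointly
under a Haario-adapted multivariate normal proposal (target acceptance
~25%), log σ gets an extra single-site update, and all z_b update in
parallel with independent accept/reject (their conditionals factorise
over birds; target ~44%). Adaptation runs only during warmup (the first
half of the iterations), so retained draws come from a fixed kernel.
Defaults are 4 chains × 2000 iterations. Split-R̂ and bulk/tail ESS are
computed with ArviZ for every parameter, including each u_b. The
sampler has been cross-validated against an independent Gibbs sampler
(JAGS) on identical data and priors; posterior means agree to ~0.05 and
intervals overlap closely.

Bayes R² is computed per posterior draw from the fitted probabilities
π (including bird effects): `R²_s = Var(π)/(Var(π) + mean(π(1−π)))`,
with Var the sample variance over observations; the posterior mean and
2.5/97.5 percentile interval are reported.

The daylight regression is ordinary least squares of
`log(distance_km + 1)` on daylight minutes per phase; the +1 km offset
keeps zero-distance segments (birds that sat out a scheduled interval)
in the fit.

## Synthetic world

The generator builds a self-contained study system in real lon/lat
coordinates so every geodesic, solar and interpolation code path is
exercised: two rectangular east–west water bands ("sea", ~1000 km
north–south; "gulf", ~890 km) separating three land masses between 0–35°N
and 90–60°W, matching the 96.9–1107 km range of observed crossings; and a
2.5°, 6-hourly wind grid whose components are a configurable mean vector
(default u=−2, v=−1 m/s, broadly supportive-to-crosswise for northward
travel) plus AR(1) noise in time (ρ=0.75 per 6-h step, SD 2 m/s — the
persistence scale of synoptic winds) and small cell-level noise.

Eleven birds (the retrieved-tag count) migrate north on the field
study's schedule mix (7× 0600/1800 CDT, 2× 0400/1600 EDT, one of each
3-slot variant) over ≤60 days, with stationary wintering and breeding
clusters at both ends so trimming is exercised. Ground speeds are drawn
per 12-h interval: over land ~N(20, 3) km/h by day and ~N(4, 1.5) by
night; over water ~N(50, 10) by day and ~N(35, 8) by night, all clipped
to [20, 80] km/h over water — the scale of the tracked birds' land and
water speeds. A bird whose step would enter water stops just short of
the coast (10–25 km); at its next scheduled fix it faces the decision.
Crossing birds fly the optimal bearing at water speeds, continuing
through night intervals, and halt at the far coast; detouring birds
follow fixed over-land corridor waypoints around the band. Crossings of
the ~1000-km band therefore necessarily span a night interval, as the
real birds' large crossings did.

Decisions are drawn from the known logistic law with default
β = (2, 1, −2, −1) and σ_bird = 0.5. Covariates at a decision point are
the interpolated tailwind and the ratio of the coast-to-coast crossing
(along the optimal bearing, +10 km landing overshoot) to the
visibility-graph circumnavigation ending at the same landing point.
Because sequential simulation cannot standardise on a sample that does
not yet exist, `simulate_tracks` standardises these covariates with
fixed reference moments (tailwind −1.0 ± 2.5 m/s, ratio 0.40 ± 0.05,
centred on what the default geometry realizes) stored in the truth
record. The departure-level generator `simulate_departures` — used for
parameter-recovery checks — standardises on the realized sample exactly
as the inference does, so recovered coefficients are directly comparable
with truth on the standardized scale.

What the synthetic world does *not* emulate: curved coastlines (its
ratios concentrate near 0.4 rather than spanning to ~0.93 as real
bay-shaped barriers allow), fix loss and location error, foraging or
wind-responsive behaviour, and within-day movement structure. Passing
tests therefore establish that the pipeline's measurement and inference
machinery is correct under known truth — not that the behavioural
assumptions hold for real birds. Decisions also cluster at night
interval starts (a day-arriving bird waits at the coast until its next
scheduled fix, which is usually the evening one); the night covariate
still varies, but less evenly than in the field data.

## Validation scales and numerical choices

Parameter recovery of the crossing model is checked by
simulate-and-refit at n = 200 departures across 20 birds, 100
replicates at 4 chains × 2000 iterations: mean posterior estimates are
required within 0.5 of truth and 95%-interval coverage of at least
90/100 per coefficient. At this sample size the logistic likelihood
carries the usual away-from-zero small-sample bias (order p/n), which
the posterior inherits under weak priors; fixed-truth coverage of the
larger coefficients therefore sits slightly *below* its nominal rate
(high-80s to low-90s per 100), a property of the sample size rather
than of the sampler — at n = 800 the bias vanishes and coverage is
nominal. The daylight
regression is checked the same way at slope 0.013 log-km/min, n = 200,
residual SD 0.4. The full-pipeline check runs the default 11-bird world
end-to-end and requires ≥95% recall of generator-truth departures and
byte-identical artifacts on rerun under a fixed seed.

Other numerical details: surface sampling step 1 km (halving it moves
over-water kilometres by less than 4 steps); ray marching for barrier
extent at 5 km; circumnavigation polygon erosion 10⁻⁹°; wind
interpolation raises on any query outside the grid envelope, naming the
violated axis; `percent_of` rounds half away from zero; zero-distance
segments classify as land and are kept in the daylight regression via
the +1 km log offset. All randomness in the pipeline and generator
flows from a single integer seed.

## Known limitations

- Spherical geodesy and straight-chord visibility edges are adequate at
  100–10000 km scale but would need an ellipsoidal treatment for
  sub-kilometre work.
- Detour identification is threshold-based and its defaults encode one
  reasonable reading of a manual field judgment.
- The measured hypothetical-crossing covariate for detours is inflated
  (see above); comparisons of cross vs detour ratio distributions partly
  reflect this measurement asymmetry.
- The stationarity trimming rule is a stand-in for an unstated field
  procedure and can shave the first truly migratory fix when movement
  resumes inside the stationarity radius.
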
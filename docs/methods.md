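# Methods

## Model structure

`soildust` is an event-driven, population-based Monte Carlo model of
incidental soil and dust ingestion for ten child age groups (0–<1 m,
1–<3 m, 3–<6 m, 6 m–<1 y, 1–<2 y, 2–<3 y, 3–<6 y, 6–<11 y, 11–<16 y,
16–<21 y).  Each simulated person is assigned an age group that does not
change over the simulated year, samples personal values for every input
variable, and lives through eight synthetic diaries (weekday and weekend
for each season, weighted 91.25 × 5⁄7 and 91.25 × 2⁄7 days).  Annual
averages are the day-weighted means over the eight diaries; seasonal
averages weight each season's two diaries 5:2.  By construction the
day-weighted mean of the four seasonal averages reproduces the annual
average exactly, which the test suite asserts.

Core behavioural assumptions:

* dust is present in all indoor locations, soil in all outdoor locations;
* every awake, non-bathing diary event offers one hand-surface contact;
  an indoor contact is with carpet or bare floor with probability
  `p_home_soft` (default 0.5 each);
* children under one year have no ground-level soil contact (outdoors
  they are carried or in a stroller), so all their ingestion is indoor
  dust;
* sleeping and bathing events have no contacts; hand loadings persist
  across events and overnight, and are reduced only by mouthing (saliva
  removal), handwashing, and bathing — there are no other off-loading or
  re-loading processes;
* the pacifier pathway operates indoors while awake, for ages with a
  nonzero use probability (under 2 y); the 1–<2 y group additionally
  picks up soil on a pacifier dropped during outdoor ground-level play;
* males and females are pooled (no sex-dependent inputs).

## Input variables and scopes

Every variable is a parametric distribution per age group (`point`,
`uniform (min,max)`, `normal (mean,SD)`, `lognormal (GM,GSD)`,
`beta (α,β[,scale])`, or a bounded `exponential (min,mean,max)`), bound in
a TOML config with a sampling scope.  Per-person variables are drawn once
per child; per-event variables are redrawn on each relevant event.
Probability-valued per-event variables (`p_blanket`, `p_pacifier`,
`p_home_soft`) are Bernoulli checks: the probability is sampled once per
person, then every diary event flips a coin with that probability.  The
barrier factor `f_blanket` is fixed per person while blanket *use* is
re-decided per event, so the same child can be on and off the blanket
through the day.

Key defaults (all overridable; the bundled config flags reconstructed
entries):

| variable | value | note |
|---|---|---|
| `p_blanket` | U(0.8,1) <6 m; U(0,1) 6–<12 m; U(0,0.2) 1–<2 y; 0 older | |
| `f_blanket` | U(0.1,0.4), all ages | mean 0.25 ≈ 4-fold reduction |
| `pacifier_size` | U(8,11) cm² | |
| `pacifier_frac_hard` / `_soft` | 0.25 / U(0.25,0.5) | contacted fraction by floor type |
| `pacifier_transfer` | U(0.25,0.75), per event | |
| `pacifier_washing` | 0 (never washed) | conservative base case |
| `pacifier_drop` | N(8,3) <6 m; N(5,2) 6–<12 m; N(2,1) 1–<2 y, truncated ≥0 | drops/h awake |
| `p_pacifier` | U(0.8,1) <6 m; U(0.5,1) 6–<12 m; U(0,0.5) 1–<2 y (reconstructed); 0 older | |
| `adherence_soil` | 0 under 1 y; LN(0.055, 2.0) 1–<2 y; LN(0.11, 2.0) ≥2 y, mg/cm² | treated as a loading |
| `dust_home_soft` / `_hard` | LN(10, 3) / LN(2.5, 3) µg/cm² | reconstructed; carpet ≈ 4× hard floor |
| `hand_mouth_fraction` | 0.10 (young) declining to 0.03 (oldest) | 0.10 ≈ thumb-sucking |
| `hand_mouth_freq` | truncated normals peaking ~20/h at 1–<2 y | reconstructed |
| `object_mouth_freq` | 0 for 0–<1 m; peaks 1–<2 y; 0 from 11 y | indoor and outdoor separately |
| `object_mouth_area` | bounded exponential (1, 10, 50) cm², scaled down for <3 y | |

Units: surface loadings µg/cm², soil adherence mg/cm² (converted ×1000
inside the engine), per-event masses µg, daily roll-ups mg/day.

Several behavioural inputs (dust loadings, transfer/removal efficiencies,
hand areas, mouthing parameters) are not published as distributions; the
bundled values are documented reconstructions chosen at field-realistic
magnitudes and marked `note = "reconstructed"` in the config.  Absolute
ingestion magnitudes therefore depend on these defaults and should be
read as demonstration-scale; the structural results (zeros, linearity,
ratios, seasonal ordering) do not depend on them.

## Exposure equations

Pacifier (dust, indoors, awake, per event; all factors as sampled):

    dust_per_drop      = surface_dust_loading × pacifier_size × pacifier_frac × pacifier_transfer
    exp_pacifier_event = dust_per_drop × pacifier_drop × duration_h × (1 − pacifier_washing)
    exp_pacifier_daily = Σ events / 1000                            [mg/day]

`pacifier_frac` follows the floor-type coin (soft fraction on carpet,
0.25 on bare floor), and the landing surface's loading is the same
carpet/bare draw used for hand contacts in that event.  The blanket, when
in use, multiplies the surface loading.  The outdoor soil variant
(1–<2 y only) substitutes the adherence loading (µg/cm²) for
`surface_dust_loading × pacifier_transfer` and uses the soft contacted
fraction (ground treated as a soft surface).

Hand dynamics: an indoor contact moves the hand's dust loading toward
`effective_surface_loading × dust_transfer_hand` over the contacted hand
fraction — a saturating update, so repeated contacts approach but never
exceed that level; a soil contact sets the hand's soil loading to the
sampled adherence level.  Each mouthing ingests
`loading × one_hand_area × hand_mouth_fraction × saliva_removal` and
removes exactly that mass from the hand, so mass is conserved and
repeated mouthing without re-contact depletes to zero.  Mouthing counts
per event are Poisson with mean `frequency × duration` (awake events
only).  Handwashing and bathing multiply both loadings by
`(1 − removal fraction)`.

The object-to-mouth pathway uses the object dust loading, the sampled
object area, the dust-to-hand transfer efficiency (objects acquire floor
dust before mouthing), and saliva removal; for pacifier-using ages
(<2 y) the result is multiplied by 0.96 to avoid double-counting the
pacifier portion of object contacts.

## Random numbers and common-random-number pairing

One master seed is expanded into named substreams via seed-sequence spawn
keys: every (person, variable) pair, and every (person, day) diary and
engine stream, is independent.  Replacing one variable's distribution in
a scenario therefore leaves every other draw bit-identical, so
distribution-shift comparisons are exactly paired.  Percent changes are
ratios of population means; their standard errors come from the delta
method on the paired person-level values.  Truncated distributions sample
by rejection (cap 1000 tries, then clip), which preserves continuity;
because rejection consumes a variable number of draws, truncated
variables live in their own substreams and cannot desynchronize others.

The bounded exponential family solves its rate by Brent's method so the
truncated mean equals the stated mean; the test suite verifies the result
against direct numerical integration of the truncated density.

## Synthetic diaries

The diary generator emulates a time-activity diary database: contiguous
integer-minute events (1–60 min) covering exactly 1440 min, with sleep
(night plus age-appropriate naps), one bath, Poisson-counted handwashes,
seasonal outdoor play, and indoor play/other filling the remainder.
Age-specific budgets (sleep hours, nap minutes, outdoor fraction per
season, handwash rate) live in the config's `[diary]` section; weekends
get 1.3× the outdoor fraction.  Outdoor fractions rise from winter to
summer for every age, which produces the summer-over-winter soil
ingestion ordering the tests assert.

What the generator does *not* emulate: real demographic diary matching,
commuting/school microenvironments, day-to-day autocorrelation, or the
empirical activity distributions of any surveyed population.  Passing
tests therefore demonstrate the engine's behaviour under controlled,
realistic-magnitude schedules — not fidelity to any measured population's
time use.

## Summary statistics

Mean, SD (ddof 1), median, and 95th percentile (linear interpolation
between order statistics) are computed over all persons; GM and GSD over
strictly positive values with the zero count reported alongside
(`n_zero`), since soil ingestion contains structural zeros from diaries
with no outdoor ground time.  An add-ε alternative was considered and
rejected because it makes the GM depend on an arbitrary offset.

## Sensitivity analyses

The deterministic OAT base run fixes every variable at the analytical
median of its (truncated) distribution and evaluates the expected-value
form of the event chain on a fixed reference diary (hourly events, one
outdoor ground hour for soil-contact ages).  Probability-check variables
enter multiplicatively in expectation — a median Bernoulli would be
degenerate.  Low/high settings default to the 5th/95th percentiles of
each variable's distribution (configurable to min/max), oriented after
evaluation so the high/low exposure ratio is ≥1; a protective variable
such as blanket-use probability takes its *lower* percentile as the
high-exposure setting.  Bands: most sensitive >2, marginal 1.5–2, least
1.1–1.5, not ≤1.1.  Point-valued inputs (e.g. the bare/carpet coin's
probability in the default config) cannot vary between their own
percentiles and correctly screen as "not sensitive".

Distribution-shift scenarios rerun the full stochastic population with
one distribution replaced, under common random numbers, and report
100 × (base − scenario)/base of the mean.  For the pacifier pathway the
expectation is exactly linear in the washing mean, the transfer mean, and
the drop-rate mean (the realized truncated-normal mean, for truncated
specs), which the acceptance tests assert within three standard errors.

## Problem sizes

Population runs use 5000 persons per age group for production and for
the paired shift scenarios (the scale at which run-to-run stochastic
error is small relative to seasonal and scenario contrasts); the
structural-zero check uses 1000 newborns; unit and property tests use
populations of 40–500 and 10⁵-draw distribution checks.

## Known limitations

* Table-scale ingestion magnitudes depend on the reconstructed dust
  loadings and behavioural inputs; only structural and relative results
  are asserted.
* No chemical dosimetry, dermal uptake, or body-weight normalization.
* No soil/dust off-loading or re-loading beyond saliva removal; hand
  loadings can persist unrealistically through long non-contact periods.
* The hand-contact update is a saturating reconstruction of a transfer
  process whose detailed published form lives in prior model
  documentation, not reproduced here.
* One diary per (season, day-type) per person; within-season day-to-day
  variability is represented only across persons.
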
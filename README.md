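# soildust

Stochastic, diary-driven simulation of children's incidental soil and dust
ingestion, for exposure scientists and risk assessors who need age-resolved
ingestion-rate distributions (mg/day) rather than single point estimates.

Young children swallow measurable amounts of soil and indoor dust through
ordinary mouthing behaviour — hands that touched the floor, toys that were
mouthed, and, for infants, pacifiers that fell on the floor and went back in
the mouth.  `soildust` simulates a population of children in each of ten
age groups (0–<1 m through 16–<21 y), one full year per child, and reports
the distribution of daily soil and dust ingestion by pathway.

## The model

Each simulated child samples personal values for every input variable
(dust loadings, mouthing frequencies, transfer and removal efficiencies,
pacifier behaviour, …) from configured probability distributions, then
lives through synthetic 24-h activity diaries — one weekday and one weekend
day per season, day-count weighted to a 365-day year.  Events are walked
chronologically; hands pick up dust indoors and soil outdoors, mouthing
ingests and depletes the hand loading, and handwashing and bathing remove
it.  Three pathways are tracked separately for dust and soil:

* **hand-to-mouth** — per mouthing, `ingestion = hand_loading ×
  one_hand_area × hand_mouth_fraction × saliva_removal`, with the same mass
  removed from the hand;
* **object-to-mouth** — `effective_loading × object_area × transfer ×
  saliva_removal` per mouthing (reduced 4 % for pacifier-using ages, since
  the pacifier is modelled explicitly);
* **pacifier** (infants) — per diary event, indoors and awake:

  ```
  dust_per_drop      = surface_dust_loading × pacifier_size × pacifier_frac × pacifier_transfer   [µg/drop]
  exp_pacifier_event = dust_per_drop × pacifier_drop × event_duration × (1 − pacifier_washing)    [µg/event]
  exp_pacifier_daily = Σ exp_pacifier_event / 1000                                                [mg/day]
  ```

  For 1–<2 y children playing outdoors at ground level the soil-adherence
  factor replaces `surface_dust_loading × pacifier_transfer`.

A "blanket" (any barrier — crib, stroller, sheet) multiplies surface
loadings by the barrier factor `F_blanket` (uniform 0.1–0.4) with a fresh
use-probability check `P_blanket` on every event.  Children under one year
have no soil contact at all, so their soil ingestion is structurally zero.

Population outputs are the six statistics standard for exposure
distributions — mean, SD, geometric mean, geometric SD, median, and 95th
percentile — annually and by season.  Two sensitivity designs are built in:
median-anchored one-at-a-time high/low exposure ratios, and
distribution-shift scenarios run with common random numbers.

## Worked example

```python
from soildust import DistributionSpec, default_config
from soildust.sensitivity import base_run_at_medians, distribution_shift_run, oat_table

cfg = default_config()
print(base_run_at_medians("6m-<1y", cfg))       # 0.410 mg/day dust, all inputs at medians
print(oat_table("6m-<1y", cfg).head(4))
res = distribution_shift_run("6m-<1y", cfg, "pacifier_washing",
                             DistributionSpec("uniform", (0.05, 0.15)),
                             n_persons=500, master_seed=1)
print(res.percent_change)                        # ~10.0
```

prints (abridged):

```
          variable  low_exposure  high_exposure  ratio sensitivity
    dust_home_soft         0.168          1.880 11.164        most
         p_blanket         0.188          0.631  3.348        most
     pacifier_drop         0.254          0.569  2.242        most
 pacifier_transfer         0.300          0.520  1.733    marginal
```

Carpet dust loading, blanket-use probability, and pacifier drop rate are
the dominant drivers of infant dust ingestion (high/low exposure ratio
above 2 = "most sensitive"), and washing the pacifier after an average of
10 % of drops cuts mean pacifier-mediated ingestion by 10 % — the washing
fraction maps linearly onto the ingestion decrease.

The `examples/` directory has one short script per capability
(distributions/config, diary synthesis, single-day simulation, population
summaries, sensitivity); each prints what it computes and what the numbers
mean.  A thin CLI wraps the same API:

```sh
soildust simulate --age-group 6m-<1y --n-persons 1000 --seed 7 --out-dir out/
soildust sens --mode oat --age-group 6m-<1y
soildust sens --mode shift --scenario washing10 --n-persons 5000
```

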
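# colonyflux

Active and resting energetics of a breeding seabird colony, from
biologging data.

Central-place foragers such as the black-legged kittiwake (*Rissa
tridactyla*) shift how they spend their time — at the colony, on the
water, in flight — as breeding progresses from pre-laying through
incubation to chick rearing. `colonyflux` implements the full analysis
chain that turns raw tag data (3-minute GPS fixes plus 25 Hz tri-axial
acceleration) and blood hormone samples into stage-level energetics:

1. **Behaviour classification.** Per 15-s window, two observation
   streams are extracted: the dominant wingbeat frequency of the
   dorsoventral acceleration channel (with a spectral-dominance
   criterion for "no flapping") and a near/far colony-distance
   indicator (near: < 500 m). A 3-state hidden Markov model — states
   *flight*, *colony*, *water*; zero-inflated-gamma emissions for
   wingbeat, Bernoulli for near/far — is fitted by Baum–Welch and
   decoded by Viterbi.
2. **Time–activity budgets and activity DEE.** Each bird's decoded path
   gives its budget T = (T_flight, T_colony, T_water), and the
   activity component of daily energy expenditure is

   DEE_act = Σ_b MR_b · T_b,

   with activity-specific metabolic rates MR_b in ml CO₂ g⁻¹ day⁻¹
   converted to energy at 27.63 J per ml CO₂ (mass-specific result in
   kJ g⁻¹ day⁻¹). A calibration helper solves the three MR_b from
   stage-level DEE means when only those are published.
3. **Resting costs.** Free triiodothyronine (T3, pg ml⁻¹) — a proxy for
   resting metabolic rate — is averaged over each bird's paired blood
   samples.
4. **Space use.** Kernel utilization distributions of at-sea locations
   with isopleth areas (50/75/85/95 %), exported as GeoJSON.
5. **Stage statistics.** Linear models of budgets, DEE and T3 on sex
   and breeding stage, type III (interaction, sum-to-zero contrasts)
   and type II (main effects) ANOVA, least-squares means with
   Tukey-adjusted pairwise stage contrasts, and a paired t-test for
   tagging effects on body mass.

Because real deployments of this kind are rarely public, the package
ships a first-class **synthetic colony generator**: stage-structured
Markov behaviour sequences on the analysis window grid, state-dependent
acceleration signatures (flapping tone in flight, sub-hertz swell on
water), central-place out-and-back GPS trips, and stage-specific T3 and
sex-specific mass draws — all seeded and bit-reproducible, written in
the same delimited formats a tag logger produces.

Intended users: movement ecologists and biologging researchers who want
a tested, scriptable re-implementation of this analysis (or its pieces:
the HMM, the energetics conversion, the UD summaries) plus a generator
for power analyses and method checks.

## Worked example

Write a small config (4 birds per stage, 6-hour deployments) and run
the whole pipeline from the shell:

```python
import yaml
from colonyflux import ColonyConfig

cfg = ColonyConfig(n_birds={"pre_laying": 4, "incubation": 4, "chick_rearing": 4})
d = cfg.to_dict()
d["deployment_days_mean"] = d["deployment_days_min"] = d["deployment_days_max"] = 0.25
yaml.safe_dump(d, open("colony.yaml", "w"))
```

```sh
colonyflux all --config colony.yaml --seed 7 --outdir demo
```

The run writes raw logger files, per-window features, decoded state
paths, budgets, DEE, UD isopleths and a report, and prints (excerpt):

```
    pre_laying  T_flight: 0.219 +/- 0.120 (n=4)
    pre_laying   dee_act: 1.680 +/- 0.418 (n=4)
    incubation  T_flight: 0.408 +/- 0.093 (n=4)
    incubation   dee_act: 2.364 +/- 0.302 (n=4)
 chick_rearing  T_flight: 0.359 +/- 0.103 (n=4)
 chick_rearing   dee_act: 2.183 +/- 0.366 (n=4)

--- T_colony ~ sex * stage ---
type III (interaction): C(sex) p=0.6047; C(stage) p=0.04847; C(sex):C(stage) p=0.5751
type II (main effects): C(sex) p=0.4873; C(stage) p=0.02044
  LSM incubation - pre_laying: -0.2556 (SE 0.0717, Tukey p=0.01792)

Paired t-test, mass change over deployment: t(11) = 0.000, p = 1
```

Reading: with only four birds per stage the incubation birds of this
seed flew more (0.408 vs 0.219 of their time) and spent correspondingly
more energy (2.36 vs 1.68 kJ g⁻¹ day⁻¹) than pre-laying birds; the
least-squares-means contrast puts incubation colony attendance 25.6
percentage points below pre-laying. The paired t is exactly zero here
because the generator's default deployment effect on body mass is zero.
`demo/ud_areas.csv` holds the UD isopleth areas (e.g. 50 %: 20.8 km²,
95 %: 179.6 km² for this run); `demo/isopleths.geojson` the polygons.

Every stage is also available as a library call (`simulate_colony`,
`build_features`, `fit_em`, `compute_dee`, `kernel_ud`,
`fit_lm_anova`, ...) and as individual CLI subcommands
(`simulate`, `features`, `classify`, `energetics`, `ud`, `stats`).

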
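# ciclovia

Open-streets programs (*Ciclovía Recreativa*) temporarily close city streets
to motor traffic so residents can use them for recreation and physical
activity.  In highly segregated Latin American cities a natural question is
whether these programs are socially inclusive: do participants' journeys
actually traverse socioeconomic environments unlike the one they started
from?  `ciclovia` implements the full analytical pipeline behind that
question, for epidemiologists and urban-health researchers:

* **Urban segregation (evenness).**  For geographic units *i* with
  population *t_i*, metro population *T* and within-unit SES proportions
  *π_ri* over groups *r* (low/middle/high), the entropy score is
  *E_i = Σ_r π_ri log(1/π_ri)* and the Theil index is
  *H = Σ_i t_i (E − E_i) / (E·T)* ∈ [0, 1], with a quartile classification
  of normalized local entropy into highly segregated → highly integrated
  units.
* **Trajectory SES exposure.**  Participants are routed origin → destination
  by shortest path through the street network; trajectories are cut into
  500-m distance bands and joined to the population-weighted SES
  *percentile* of the units they cross.  Per SES-of-origin group the
  package reports band mean/variance profiles, the signed **maximum SES
  percentile difference** from the origin baseline (with the distance at
  which it is reached and a permutation p-value), trajectory length shares
  by SES, and route overlays by SES category and segregation class.
* **Survey harmonization and analytics.**  A codebook maps four
  city-dialect questionnaires (DANE strata 1–6, Chilean E/D/C3/C2/ABC1, a
  3-level Mexican coding, birthdate vs. age, WHO BMI cuts, WHO
  physical-activity guidelines, Likert safety…) into one schema, produces
  descriptive tables with Pearson χ² tests, and fits a two-level
  (participant-within-city) random-intercept logistic regression by
  adaptive Gauss–Hermite maximum likelihood.
* **Synthetic cities.**  The original survey/GIS data are not public, so a
  seeded generator produces cities with a controllable west–east SES
  gradient, lattice street networks, crossing or confined routes,
  population-weighted participants and raw city-dialect surveys whose PA
  outcome follows a logistic model with city random intercepts — every
  stage is testable end to end.

## Worked example

```python
import ciclovia as cv

cfg = cv.RunConfig(outdir="demo", seed=7,
                   city=dict(grid_rows=6, grid_cols=16,
                             gradient_strength=6.0, mixing_noise=12.0))
report = cv.run_all(cfg)
print(report["stages"]["entropy"]["summary"])
print(report["stages"]["exposure"]["summary"]["maxdiff"]["low"])
```

prints (abridged):

```
{'H': 0.7799, 'mean_e': 0.2114, 'sd_e': 0.2324}
{'baseline_percentile': 12.70, 'max_diff': 76.51,
 'distance_km': 7.75, 'p_value': 0.005, 'defined': True}
```

Read: this strongly sorted synthetic city is heavily segregated (Theil
H ≈ 0.78; mean normalized local entropy 0.21).  Participants whose home
units are dominantly low-SES start, on average, at the 12.7th SES
percentile; along their journeys on the gradient-crossing route their
500-m band exposure climbs until, 7.75 km from the origin, it exceeds the
baseline by 76.5 percentile points (permutation p = 0.005) — the route
lets them traverse much higher-SES environments than their origin.  The
same run writes `entropy.csv`, `trajectories.geojson`, `profiles.csv`,
`maxdiff.json`, `overlay.json`, `table3.csv` and `model_table4.json` under
`demo/`, and the equivalent CLI is

```bash
ciclovia run-all --config config.yaml --out demo --seed 7
```

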
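# stressnet

Bayesian-network analysis of longitudinal stress–injury cohorts in
athletes: instrument scoring, repeated-measures data preparation,
discrete and conditional-linear-Gaussian structure learning with
bootstrap model averaging, and likelihood-weighted conditional
probability inference — exercised end to end on a synthetic cohort
generator with a known ground-truth dependency structure.

## What is in here

| Module | Purpose |
| --- | --- |
| `stressnet.cohort` | Synthetic athlete cohorts (3 measurement time points + 1 remote injury report, post-baseline dropout, MCAR missingness in stiffness/HRV, over-dispersed life-event counts, logistic injury model) and IBI fixture recordings. |
| `stressnet.measures` | Scoring of the raw instruments: 69-item life-event survey (NLE/PLE/TLE), 51-item reinforcement-sensitivity questionnaire subscale sums, adaptive IBI filtering + RMSSD over the central 5-minute window, eight-site muscle-stiffness totals with a CV < 3% gate, six-stance balance error totals and limb asymmetry. |
| `stressnet.prep` | Bagged-tree imputation, cumulative + log-scaled life events, median-split discretisation (with Low/High span maps), the two-time-slice table and the standardised change-score table. |
| `stressnet.bn` | DAGs, blacklist/whitelist constraints, decomposable BIC scoring (discrete and CLG), Tabu search, parameter fitting (CPTs with Laplace smoothing; linear-Gaussian locals), bootstrap arc strengths and model averaging with 0.3/0.5 thresholds. |
| `stressnet.inference` | Markov blankets, likelihood-weighted conditional probability queries with Monte-Carlo standard errors, exact enumeration (test oracle), evidence-combination tables (±1 SD grids for continuous nodes), conditional sampling and conjugate Bayesian linear regression (normal(0, 5²) priors). |
| `stressnet.pipeline` / `stressnet.cli` | End-to-end orchestration of the two analyses with per-stage child seeds, run logs and plain CSV/JSON/DOT artifacts. |

## CLI

```sh
# simulate a cohort (351 recruited, 94 post-baseline dropouts)
stressnet simulate --n 351 --dropout 94 --miss-stiffness 0.0477 \
    --miss-hrv 0.1077 --effect-scale 1.0 --seed 17 --out cohort.csv

# build an analysis table
stressnet prepare --mode 2tbn --cohort cohort.csv --seed 17 \
    --out prepared.csv --disc-map maps.json

# learn a bootstrap-averaged network from a prepared table
stressnet learn --data prepared.csv --bootstrap 1000 --inclusion 0.3 \
    --significance 0.5 --seed 17 --out net.json --strengths strengths.csv

# query it
stressnet query --net net.json --target injured_1=injured \
    --evidence stiffness_1=High,balance_1=High --samples 100000 --seed 17
stressnet blanket-table --net net.json --target injured_1=injured --out table.csv

# or run either full analysis in one go
stressnet run-first  --out-dir artifacts --seed 17 --bootstrap 1000
stressnet run-second --out-dir artifacts --seed 17 --bootstrap 1000
stressnet report --out-dir artifacts
```

`run-first` chains: impute → cumulative/log life events → median split
→ two-slice layout → automatic blacklist (temporal order,
independent→explanatory, same-variable slice arcs, named explanatory
pairs) + life-event→injury whitelist → 1,000-bootstrap arc strengths →
averaged network → Markov blankets of the injury nodes →
single-variable and full cross-product query tables.

`run-second` chains: impute → standardised change scores with a
study-level any-injury outcome → CLG-aware blacklist → bootstrap
averaging → Markov blanket of the injury node → ±1 SD evidence grid →
conditional samples of the personality/HRV nodes → Bayesian linear
regression with interaction.

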
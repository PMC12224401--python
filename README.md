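# foodenv

Community food environment metrics and multilevel outcome models for urban
health research.

Where no registry of food retail exists, a points-of-interest (POI)
provider queried over a covering grid can stand in for one: search terms
from a qualitative inventory of food-outlet terminology are run at every
lattice point, the hits are cleaned and de-duplicated, and each named
establishment is classified into an outlet category (fruit/vegetable
store, fresh food retail, small food retail, supermarket,
ready-for-consumption, convenience store, fast-food chain, candy/ice-cream
shop) and a health group (most healthy / mixed / less healthy). Densities
per km², census-based population density and a composite social
environment index (SEI — z-scored sanitation, housing, employment and
education dimensions, averaged; higher = more favourable) are computed per
neighbourhood, and the association between establishment densities and
non-daily fruit/vegetable (FV) consumption is estimated with two-level
random-intercept logistic regression:

    logit P(y_ij = 1) = x_ij'β + u_j,   u_j ~ N(0, σ_u²)

fitted by maximum marginal likelihood with adaptive Gauss–Hermite
quadrature (15 nodes; σ_u = 0 reduces exactly to ordinary logistic
regression). Exposures are z-scored, so ORs are per 1 SD of density; the
Model 1→3 sequence adds individual (age, gender, education) then
area-level (population density, SEI) confounders, with AIC for structure
comparison.

Because the real data such studies use (commercial POI extractions, census
microgeography, national health surveys) are proprietary, the package
includes a first-class synthetic-city generator with known ground truth;
every stage is testable offline, and estimator calibration is checked by
simulation-recovery. See `docs/methods.md` for the full model and design
choices.

## Worked example

Run the staged analysis on the default study-scale synthetic region
(2,442 neighbourhoods in three cities):

```bash
python analysis/01_simulate_city.py --seed 1
python analysis/02_acquire_establishments.py
python analysis/03_classify_establishments.py
python analysis/04_neighbourhood_metrics.py
python analysis/05_survey_outcome.py
python analysis/06_fit_models.py
```

which prints, stage by stage (seed 1):

```
2442 neighbourhoods in 3 cities
52341 establishments (Concepcion: 7142, Santiago: 35323, Valparaiso: 9876)
1292 survey respondents in 315 neighbourhoods

237818 raw records from 66 terms -> 52341 unique establishments
registry has 52341; acquisition complete (set equality)

classified 50745 of 52341 establishments (97.0%); 1596 to review queue
  ready_for_consumption: 34388 (67.8% of classified)
  small_food_retail: 5670 (11.2% of classified)

median total density 36.0/km2; median popdens 10268/km2
social gradient: median total density 108.0 in SEI Q4 vs 12.0 in Q1

1292 records, 10 excluded -> 1282 analytic
non-daily FV prevalence: 16.7%

fitted 27 models on 1282 respondents in 315 neighbourhoods
     exposure            model1            model2            model3
density_total 1.26 (1.10, 1.44) 1.27 (1.10, 1.45) 1.51 (1.22, 1.88)
...
```

Reading the output: the grid query retrieves the full registry (the
covering-radius guarantee), 97% of establishments are classifiable with
the shipped term inventory, establishment density rises steeply across SEI
quartiles, and the fitted OR per SD of total density brackets the
generative truth (OR 1.20, σ_u = 0.5) within its sampling error — the
single-run estimate at n ≈ 1,280 carries an SE of ≈ 0.1 on the log-odds,
so replicated recovery (below) is the calibration check, not one run.

The same stages are available as a console tool
(`foodenv simulate|query|classify|metrics|outcome|model|run`) and as one
call, `foodenv run --config city.yaml --out run/`, which also writes a
reproducibility manifest with per-stage counts and conservation checks.

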
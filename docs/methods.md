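# Methods

## Scope and design

`foodenv` re-implements, as a tested pipeline, a community-food-environment
analysis workflow: acquisition of named food establishments from a
points-of-interest (POI) provider over a covering query grid, rule-based
classification into outlet categories and health groups, neighbourhood-level
density and social-environment metrics, and two-level random-intercept
logistic models linking establishment densities to non-daily fruit/vegetable
(FV) consumption.

The real inputs of such a study — a commercial POI extraction, census
microgeography and a national health survey — are proprietary. The package
therefore ships a synthetic-city generator that emulates their statistical
structure with known ground truth. Every claim the test suite makes is about
the pipeline's behaviour on data of that structure, not about any real city.

## Synthetic-city generator

**Neighbourhoods.** Each city is tiled with square cells (default 0.5 km,
area 0.25 km²) on a planar km grid; cities are separated by a 50 km gap so
bounding boxes never overlap. 2,442 neighbourhoods are split across three
cities with weights 1700/386/356. Population density is log-normal with
(μ, σ) = (9.25, 0.7) on the log scale, putting the median near 10,400
persons/km² with quartiles ≈ 5,800–15,200. Population is density × area
exactly. Four census dimension scores (sanitation, housing, employment,
education) are generated as `r·z(log popdens) + √(1−r²)·noise` with
r = 0.4, then given arbitrary per-dimension affine scales — the social
environment index (SEI) must be invariant to those scales, and the tests
check that it is.

**Establishments.** Per-neighbourhood counts are negative-binomial
(dispersion 1.2 — overdispersed, giving the heavy-tailed mean ≫ median
pattern typical of retail counts) with mean proportional to
`population · exp(g · SEI)`, normalized so the expected total equals
`establishments_per_capita · Σ population`. The default per-capita rate
0.006 yields ≈ 48,000 establishments for the ≈ 8M people implied by the
density distribution (the mean of the log-normal, e^{μ+σ²/2} ≈ 13,300/km²,
not its median, sets the total). The SEI gradient default g = 0.5 produces
a Q4-vs-Q1 median density ratio of roughly 3–9 across seeds, a strong
positive social gradient. The category mix defaults to the
ready-for-consumption-dominant pattern (≈ 66% ready-for-consumption, 11%
small food retail, 7–8% each convenience and supermarkets, small shares for
the rest). Each establishment gets uniform coordinates inside its cell, a
name composed from a category naming term plus a proper noun, and
provider-style primary/secondary type labels. Two deliberate imperfections
are configurable: `ambiguous_name_fraction` (default 0.03) of records get a
term-free name *and* an uninformative label (exercising the unclassified
path, targeting a ≈ 97% classification yield), and `fallback_name_fraction`
(default 0.10) get a term-free name with an informative label (exercising
the provider-type fallback). `label_noise` (default 0.05) swaps the primary
label for another category's label — a mislabel, not an information loss.

**Participants.** Respondents (default 1,292, emulating the survey intake
before exclusions) are assigned uniformly to a random subset of 319
neighbourhoods. Age is 20 + 70·Beta(1.2, 1.6) (median ≈ 49), gender is
female with probability 0.616, and 4-level education follows the mix
(10.7, 45.5, 30.8, 13.0)%. The binary non-daily outcome is drawn from

    logit P = β₀ + β_e·z(exposure) + β_age·z(age) + β_male·male
              + β_edu·low_edu + u_j,   u_j ~ N(0, σ_u²)

with defaults β_e = 0.18 (OR ≈ 1.20 per SD of neighbourhood total density),
β_age = −0.40, β_male = 0.60, β_edu = 0.20, σ_u = 0.5. The intercept default
−2.07 is calibrated (by numerical averaging over the default covariate mix
and random intercepts) so the *marginal* prevalence sits near 17.3%; with
all slopes and σ_u at zero, `logit(0.173) = −1.565` gives that prevalence
directly. Weekly fruit/vegetable day counts are back-filled uniformly over
the integer pairs consistent with the drawn outcome (daily ⇒ capped sum
= 7, i.e. f+v ≥ 7, 36 pairs; non-daily ⇒ f+v ≤ 6, 28 pairs). A 17/1292
missingness rate blanks one required item on a random subset, feeding the
exclusion stage.

What the generator does **not** emulate: real street networks or travel
access, spatially autocorrelated deprivation, informal/street vending,
provider coverage error (every registry record is retrievable), temporal
dynamics, or survey design weights. Passing tests therefore demonstrate the
pipeline's correctness and the estimator's calibration on clustered data of
this structure — not that any real-data estimate is reproduced.

## Acquisition

Query points form a regular lattice at `spacing` covering each city's
bounding box inclusive of edges (a spacing larger than the box still emits
corner and far-edge points). With `search_radius ≥ spacing/√2` the union of
radius-discs covers the box (half-diagonal argument); the tests verify this
by Monte-Carlo. The provider is queried for every term × point pair; a
failure is retried once, then skipped with a logged warning. De-duplication
keeps the first occurrence per provider id; records without an id merge
when their normalized names are equal and they lie within 25 m (two
same-name chain branches further apart stay distinct). Name normalization
is lowercase + Unicode accent folding + punctuation strip + whitespace
collapse, which makes "Almacén" and "almacen" equal. Distances are
Euclidean on planar-km data and haversine on lon/lat, selected by the
declared CRS flag.

## Classification

The inventory maps normalized terms to the eight outlet categories, with a
`match_kind` (name, provider_type, or both) and an integer priority (lower
= higher precedence). Name matching is word-boundary, never substring, so
"mercado" cannot fire inside "supermercado"; among multiple hits the
highest priority wins, ties broken by longest term then lexicographic
order, making multi-term names deterministic. If no name term matches, the
provider's primary then secondary labels are looked up against
provider-type entries; otherwise the record is `unclassified`. Unclassified
records count toward total density only and are emitted to a review-queue
CSV with their nearest-miss terms (difflib ≥ 0.75 similarity) — an
automatable surrogate for a manual review pass. The categories partition
into three health groups: {fruit/vegetable stores, fresh food retail} most
healthy; {small food retail, supermarkets, ready-for-consumption} mixed;
{candy/ice-cream, fast-food chains, convenience stores} less healthy.
Although the field sometimes counts "seven" outlet types, the working
enumeration here has eight labels under the three groups; the closed
eight-label enumeration is implemented. The shipped Spanish-language
inventory (~60 terms) is a stand-in, fully replaceable by CSV; with a
different inventory, category proportions will differ.

## Neighbourhood metrics

Point-in-polygon assignment uses an STR-tree; a point on a shared boundary
goes to the lexicographically smallest neighbourhood id (deterministic
tie-break; the convention is arbitrary but fixed). Densities are
count/area: the total includes unclassified records, category and
health-group densities do not, so Σ category densities ≤ total with
equality only when the residue is empty. The SEI z-scores each dimension
across the pooled analysis set (all cities on one scale — city-level
medians of one common index only make sense on a pooled scale), flips any
dimension declared deprivation-coded, and averages with equal weight.
z-scores use the population-SD convention (ddof = 0) throughout the
package. Quartile tables use linear-interpolation quantiles (numpy default,
type 7); heavy ties that collapse a cut point fall back to unequal bins
with a logged warning.

## Survey outcome

Records missing age, gender, education or either FV item are dropped, with
per-field counts logged; retained records are never altered. Weekly fruit
and vegetable days are summed and capped at 7; non-daily means a capped
total below 7. The capping semantics are applied verbatim: fruit on 4 days
plus vegetables on 3 counts as daily even if the days never coincide.
Education is carried both as the 4-level variable (descriptive tables) and
as the binary incomplete-secondary recode (models). Bivariate comparisons
use the uncorrected chi-square (including 2×2 — documented choice) and the
asymptotic, tie-corrected Mann–Whitney U.

## Mixed logistic estimation

The marginal likelihood of each group integrates the Bernoulli-logit
likelihood over u ~ N(0,1) scaled by σ_u. The integral uses adaptive
Gauss–Hermite quadrature: the integrand's mode û_j is found per group by a
damped Newton iteration (vectorized over groups via `np.add.reduceat`),
the curvature there sets the scale τ_j = (−g″)^{-1/2}, and the physicists'
Hermite nodes are recentred as û_j + √2 τ_j z_k with log-sum-exp
accumulation. Default 15 nodes; 1 node is the Laplace approximation.
Optimization is BFGS on (β, log σ_u), initialized at the plain-logistic
IRLS solution and log σ_u = log 0.5 — deterministic, no random starts.
Wald SEs come from the central-difference Hessian of the negative marginal
log-likelihood at the optimum (σ_u's SE by the delta method from the log
scale); CIs are exp(β ± 1.96·SE). AIC = 2k − 2ℓ with k counting fixed
effects (incl. intercept) plus the variance parameter. A fitted σ_u below
1e−4 is treated as a boundary solution: the model is refitted with σ_u
pinned at 0 (exactly ordinary logistic regression) and flagged. σ_u = 0
can also be requested directly via `fix_sigma_u`. Accuracy is verified
against dense-trapezoid integration (≤ 1e−6 on small instances), against
ordinary logistic regression at σ_u = 0 (≤ 1e−4), for 15-vs-25-node
stability (≤ 1e−4 relative) and against `lme4::glmer` (nAGQ = 15) run
through Rscript as an independent routine — the cross-check lives in the
test suite, never in the pipeline path.

The progressive sequence fits, per exposure (z-scored within the analytic
sample): Model 1 unadjusted; Model 2 plus z(age), male, low education;
Model 3 plus z(population density) and z(SEI). Reference levels are female
gender and completed-secondary-or-above education. All three models use
the identical analytic sample, so their AICs are comparable.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on compact regions (40–400 neighbourhoods,
10²–10⁴ establishments). The parameter-recovery study uses 100 replicates
(50 in the acceptance script) of n = 5,000 individuals in 250 groups with
β_e = 0.18, σ_u = 0.5 — large enough that the Monte-Carlo SE of the mean
estimate is ≈ 0.001 and Wald coverage is informative. The social-gradient
direction check uses 200 single-city replicates of 120 neighbourhoods. The
acceptance script's pipeline run uses the full default scale (2,442
neighbourhoods, ≈ 50,000 establishments, 1,292 respondents).

## Known limitations

* The query model assumes the provider indexes every establishment;
  coverage error and stale listings are out of scope.
* The classifier is vocabulary-bound: yields on real data depend entirely
  on the inventory supplied.
* Neighbourhood exposure is a cluster-level covariate; with ~4 respondents
  per neighbourhood the single-run exposure estimate at survey scale is
  noisy (SE ≈ 0.1 on the log-odds), which is why calibration claims rest
  on the replicated recovery study rather than one run.
* Wald intervals can undercover for σ_u near the boundary; profile or
  bootstrap intervals are not implemented.
* No survey weights, no spatial correlation beyond the shared intercept,
  no random slopes, no cross-level interactions.
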
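# Methods

This note documents the statistical machinery behind `hhci`, the conventions
chosen where several were defensible, and what the synthetic-data generator
does and does not emulate.

## The synthetic study region

The generator produces a contiguous planar map of municipalities (a
rectangular lattice with cells removed; the default 20×20 minus one cell
gives 399 units), a 37-column municipal table (two identifiers plus 35
covariates), adult populations by age decade, seven annual death-count
series, provider sites of three service types, and an origin–destination
travel-time matrix. Everything derives from one integer seed through a
single `numpy` generator, so equal seeds give byte-identical panels.

**Latent risk.** The adult log mortality rate is

    log r_i = log(r0) + Σ_k β_k x_ik^std + s_i,

where `r0` is the base rate (130 per 100,000 — a plausible ischemic-heart-
disease rate for a 20–79 population), the β are ten signed covariate
effects, and `s` is a simultaneous-autoregressive (SAR) field,
`s = (I − ρW)⁻¹ e`, `e ~ N(0, 0.25²)`, with `W` the row-standardized queen
contiguity matrix. The SAR form was chosen because it is the standard
device in disease mapping for inducing controllable spatial autocorrelation
with a single matrix solve; ρ defaults to 0.6, and ρ = 0.9 produces maps
clustered strongly enough that the global Moran test always hits its
permutation floor.

**Effect signs.** The planted β follow the sign structure reported for the
variable weights of the original index: aging rate, illiteracy,
family-health-strategy coverage, diabetic-consultation rate and IHD
morbidity positive; advanced and basic ambulances, GINI, hemodynamics
accessibility and myocardial scintigraphy negative. Magnitudes (0.08–0.27
on the log scale) were set so the covariate signal and the spatial field
have comparable variance — large enough for sign recovery, small enough
that spatial structure remains visible in the rates.

**Counts.** Stratum-year deaths are Poisson with expectation
`population × rate × age-relative-risk × year-noise`, truncated at the
stratum population. Age relative risks rise steeply over the six decades
(normalized to population-weighted mean 1); year noise is log-normal with
sd 0.08. Populations are log-normal (median 6,000 adults, log-sd 1.1),
spanning roughly three orders of magnitude so empirical-Bayes shrinkage is
visibly population-dependent — mirroring a state where ~90% of
municipalities are small.

**Collinearity.** Seven designated covariate pairs are engineered as affine
near-copies (noise-to-signal 0.3, |r| ≈ 0.96): income per capita ↔ human
development index, schooling pair, urbanization ↔ density, income ratio ↔
low-income share, cardiologist supply ↔ cardiologist accessibility,
employment pair, and an imaging-rate pair. Seven pairs (not some other
count) because the table always has 35 covariates and the downstream
contract expects 28 features after pruning. Pairs deliberately avoid every
β-carrying covariate so correlation pruning cannot delete planted signal.
With `n_duplicate_pairs < 7` the remaining pairs are drawn independently;
the column count stays 35.

**What is not emulated.** Real geography and road networks (travel times
are Euclidean distances over a nominal speed plus noise); temporal trends
and migration; measurement error in covariates; any dependence *between*
covariates beyond the engineered pairs. Passing tests therefore demonstrate
that the machinery is correct and that the diagnostics have power under the
assumed data-generating process — not that any particular real region would
reproduce the published coefficients.

## Rates

Age adjustment is direct standardization against the panel-wide age
distribution (configurable). The learning outcome is the 2009–2014-analog
mean of the annual adjusted rates; the penultimate and final years serve as
external validation series. All three series are smoothed with the Marshall
(1991) global empirical-Bayes estimator — the method behind the widely used
desktop smoother the original workflow cites by name only:

    b  = Σd / Σp                 (global rate)
    s² = Σ pᵢ(rᵢ − b)² / Σp      (between-area variance)
    a  = max(0, s² − b/p̄)
    wᵢ = a / (a + b/pᵢ),  θᵢ = wᵢ rᵢ + (1 − wᵢ) b

Smoothed rates are convex combinations of the raw and global rates; a
negative moment estimate truncates to full shrinkage. Since the smoother is
defined on counts, adjusted and period-mean rates are smoothed through their
implied pseudo-counts `dᵢ = rᵢ pᵢ`. Whether the original study smoothed
each year separately or the period mean is ambiguous; this package smooths
the period mean (one pass per outcome series), and single-year series are
smoothed the same way.

## Spatial statistics

Queen contiguity (any shared boundary point) is the default, rook is
available; weights are row-standardized, isolated units keep zero rows with
a warning. Global Moran's I uses the centered cross-product form;
inference is by random relabelling with 999 permutations and the
`(extreme + 1)/(M + 1)` pseudo p (floor 0.001), one-sided "greater" by
default because clustering is the hypothesis of interest. Local Moran
statistics use population-sd standardization so the mean of the local
statistics equals the global I; per-unit inference holds the unit fixed and
draws its neighbors as uniform subsets of the remaining values (conditional
permutation), reporting the smaller tail. Labels HH/LL/HL/LH come from the
(zᵢ, lag) quadrant, gated at α = 0.05 uncorrected — the source workflow
states no correction; Bonferroni/FDR can be applied by lowering α. Map
classes are empirical quantiles with stable-rank tie-breaking; fewer
distinct values than classes collapse with a warning.

## Accessibility

Plain binary-catchment 2SFCA with d₀ = 60 minutes, no distance decay — the
source describes fixed 60-minute buffers. Providers with empty catchments
get ratio 0 (warned). The published index is described only as "0 (poor) to
1 (ideal)", so normalization is min–max; in the degenerate all-equal case
the score is 1 everywhere (equal access read as ideal-relative) unless the
constant is 0, which stays 0 — both warn loudly. Note that raw 2SFCA scores
are *not* monotone in d₀: enlarging the catchment adds reachable providers
but also inflates every provider's demand denominator.

## Pre-processing

Fixed order: drop the two identifier columns → near-zero-variance screen
(frequency-ratio 95/5 and unique-fraction 10%, the conventional cutoffs of
the toolkit the original workflow names) → iterative Pearson pruning at
|r| ≥ 0.7, dropping from each worst pair the member with the larger mean
absolute correlation (ties: earlier column) → center/scale to mean 0, sd 1.
Scaling statistics are fitted once and reapplied unchanged to later data;
because the covariates are static across outcome years, this coincides with
global scaling here.

## Models and tuning

Eight regressors behind one contract. kNN, PCR (PCA + least squares), PLS
(NIPALS), and ε-insensitive linear SVR are the analytically transparent
core; random forest, bagged trees, gradient boosting and a Bayesian-style
regularized single-hidden-layer network (L2-penalized MLP, L-BFGS) are
adapters over scikit-learn/xgboost — their internals are not this package's
contribution. Hyperparameters are chosen by seeded 3-fold internal CV
minimizing RMSE over `tune_length` (default 10) candidates; the SVR cost C
is searched over random log-uniform draws in [1e-3, 1e2], matching the
random-search convention described for the original C selection, with
ε = 0.1·sd(y). The outcome is modelled on the smoothed-rate scale, so RMSEs
are in deaths per 100,000 and are comparable only within a given dataset.

## Evaluation and selection

`rmse_train` is resubstitution error on the training outcome; external
RMSEs compare the same predictions against the smoothed single-year
analogs. Proportionality = RMSE_train / RMSE_external; a model is flagged
**overfit** below the 0.7 floor — chosen to separate the published table's
robust rows (≥ 0.827) from its flagged rows (≤ 0.633) — and **underfit**
when the coefficient of variation of its predictions falls below 0.05
(a convention; the source describes underfitting only qualitatively).
Blocked cross-validation partitions the data into three equal blocks with
every block validating once per repartition; five repartitions give the 15
validation runs, and a `one_block` scheme supports the alternative reading
of "repeated 15 times".

Selection: the fit classification gates, then the lowest penultimate-year
external RMSE wins (ties: final-year RMSE, then name). Proportionality
disqualifies rather than ranks: ranking by proportionality alone would
systematically favor the most heavily shrunken fit, whose predictions — and
hence the index — track actual risk poorly. On the published table this
rule still selects the linear SVR. When a weight-free model (e.g. the
network) wins, the best linear-family model supplies the index weights,
with a warning.

## The index

PMRₙ = Σₖ Wₖ Cₖₙ + intercept (the formula's repeated first term is read as
the obvious W₁C₁ + W₂C₂ + … sequence), min–max scaled to MR_adj ∈ [0, 1],
and complemented: Iₙ = 1 − MR_adj. The maximum predicted rate maps to index
0 (highest risk) and the minimum to 1, exactly; a constant prediction
vector degenerates to index 1 everywhere with a loud warning. Risk strata
are five quantile classes of Iₙ (k configurable). The index uses the
training-period fit by default; refitting on the validated final year is a
flag away by passing that outcome series instead.

## Numerical conventions and problem sizes

Permutation counts default to 999 everywhere (floor p = 0.001); all
stochastic stages are seeded and deterministic. The test suite exercises
the full 399-municipality region for the generator round-trip, parameter
recovery (5 seeds) and the overfit-diagnostic power study (20 seeds), and
uses 25–50-unit fixtures where brute-force oracles are compared at 1e-9 to
1e-12. Known limitations: the conditional-permutation LISA p-values are
approximate by construction; the global empirical-Bayes smoother ignores
spatial structure (a local variant is out of scope); and the generator's
covariate marginals are conventions, not reconstructions of any real
distribution.
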
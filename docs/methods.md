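# Methods

`phytoland` implements a two-path analysis linking among-plant metabolomic
variation to the performance of an insect herbivore reared on those plants.
The data structure it targets: ~45 individual host plants, each
characterized by an LC-MS feature table (~163 compounds, "relative
abundance per dry weight": peak area normalized to an internal standard and
to sample dry mass) and three leaf traits (protein content, specific leaf
area, toughness); ~10 caterpillars reared per plant, each scored for
survival to adult, sex, days to eclosion, and adult weight (mg).

## Path 1 — reduce, then estimate

**Module detection.** Compounds are z-scored across plants (sample sd,
denominator n−1) and their Pearson correlation matrix is soft-thresholded
into a *signed* adjacency `a_ij = ((1 + r_ij)/2)^β`, β = 5 by default (a
`scale_free_fit` scan reports the fit index over a β grid and flags the
plateau). Adjacency is converted to topological-overlap (TOM)
dissimilarity and clustered by average linkage. The tree is cut statically:
among all merge heights below an absolute ceiling, the height maximizing
the number of clusters with at least `min_module_size` (default 5) members
is chosen; smaller clusters become module 0 ("unassigned"). Modules whose
first eigenvectors correlate above `1 − merge_cut_height` (default cut
0.25, i.e. correlation 0.75) are fused iteratively. Unassigned leftovers go
through a second clustering round whose new modules are appended with fresh
indices. Each module is summarized by its first eigenvector — the first
principal-component score of the z-scored member columns, scaled to unit
sample sd, sign-aligned to positive mean member correlation.

*Cut-height ceiling.* A pure max-cluster-count rule degenerates on
structureless data (near the tree root everything is one giant "module"),
so the search is capped at an absolute 1−TOM height, default **0.85**. The
default was calibrated against the package's own null generator: at 45
plants and 163 independent compounds, chance clusters of ≥ 5 compounds
complete above ≈ 0.85 (93% of 40 null datasets end fully unassigned),
while modules with within-correlation ≥ 0.6 complete well below (median
merge height ≈ 0.84). The ceiling is a parameter (`static_cut_height`),
and `use_topological_overlap=False` switches to clustering on
1 − adjacency; a dynamic-cut algorithm is a possible extension point.

**Feature selection.** Module eigenvectors plus z-scored traits enter a
lasso GLM per response — binomial (survival), Poisson (days), Gaussian
(weight) — with the penalty chosen by grouped cross-validation whose folds
are whole plants ("leave one plant and its caterpillars out"), because
plant-level predictors make caterpillars on one plant pseudo-replicates.
The chosen λ is the CV-deviance minimizer (not the 1-SE rule; a flag can
switch). Days models carry sex (0/1 dummy, not z-scored) and z-scored
adult weight as covariates; weight models carry sex and z-scored days;
survival models carry none (sex/days/weight are unobservable on dead
individuals). Each design matrix is re-standardized on the analysis sample
it actually uses (survivors-only models restandardize).

**Bayesian estimation.** The lasso-selected predictors are refit as a
Bayesian GLM under N(0, var = 100) priors per coefficient, sampled by
adaptive random-walk Metropolis-within-Gibbs: one univariate proposal per
parameter per sweep, scales adapted toward 0.44 acceptance for the first
2,000 sweeps and then frozen (preserving detailed balance thereafter).
Defaults are 2 chains × 10,000 sweeps with no burn-in discarded;
diagnostics (Gelman–Rubin PSRF, Geyer initial-positive-sequence ESS) run
on full chains, and a PSRF > 1.1 flags the result prominently rather than
failing. For Gaussian responses the residual sd carries a uniform prior on
(0, 10·sd(y)) and is updated on the log scale with the Jacobian term; the
scale factor is a knob (`sigma_prior_scale`). Confidence in a coefficient's
direction is its *sign probability*: the fraction of posterior samples
strictly on the posterior median's side of zero (0.5 if the median is
exactly zero).

**Validation.** `loo_validate` refits the reduced model once per plant
(point refit: maximum likelihood by default, posterior means by flag — the
two agree closely under these flat priors), predicts the held-out
caterpillars with their observed covariates, aggregates to per-plant means
(survival: predicted probability vs observed proportion), and correlates
observed with predicted across plants; 100·r² is the percent of
among-plant variation explained. Note an intrinsic property of this
procedure: under a pure-noise response the expected correlation is not 0
but slightly negative (≈ −(p+1)/n_plants, about −0.11 at 45 plants and 6
predictors), because the held-out plant is absent from every training
quantity. `random_module_null` asks whether randomly assembled compound
sets of the same sizes as the model's modules predict as well: each
resample draws disjoint random sets, computes their eigenvectors, refits
by maximum likelihood (full-MCMC refits would add nothing to a point
statistic at 1,000× the cost; a flag exists), and records in-sample
variance explained (R² for Gaussian, McFadden's 1 − dev/dev₀ otherwise —
the statistic is named in the output metadata). The exceedance fraction
counts resamples strictly beating the empirical statistic, with ties (and
float jitter below 1e-10) counting as not exceeding.

## Path 2 — estimate everything

All compounds enter one ridge GLM per response (same families, covariates
and plant folds). Uncertainty comes from a cluster bootstrap: whole plants
are resampled with replacement (row-level resampling by flag), the ridge
is refit 1,000 times at the CV-chosen λ, and a compound is "supported"
when its 2.5–97.5 percentile interval excludes zero. Degenerate binomial
resamples (all-survived/all-died) are redrawn and counted. Coefficients
are back-transformed to natural-scale deltas relative to the intercept:
`invlogit(b0 + b) − invlogit(b0)` for survival, `exp(b0 + b) − exp(b0)`
for days, identity (mg) for weight; "one unit" is 1 sd of the z-scored
predictor. Deltas are summarized per chemical class (median, quartile box,
Tukey fences, classes ordered by median survival effect) and the k = 15
largest |delta| among supported compounds are labeled (ties broken by
compound id). `cv_effect_association` correlates each compound's
coefficient of variation (sd/mean on raw abundances; zero-mean compounds
excluded) with its |effect|.

Pairwise interactions are screened by lasso on all p + p(p−1)/2 columns
(products of z-scored mains, re-z-scored so the penalty treats every
column equally), with the same plant folds and covariates as the
single-compound models. Class over-representation among surviving
interactions is tested by permuting class labels over compounds (10,000
permutations, two-sided add-one p); this formal test is an addition on top
of a comparison that is otherwise descriptive, and the output labels it as
such.

## Penalized solver

One solver covers lasso and ridge for all three families: outer IRLS
linearization with inner coordinate descent (lasso; active-set iteration
with full-sweep verification, numba-compiled with a numpy fallback) or a
direct weighted penalized solve (ridge). The objective is the *summed*
negative log-likelihood plus `λ|β|₁` or `λ‖β‖²/2`, intercept unpenalized —
so closed forms like `Σxy/(Σx² + λ)` hold exactly. Auto grids are
log-spaced from the smallest all-zero λ (nudged one part in 10⁹ above the
exact stationarity bound so the grid top is strictly null) down to 10⁻³ of
it (10⁻² when p ≥ n, where the tiny-λ tail is ill-conditioned and never
chosen by grouped CV). The λ = 0 limit matches an independent IRLS
implementation to < 1e-5, which the tests verify against `statsmodels.GLM`.

## Synthetic data

The generator is the package's test bed and defines its study conditions;
defaults mirror the target design: 45 plants × 10 caterpillars, 163
compounds in 14 modules (sizes 20…6, summing to 161, plus 2 free
compounds), within-module correlation 0.6. Compounds follow a
one-factor-per-module model on the log scale (`x = √ρ·z_m + √(1−ρ)·ε`,
then exponentiated to log-normal abundances), chosen over direct
covariance draws because it guarantees positive-definiteness and makes
module eigenvectors well-defined; correlations are targeted on the log
scale and module detection works on z-scores, so the marginal transform is
immaterial to structure. Outcomes follow the three GLMs with defaults
taken from the reporting scales of the target design: survival intercept
0.34 log-odds (≈ 58% survival), days intercept 3.48 log-days (≈ 32.5
days), weight intercept 10.36 mg, sex effects 0.06 log-days and 1.12 mg,
days-on-weight −1.41 mg/sd. Poisson days are truncated at ≥ 1 by
resampling (eclosion cannot take zero days). The weight noise sd default
(2.15) comes from the closed-form variance budget that puts the
days–weight correlation at ≈ −0.52 given the default effect sizes. Dead
caterpillars have explicitly missing sex/days/weight, never zeros.

What the generator does *not* emulate: mass-spectral intensity
distributions, ionization-response differences between compounds, missing
or censored peaks, compositional effects, or any relationship between a
compound's chemical class and its effects. Tests passing on this generator
show the algorithms recover the structure they assume; they are not
evidence about any particular real dataset.

## Numerical choices and degenerate inputs

Probabilities are floored at 1e-10 and linear predictors clipped at ±30
inside family evaluations; deviance terms with y = 0 take their 0·log 0 = 0
limit. Constant predictor columns are a typed error (no silent dropping).
Quantiles use linear interpolation throughout (so samples 1..100 give a
(3.475, 97.525) central interval). Cluster trees, eigenvectors, and
solver paths are deterministic given inputs; all Monte-Carlo stages take
explicit seeds, and the pipeline fans one global seed into per-stage seeds
via `SeedSequence.spawn` in a fixed stage order.

Problem sizes used by the test-suite simulations and the acceptance script
(e.g. 20 seeds for module recovery, 100 datasets for CI coverage, 200
resamples per null calibration, 2,500 MCMC sweeps for the coverage sweep)
are scaled to keep the whole suite conveniently re-runnable; every such
size is a parameter of the corresponding function.

## Known limitations

- The static tree cut is a deliberate simplification of dynamic hybrid
  cutting; on data with nested or unevenly sized modules the dynamic
  variant may resolve structure the static cut misses.
- The module count and unassigned-compound count on real data depend on
  `min_module_size`, β, and the cut ceiling; they are reported in the run
  summary, not treated as reproduction targets.
- Metropolis-within-Gibbs is adequate for the ≤ 10-coefficient reduced
  models it serves; it would mix poorly for high-dimensional or strongly
  correlated posteriors (no HMC is provided).
- The interaction scan at full scale (163 compounds → 13,366 columns) is
  the most expensive stage; `interactions.max_compounds` caps the scan to
  the most variable compounds when a faster run is wanted.
- LOO predictive correlations are slightly negatively biased under the
  null (see above); comparisons against the random-module null use the
  same procedure on both sides and are unaffected.
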
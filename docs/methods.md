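# Methods

This note documents the statistical machinery, the synthetic-data
generator's assumptions, the numerical choices, and the places where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Diets and intake accounting

A diet is a P:C ratio diluted with non-nutritive cellulose; every diet also
carries a fixed 4.055% block of lipids and micronutrients. The digestible
nutrient fraction is closed as

    nutrient = 1 − cellulose − 0.04055,

split between protein and carbohydrate in the P:C proportion. **Open
assumption:** source recipes do not state whether the micronutrient block is
inside or outside the cellulose dilution; this package treats it as outside
(a constant absolute fraction of dry mass at every dilution), because that
closure reproduces the stated compositions exactly. All downstream nutrient
masses inherit this convention.

Weekly intake is the dry-mass difference of the food dish before and after
feeding. Apparent negative consumption (a dish gaining weight, e.g. by
humidity) is clipped to zero and flagged rather than dropped, preserving
the week count; no desiccation correction model is attempted. Cumulative
(P, C) per animal is the componentwise sum over weeks, which places every
subject exactly on its diet's nutritional rail.

Ratios are rendered with the larger side first at two decimals
("3.14P:1C", "1P:6.72C").

## Body-size index

PCA on the **correlation** matrix of head width, pronotum width and
pronotum length (standardized traits), so eigenvalues sum to 3 and PC1's
variance share is eigenvalue/3. The covariance alternative would make the
share depend on measurement units; the correlation form is also the only
one consistent with a three-trait eigenvalue near 2.9 corresponding to a
~95% share. PC1's sign is fixed so all loadings are nonnegative (the score
increases with size). Measurer averaging is assumed to happen upstream.
Subjects with incomplete trait triples are excluded from the fit and
receive NaN scores. Sexes are pooled by default; per-sex PCA is available
by subsetting the input.

## Response surfaces

Each trait is regressed on {P, C, P², C², P·C} by OLS; per-term t tests,
R² and the overall F statistic come from the standard linear-model theory
(statsmodels backend). Collinear designs — e.g. all intakes on a single
rail — raise an error naming the offending term.

**Constrained optimum.** The fitted quadratic is maximized over the convex
hull of the observed intake points, not over the plane: a quadratic with
any non-concave direction has no finite unconstrained maximum, and even a
concave fit should not be extrapolated outside the sampled region. When
the Hessian H = [[2·bPP, bPC], [bPC, 2·bCC]] is negative definite and the
stationary point −H⁻¹(bP, bC) lies inside the hull, that point is reported
(flag `boundary=False`); otherwise the maximum over the hull edges is
found in closed form per edge (each restriction is a 1-D quadratic) and
flagged as a boundary optimum. A dense-grid oracle in the tests verifies
this logic. Using the exact hull rather than a visually extrapolated
triangle makes the constraint deterministic and auditable.

**Confidence region.** `confidence_region` draws `n_sim` (default 500)
coefficient vectors, maximizes each over the hull, orders the optima by
Euclidean distance from the point estimate after scaling each axis by the
draws' standard deviation (a scale-free depth), retains the central 95%,
and returns their convex hull. Two draw mechanisms are available:
`"coefficients"` (default) samples β ~ N(β̂, Σ̂); `"residuals"` resamples
residuals onto fitted values and refits. The reference procedure this
approximates is a packaged bootstrap whose internals are not fully
specified; both variants are exposed behind a switch and the default is
stated openly as a parametric approximation. The region's nominal
coverage is checked by simulation (200 replicates at n = 150, noise sd 12
on a surface with an interior optimum) in the acceptance tests; the seed
is fixed there. The random seed is a required argument (default
20241204), so regions are reproducible.

**Thin-plate-spline landscape.** The smoother solves the standard
penalized TPS system (kernel r²·log r, affine null space); duplicates are
averaged before solving. The penalty is chosen by GCV,
n·RSS(λ) / (n − edf(λ))², computed from the eigendecomposition of the
projected kernel; `smoothing=0` interpolates exactly, and affine data are
reproduced exactly at any penalty (null-space property). Predictions are
masked outside the data hull — no extrapolated cells are rendered.

**Multiplicity.** Model-level p-values across a family of m surface fits
use the Benjamini–Yekutieli step-up rule with c(m) = Σᵢ 1/i, which is
valid under arbitrary dependence among the tests (the per-sex and pooled
fits share data). The development-time surface's "optimum" is reported
identically to the others but labelled undesirable: it is the intake that
*slows* development.

## Survival and development models

Two event definitions share one machinery: development (event = adult
eclosion; death is treated as censoring at the death day — an
interpretation, since an animal that died can no longer eclose) and
survival (event = death; lost animals and survivors are censored).

Fits maximize the Cox partial likelihood with the **Efron** tie
approximation (lifelines backend; ties are expected with thrice-weekly
monitoring, and Efron is the conventional default). Categorical predictors
are dummy-coded against declared references (3P:1C, low cellulose), so the
reference hazard ratio is 1 by construction. Constant columns are dropped
with a rank warning; very large standard errors trigger a separation
warning. Block chi-square tests are likelihood-ratio tests against the
model without that block.

**Episode splitting** cuts each subject's follow-up at 7 and 14 days
(final cutpoint 153, the study horizon), labels episodes by interval, and
carries the event only on the final episode. Total follow-up is conserved,
and when a covariate's coefficient is shared across intervals the partial
likelihood is unchanged — both are tested. Crossing cellulose with the
interval label gives one cellulose coefficient per interval, which is how
strong early-life dilution effects are represented without violating
proportional hazards. A proportional-hazards diagnostic is available from
the underlying fitter but is advisory only.

**Model selection.** Candidates are compared by AIC = −2·logPL + 2k.
Akaike weights are normalized over the full candidate list; models with
ΔAIC ≤ 4 are retained; then the nesting rule removes any retained model
whose term set strictly contains that of a retained model with lower AIC.
The phrase "rejecting models with ΔAIC < 4" in the source methods
contradicts itself as written (it would reject the best model); the
standard reading — retain ΔAIC ≤ 4 — is implemented.

Censoring day for lost animals is taken as the last observed day as given
in the input; whether the original study censored at last-seen or at the
horizon is unstated.

## Yield metric

yield = mass × proportion surviving / days to adulthood, per P:C ratio
pooling cellulose dilutions; mass and days average adults only, while the
proportion surviving counts survivors of *all* enrolled subjects
(replacements included), adults and still-alive juveniles alike, with a
binomial standard error. This denominator choice follows from the printed
summaries themselves: adult counts divided by adults-plus-deaths do not
reproduce the printed proportions, while a survivors-of-all-enrolled
reading is consistent with them. The standard error uses the
product/quotient propagation formula on relative errors and the CI fixes
the critical value at 1.96. Display rounding is two decimals, three when
the magnitude is below 0.1. A diet with zero adults yields a flagged row
with NaN mass/days rather than an error.

Because the published inputs to these formulas are themselves rounded to
print precision, recomputed yields can differ from printed ones by up to
one display unit, and one published CI endpoint (the most
carbohydrate-biased diet's lower bound) differs in the third decimal from
what the stated formula gives on the printed inputs; the formulas are
implemented exactly as stated and the discrepancy is surfaced by the test
suite rather than absorbed.

## Choice experiment

Both dishes share the 45% cellulose dilution, so a dish's nutrient content
is its dry mass × 0.50945 and the cumulative P:C ratio equals the ratio of
dry-mass totals. Group tests transform the per-animal ratios (log10
pooled, square root males, inverse females — the transforms that met
normality in the source analysis), run a one-sample t against the
transformed 1:1 expectation, report the back-transformed mean, and attach
a Shapiro–Wilk check. Zero within-group variance is flagged as degenerate
rather than reported as t = ∞. Note that with a mean ratio above 1 this
statistic is positive; the source's reported pooled t is negative at a
mean ratio of 1.05, which cannot be reconciled with the stated procedure
and is not chased.

**Consumption model.** Weekly amount eaten per dish is modelled as
Gamma with a log link; fixed effects always include week, food type, sex
and week-1 body size, and the nine candidates vary the interactions (all
subsets of the three two-way interactions, plus the full model with the
three-way). The random intercept per animal is integrated out by
Gauss–Hermite quadrature (25 nodes by default) so the log-likelihood is a
true marginal ML quantity and AIC selection is well defined; no installed
Python package provides a Gamma GLMM with ML/AIC, so this routine is part
of the package (`nutrigeom.glmm`), and its σ → 0 limit is cross-checked
against an ordinary Gamma GLM. A `backend="glm"` shortcut fits that limit
directly — appropriate when between-animal heterogeneity is known to be
absent, as in the default generator. Zero amounts under the log link are
replaced by half the smallest positive observation and flagged; the
substitution is reported, not silent. Group-phase feeding (amount /
animals / days) is provided as a descriptive summary only.

## Synthetic-data generator

The generator reproduces the *design* and the *statistical structure* the
analysis assumes, with every parameter explicit in `SimConfig`:

- 7 P:C ratios × 3 cellulose dilutions × `n_per_diet` = 20 animals, up to
  22 weeks, horizon 153 days; deaths before day 14 are replaced
  recursively, and both the dead and the replacements are retained, so
  enrolment grows beyond the 420 slots as it does on the bench.
- Weekly dry intake is lognormal (σ = 0.30) with a median growing 20% per
  week until a plateau at week 10 — appetite data at weekly resolution are
  not published, so this growth curve is a placeholder chosen to land
  cumulative intakes on the scale of the published landscape coordinates
  (≈ 0–1 in the printed units).
- Mortality is piecewise-exponential on 0–7 / 7–14 / 14–153 days with
  baseline 0.012 d⁻¹, cellulose-interval multipliers (medium 1.89 and
  high 2.74 in week 1; high 6.05 in week 2) taken from the published
  hazard ratios, and per-diet multipliers backed out of the published
  per-diet survival proportions and development times (e.g. 1.45 for
  8P:1C). Death competes with eclosion: whoever fires first fixes the
  fate. A 3% uniform loss process generates censoring.
- Days to adulthood are Normal per diet (means from the published table,
  sd 12 d, truncated to [21, 150]).
- Adult mass and a latent size scalar are known quadratics of cumulative
  (P, C) — mass peaking 135 at (0.532, 0.165), size at (0.546, 0.174) —
  plus Gaussian noise (sd 15 and 0.4). Three morphometric traits are
  affine in the latent size plus independent noise (sd ≈ 0.1 mm), sized so
  PC1 carries ≈95% of standardized variance.
- The choice generator draws each animal's weekly protein-dish share from
  a Beta around its sex's target ratio (male 1.38, female 1/1.15,
  concentration 400), total consumption lognormal and growing, dish sides
  alternating (exactly balanced), and thins survivors to a configured
  adult count (34 of 60).

Randomness flows from one seed through per-subject substreams
(`SeedSequence` keyed by diet, slot and replacement depth), so datasets
are byte-identical for a fixed seed regardless of iteration order.

**What the generator does not emulate** — and therefore what passing tests
do *not* establish about real data: compensatory feeding and
appetite–state feedback, container microclimate, parental/batch effects,
measurement error in dish weighing (beyond the clipping rule), sex
differences in the no-choice traits, overdispersed or heavy-tailed trait
noise, and informative censoring. The quadratic trait truth also goes
negative at extreme carbohydrate intakes, a known artifact of quadratic
response surfaces rather than a biological claim.

## Numerical choices and problem sizes

- OLS optimum search tolerances: hull membership 1e−9; interior optimum
  preferred when within 1e−12 of the best edge value.
- Cox fits: Efron ties; the whole-vs-split likelihood identity is asserted
  to 1e−6 (the two lifelines fitters stop at slightly different gradient
  norms); the brute-force partial-likelihood oracle agrees to 1e−10 on
  ≤ 8-subject tie-free instances.
- Gamma GLMM: Nelder–Mead then BFGS on (β, log σ, log ν), 25-node
  Gauss–Hermite; started from the Gamma GLM solution.
- TPS/GCV: 49-point geometric λ grid over [1e−10, 1e2] plus exact
  interpolation; kernel eigenvalues clipped at zero (conditional PSD).
- Calibration runs: coefficient-CI and region coverage use 200 replicates
  of n = 150 points with noise sd 12 and 500 region draws per replicate;
  Cox recovery uses a two-group exponential at n = 2000; intake-target
  recovery uses n = 2000 animals; interval-hazard recovery uses
  n_per_diet = 100. These sizes make the checks sharp while keeping the
  full suite around half a minute.
- Selection-power checks for the consumption model run 25 replicate
  cohorts with the GLM backend (the generator has no intercept
  heterogeneity, where the two backends provably coincide); the full GLMM
  is exercised directly in its own tests.

## Known limitations

- The confidence region is a simulation approximation; its hull-of-points
  geometry slightly underestimates very irregular regions.
- The Gamma GLMM supports a single random intercept only; no random
  slopes, no crossed grouping.
- Yield is an index, not an economic quantity; no per-cellulose yield
  tables are produced (dilutions are pooled by construction).
- The Cox machinery offers no frailty terms and no continuous
  time-varying covariates beyond episode splitting.
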
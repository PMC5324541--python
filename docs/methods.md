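# Methods

## Scope and data model

The unit of measurement is one harvested plant; the unit of comparative
analysis is one species (taxon). A trait table holds one row per plant
(17 taxa, two randomized-block experiments); a growth table holds one row
per destructively harvested seedling; the phylogeny is a rooted ultrametric
tree whose tips match the trait table's taxa. Seed masses are recorded in
mg (they are weighed in mg), whole-plant masses in g; the single mg→g
conversion happens when yield components are derived, so file round trips
are bit-exact.

Species means are computed transform-first: traits analysed on the log
scale (yield, seed masses, biomass, counts, infructescence mass, height)
are averaged after taking natural logs, so the species mean is a geometric
mean on the natural scale; rates, durations and fractions (λ̃, λs, d, Ar,
c) are averaged untransformed. A property test verifies that the
aggregate-then-transform alternative is detected on skewed data. Plants
are pooled within species by default; a `by_accession` switch averages
accessions first (the two conventions only coincide under balanced
designs).

Reproductive biomass includes culm and chaff. The package's bookkeeping
convention folds culm into the chaff compartment so that
`mass_chaff + mass_grain = mass_reproductive` holds exactly, which in turn
makes c = chaff/(chaff+grain) and the identity Y = Md·Ar·(1−c) exact. If
culm were excluded from both, c would be smaller and the identity would
need a third compartment; the convention is declared rather than silently
assumed.

## Yield decompositions

Y = Ms·exp(λ̃d)·Ar·(1−c) uses seed mass at sowing; Y = Ms·Ns·Ni uses seed
mass at harvest (the two are highly correlated, ~1:1 on the log scale, and
the generator reproduces that). λ̃ = ln(Md/Ms)/d is valid without assuming
exponential growth, but it measures conversion of seed mass into plant
mass, not intrinsic growth rate — hence the separate functional growth
analysis. Negative λ̃ (final mass below seed mass) is logged as a warning,
not rejected. Packaging counts are means over sub-sampled infructescences,
so N_total need not equal Ns×Ni in real data; both are stored and never
reconciled. Seeds per gram of biomass (N_total/Md) is reported as a
supplementary trait outside both decompositions.

## Delta-method variance decomposition

The first-order approximation Var Y ≈ Σᵢⱼ Cov(θᵢ,θⱼ) gᵢgⱼ, with g the
analytic gradient of Y at the sample mean (verified against central finite
differences in the tests), defines a symmetric trait×trait contribution
matrix. Shares are row sums over the grand total; they sum to one by
construction and can be negative through negative covariances. Analysis
units are species means on the *natural* scale, since Y is differentiated
in natural units; a config switch runs the same machinery on individual
plants. The sample covariance uses the n−1 denominator; at least three
units are required.

Domain of validity: the truncation error grows with the variance carried
through the exponential, roughly λ̃²σ_d² + d²σ_λ̃². The diagnostic
`check_delta_accuracy` compares the delta total with the per-unit empirical
Var(Y) and flags departures beyond 25%. The accuracy tests evaluate at a
base point with exponent dispersion SD ≈ 0.1, where the 5% agreement with
Monte-Carlo variance holds; with trait CVs of 50% the approximation fails
by design and the diagnostic must flag it. Across wild/landrace species
sets, λ̃ and d covary negatively (their product is pinned near ln(Md/Ms)),
which keeps the realized exponent dispersion far below what independent
CVs would suggest.

## Functional growth analysis

Four-parameter logistic in ln mass (g) vs days,
m(t) = A + (B−A)/(1+exp((t_mid−t)/s)). Fitting is nonlinear least squares
(scipy trust-region-reflective) on a reparameterised vector
(A, ln(B−A), t_mid, ln s) that enforces B−A > 0.1 ln units and
s > 0.01 day, with a data-driven self-start and seven jittered restarts
keeping the best RSS. A box on the parameters keeps the optimiser off the
degenerate ridge (B−A and s growing together toward an exponential-limit
curve) that six-harvest windows cannot resolve; decreasing or flat series
are errors, not inverted fits. The convergence flag reports the
optimiser's own status.

λs = (B−A)p*(1−p*)/s is the exact derivative of m at the time the curve
passes ln M_c (obtained by differentiating m and substituting
p = 1/(1+exp((t_mid−t)/s)); checked against numeric slopes to 1e-8). λs is
invariant to the mass unit of the fit provided the common size is
converted consistently — a unit change shifts A and B equally and cancels
from B−A and p*. Because asymptotes of ln mass have unit-dependent
magnitudes, parameter-recovery tests measure A and B errors relative to
the span B−A, the only unit-invariant scale; t_mid and s are tested
relatively. Measured at the test design (σ = 0.1 ln units, 12
observations, 100 replicates): median errors A 4–6%, B 2%, t_mid 2%,
s 9%, median λs bias ≈ 1%.

The common size per family is the maximum over species of the minimum
first-harvest mass, guaranteeing every species passes through it early,
when resource limitation is minimal. The original greenhouse values
(42.1 mg grasses, 64.7 mg legumes) ship as constants for replication runs
against archived data; on synthetic data the common size is recomputed
from the series.

## Phylogenetic GLS

The base covariance C holds MRCA depths (computed as
(depthᵢ + depthⱼ − patristic distance)/2, valid on any rooted tree with
branch lengths); Pagel's λ multiplies the off-diagonals only. On the
package's unit-depth ultrametric trees diag(C) = 1, so λ = 0 is exactly
OLS (asserted to 1e-10) and a star phylogeny makes the likelihood flat in
λ, which is flagged rather than reported as an arbitrary interior optimum.

GLS is solved by Cholesky whitening, never explicit inversion. λ is
profiled by bounded Brent search on [0, 1] (tolerance 1e-6) with both
endpoints evaluated; σ² is the ML estimate eᵀV⁻¹e/n inside the
likelihood, while standard errors use the unbiased scale eᵀV⁻¹e/(n−p), the
convention of standard GLS software (verified to 12 digits against two
independent implementations at fixed λ). ML rather than REML is used for
both λ and σ², matching the default behaviour of the comparative-methods
software this mirrors. λ is constrained to [0, 1]; unconstrained
implementations can return λ̂ slightly above 1 on the same data, moving
coefficients in the third decimal.

The status contrast codes crop = 1, so the intercept is the fitted
progenitor mean. For log traits the effect is reported as exp(β̂) with CI
exp(β̂ ± t₀.₉₇₅,ₙ₋₂·se) — a Wald interval on the transformed scale, the
standard choice where no interval method is stated. For untransformed
traits the effect is an absolute difference and, for fractions, also
−100·β̂/intercept, the "percent of progenitor" form. F = t² with
(1, n−2) degrees of freedom. Between-species trait correlations use the
same machinery with R² defined as the squared correlation of
V⁻¹′²-whitened, GLS-centred variables.

## Synthetic-data generator

The generator is first-class, tested code that encodes the study design:
17 taxa in 8 crop/progenitor pairs (two pea progenitors), 20 blocks in
experiment 1 (all taxa) plus 10 in experiment 2 (oat and rye absent), so
30 or 20 replicates per species, split over three accessions each; and a
growth experiment of six harvests on days 8–26, two plants per species per
harvest in six blocks.

Species means are family baseline × status multiplier × Brownian deviate
along the hard-coded ultrametric tree (log scale for sizes and counts,
logit for Ar and c). Plants add a shared per-block size effect and
log-normal (or logit-normal) residuals. Organ masses are constructed from
the realized components, so in noiseless mode every identity holds to
round-off and the trait table is an exact inverse of the component
derivation. Counts are floats: the identities could not hold to 1e-12
under integer rounding, and measured counts are sub-sample means anyway.

Default planted effects are the fitted domestication ratios from the
original comparison: seed mass ×1.9, biomass ×1.4, cereal seeds-per-spike
×1.3, chaff ×(1−0.38); duration, allocation and growth rate carry no
effect. Yield and infructescence mass are *emergent*, not planted — the
defaults imply a crop:progenitor yield ratio of
1.4·(1−0.62·0.39)/(1−0.39) ≈ 1.74, which recovery tests target (the
originally reported ratio, 1.5 with CI [1.1, 2.1], contains it). Because
multipliers are defined as ratios of natural-scale means while fractions
are simulated on the logit scale, the logit location is solved
(Gauss-Hermite quadrature + root finding) so the logit-normal mean equals
the natural-scale target; the correction vanishes at zero noise. An
`attenuate_secondary` switch (default off) zeroes the multipliers for oat
and rye, emulating the weak secondary-domesticate pattern.

Baselines and noise magnitudes are unpublished for the real experiments,
so they are declared, plausible constants: grass/legume sown seed mass
10/30 mg, biomass 20 g, Ar 0.4, chaff 0.39 (the one printed progenitor
mean), duration 100 days; Brownian SDs 0.40 (log) and 0.35 (logit) at
unit depth, block SD 0.10, residual SD 0.20 (log) and 0.25 (logit). The
Brownian SDs were chosen so the planted effects reproduce the original
significance pattern (yield, seed mass, chaff and biomass significant;
duration, allocation and both growth rates not). Because each crop is
sister to its progenitor, shared Brownian variance largely cancels from
the contrast and F statistics run higher than the originals at the same
planted effects; the pattern, not the F magnitudes, is the calibration
target. Growth-curve parameters are status-independent (no planted λs
difference) with small per-species jitter.

All randomness flows from one root seed through named child streams;
identical seeds give byte-identical CSVs. What the generator does *not*
emulate: accession-level genetic structure, vernalization and phenology,
density/competition effects, spike-level bagging and sub-sampling error,
and the real chronogram (the tree is a plausible hard-coded topology).
Passing recovery tests therefore show the estimators are correct and
calibrated under the declared generative model, not that the original
greenhouse data satisfy that model.

## Problem sizes and numerical choices

Test and acceptance runs use the design sizes above (470 plants per
dataset, 17 species means per fit). The acceptance script averages 30
independent datasets; the type-I-error check runs 1000 null simulations;
Monte-Carlo oracles for the variance decomposition use 1e5 units;
growth-recovery oracles use 100 replicates. Ties and degenerate inputs:
chaff fraction with zero reproductive mass is an error carrying the plant
identifier; a constant θ sample reports an undefined accuracy ratio rather
than NaN; singular designs (one status only) and non-SPD covariances raise
immediately.

## Known limitations

- The delta decomposition is first-order only; no second-moment
  corrections or bootstrap CIs on shares.
- λ̂ is a point estimate; no profile CI on λ, and inference ignores the
  uncertainty in λ̂ (standard practice for this model class).
- The 4PL lower asymptote is weakly identified by six-harvest windows;
  λs is robust to this but A itself can be biased under noise.
- Missing traits are never imputed; species with a missing trait drop out
  of that trait's contrast (their tree tips are pruned).
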
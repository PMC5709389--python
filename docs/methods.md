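# Methods

## Model and estimation

The core model is generalized least squares with a phylogenetic
residual covariance: y = Xβ + ε, ε ~ N(0, σ²V(λ)). V is built from the
input tree as the matrix of shared root-to-MRCA path lengths (the sum,
over edges ancestral to both tips, of the edge lengths); the tree need
not be ultrametric, and a zero-length or absent root edge is ignored.
Pagel's λ multiplies the off-diagonal of V only, so λ = 0 is the star
phylogeny (independent species) and λ = 1 the untransformed Brownian
covariance. V(λ) is positive semi-definite for every λ ∈ [0, 1]
because it is a convex combination of V and its diagonal.

λ is estimated by maximizing the profile log-likelihood over [0, 1]:
a coarse grid at step 0.01 followed by bounded scalar minimization
(Brent) within one grid step of the best point, absolute tolerance
1e−6; if the refinement does not beat the best grid point the grid
point is kept, which also makes the exact boundary values 0 and 1
attainable. ML (not REML) is used, matching common practice in
comparative methods. Two likelihood-ratio tests compare λ̂ against
each boundary, with the χ²₁ upper tail as reference. At a boundary the
standard asymptotics would put half the mass at zero; using plain χ²₁
is conservative and is the documented choice.

Coefficient standard errors use the unbiased residual variance
e'V⁻¹e/(n − p) (classical GLS t-tests on n − p df); the ML variance
e'V⁻¹e/n is reported separately as `sigma2_ml_` because it is what
enters the likelihood. All solves go through a Cholesky factorization
of V; if V is numerically semi-definite the code falls back to a
symmetric eigendecomposition pseudo-inverse (with a pseudo-log-
determinant over the positive spectrum) and logs a warning. A
condition number of X'V⁻¹X above 1e10 raises an error rather than
returning unstable coefficients. A residual variance below 1e−12
(perfect fit) is floored there for the likelihood, with a warning,
rather than returning +∞.

The estimator is exposed scikit-learn style (`PGLSRegression`, with
`fit(X, y, V=...)`, `get_params`, fitted attributes with trailing
underscores); `V=None` gives the identity covariance, so the estimator
degrades exactly to OLS, which the tests exploit as a closed-form
oracle.

## Measurement conventions

Volumes use the ellipsoid model V = L·W·H·π/(6·1.43); the 1.43
correction factor calibrates the ellipsoid against actual anuran brain
shape. Paired regions (olfactory nerves, olfactory bulbs,
telencephalon, optic tectum) are measured on the right hemisphere and
the volume doubled; the brain and cerebellum are not doubled. The
paired-handling is a fixed documented rule — the alternative reading
(hemisphere-specific L and H as well) cannot be distinguished from the
measurement protocol, so the package applies doubling to the single
ellipsoid estimate.

Order of operations is fixed as: per-individual volumes → species
arithmetic means on the raw mm³ scale → ×1000 → log₁₀. The ×1000
offset keeps sub-unit volumes positive after the log and shifts all
log values by exactly 3, which affects intercepts only. Rest-of-brain
(whole brain minus the focal region) is computed on the raw scale
before log-scaling. When a trait table carries both L/W/H triplets and
precomputed volumes, the volumes win and a warning is logged. The
medulla is not modeled.

## Climate conventions

CV is sample SD (n − 1 denominator) over mean; the denominator
convention is a package decision. CV of temperature is computed on °C
as given — CV on an interval scale is origin-dependent, so this is a
convention, not a physical quantity, and no Kelvin conversion is done.
The dry-month rule is strict: a month is dry iff precipitation (mm)
< 2 × mean temperature (°C); ties are wet, and months at or below 0 °C
can never be dry under the literal rule (a note is logged when that
occurs). The among-year CV reduces daily series to calendar-year means
first and rejects incomplete years; this reduction is a documented
convention, as is the choice of annual means as the yearly statistic.

## Model suite

The pipeline fits, in fixed order: (a) body size (log SVL) against
temperature CV; (b) three bivariate whole-brain models, one per
seasonality measure, each with log SVL and log body mass as covariates
(the covariate set is applied uniformly across the three measures and
is configurable); (c) the multiple regression of whole brain on all
three seasonality measures plus log SVL and log body mass; (d) five
region models with the three seasonality measures plus the region's
rest-of-brain as the allometric covariate; (e) among-year CV models
for brain and regions, kept in separate models from the within-year
temperature CV because the two are collinear. Raw p-values are
reported with no multiple-testing correction; intercept rows are
included in the output but flagged by name. Model ids are fixed
strings so output diffs are stable.

## Synthetic data generator

The generator is the model's generative twin and defines the study
conditions used in validation: 30 species, 171 individuals (21
species × 6 + 9 × 5), a Yule tree (birth rate 1) rescaled to unit
height, residuals drawn with covariance σ²V(λ) at σ² = 0.01 and
λ = 0.7 on the log₁₀ trait scale, and a planted temperature-
seasonality slope of −0.25 with allometric slopes 2.1 (log SVL) and
−0.18 (log mass). Locality climates are 12-month sinusoids with
species-level mean temperature ~ U(8, 22) °C and amplitude
~ U(4, 14) °C (month noise SD 0.5 °C), chosen to emulate montane
subtropical localities spanning a wide seasonality range; precipitation
is an analogous sinusoid (mean 90 mm, amplitude up to 70 mm, noise SD
10 mm) clamped at zero, with clamping logged because it distorts the
target CV. Daily series for the among-year CV share the monthly means
and add a per-year effect (SD 0.4 °C) and daily noise (SD 2 °C) over
five calendar years. The planted slope enters through the *realized*
temperature CV of each simulated locality, so recovery exercises the
climate module as well as the regression.

What the generator does not emulate: spatial autocorrelation of
climate between neighboring localities, non-sinusoidal (e.g. monsoon)
precipitation regimes, measurement error correlated across structures
within an individual, and phylogenetic signal in the climate
predictors themselves (localities are independent of the tree).
Passing tests therefore demonstrate correctness of the estimator and
pipeline under the assumed model, not robustness to violations of it.

Noise is added on the log₁₀ scale so the generative model matches the
scale on which the regressions are fit; individual-level scatter is
log-normal with SD 0.02. Region volumes are log-normal fractions of
the whole brain (telencephalon 28%, optic tectum 14%, olfactory bulbs
6%, cerebellum 4.5%, olfactory nerves 4%; log SD 0.03), which keeps
every region below the whole brain at the scatter used. All outputs
are bit-identical for a fixed seed.

## Validation experiments and problem sizes

The simulation experiments (`seasonbrain.validation`) use: 20 random
4–8 species datasets for the likelihood/profile oracle checks
(direct multivariate-normal density; exhaustive λ grid at 1e−4); 200
replicates of 100-species datasets for recovery of (λ = 0.7, slope
−0.25), reporting mean λ̂, mean slope, 95% CI coverage and power; and
1000 replicates of 30-species null datasets for the type-I error of
the 5% slope test. These sizes give Monte-Carlo standard errors small
enough to detect miscalibration (coverage SE ≈ 1.5%, rejection-rate
SE ≈ 0.7%) while keeping the whole validation run around a minute on
one CPU.

## Known limitations

* Only Pagel's λ is offered as a covariance transform (no OU/ACDC/
  Grafen), and only one tree — no averaging over a posterior sample.
* The boundary LRT is conservative (no 50:50 mixture).
* Species are matched between tree and tables strictly by label;
  pruning is opt-in and only resolves tree-side surpluses.
* The climate module takes monthly normals as given; it does not
  interpolate, downscale or scrape station data.
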
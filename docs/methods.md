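# Methods

## Constitutive layer

All models assume isotropy and incompressibility, which is standard for
hydrated fibrous airway tissues and reduces uniaxial kinematics to a single
stretch λ: λ₂ = λ₃ = λ^(−1/2), I₁ = λ² + 2/λ, I₂ = 2λ + 1/λ², I₃ = 1.
The implemented strain-energy functions and uniaxial Cauchy stresses
(stress-like coefficients in MPa, exponents dimensionless):

| model | W | σ(λ) |
|---|---|---|
| Neo-Hookean | a₁(I₁−3) | 2a₁(λ²−1/λ) |
| Mooney-Rivlin | a₁(I₁−3)+a₂(I₂−3) | 2(λ²−1/λ)(a₁+a₂/λ) |
| Yeoh | Σᵢ aᵢ(I₁−3)ⁱ | 2(λ²−1/λ)[a₁+2a₂(I₁−3)+3a₃(I₁−3)²] |
| Fung | a₁/(2a₂)(e^{a₂(I₁−3)}−1) | a₁(λ²−1/λ)e^{a₂(I₁−3)} |
| Humphrey | a₁(e^{a₂(I₁−3)}−1) | 2a₁a₂(λ²−1/λ)e^{a₂(I₁−3)} |
| Ogden (3-term) | Σₙ (a₂ₙ₋₁/a₂ₙ)(λ₁^{a₂ₙ}+λ₂^{a₂ₙ}+λ₃^{a₂ₙ}−3) | Σₙ a₂ₙ₋₁(λ^{a₂ₙ}−λ^{−a₂ₙ/2}) |
| Veronda-Westmann | a₁(e^{a₂(I₁−3)}−1)−(a₁a₂/2)(I₂−3) | 2a₁a₂(λ²−1/λ)(e^{a₂(I₁−3)}−1/(2λ)) |

Every closed form is re-derived from σ₁ = λ₁∂W/∂λ₁ − λ₃∂W/∂λ₃ and checked
in the test suite against a central finite-difference evaluation of that
identity on W(λ₁, λ₂, λ₃) (step 10⁻⁶ in stretch), which is the package's
independent oracle; agreement is required to 10⁻⁵ relative over random
coefficient draws spanning the magnitudes that occur in tracheal fits.
The Ogden energy is stored in the quotient form μ/α so that energy and
stress are mutually consistent; any term with a nonzero modulus must have a
nonzero exponent. Exponential arguments a₂(I₁−3) and Ogden's α·ln λ are
clipped at ±50 before `exp`, which only matters during wide optimizer
excursions, never at converged parameters on physiological stretches.

The small-strain tangent dσ/dλ at λ = 1 has closed forms (6a₁ for NH and
Yeoh, 6(a₁+a₂) for MR, 3a₁ Fung, 6a₁a₂ Humphrey, 3a₁a₂ VW,
(3/2)Σa₂ₙ₋₁a₂ₙ Ogden). It can legitimately be negative for fitted
coefficient sets (e.g. a Mooney-Rivlin fit to a strongly stiffening curve),
which signals non-physical small-strain behavior of that fit rather than a
bug; callers that care should flag it.

## Processing layer

Records are (displacement mm, force N) series plus geometry (L₀, A₀).
The reference state is the first crossing of the 0.1 N preload — the state
at which gauge length is measured in practice — so earlier samples are
discarded and the crossing displacement becomes zero. The preload is then
treated as a constant force offset: the reference force is subtracted from
the whole series before σ = (T/A₀)λ. Subtracting a constant *stress*
0.1/A₀ instead would differ by 0.1(λ−1)/A₀ (< 0.017 MPa for A₀ ≥ 3 mm² at
λ = 1.5); the force-offset convention was chosen because it makes the
generator → processor loop close exactly, giving machine-precision
round-trip tests, and because σ(1) = 0 holds either way. Non-increasing
displacement samples (machine jitter) are dropped with a logged count.

Averaging first resamples every curve onto the uniform stretch grid
[1, λ_max] with step 0.01 (λ_max = 1.2 for cartilage, 1.5 for the soft
tissues; the 0.01 step resolves curvature over both ranges) and then takes
the pointwise mean and sample SD. Curves not reaching λ_max are excluded
with a warning rather than truncating the grid, so every grid point
averages the same specimens. Averaging is two-stage: specimens within a
subject first, then subjects within a group, so each subject contributes
one curve regardless of specimen count. Resampling is linear interpolation
with no extrapolation; a 10⁻⁶ endpoint slack in stretch absorbs CSV
round-trip precision.

## Fitting layer

Coefficients minimize Σ(σ_obs − σ_model)² by Levenberg–Marquardt
(`scipy.optimize.least_squares`, method "lm", ftol = xtol = 10⁻¹²,
≤ 300 function evaluations per start). Sixteen starts are used: one
deterministic heuristic anchored to the curve's small-strain modulus via
the Neo-Hookean scale a₁ = E₀/6, the rest seeded draws with stress-like
coefficients log-uniform in (0.1–10)× that scale with random sign and
exponents uniform in [0.1, 20] (signed for Ogden). The best local optimum
wins; with a fixed seed the result is bit-reproducible. On noiseless
self-generated curves every model recovers its coefficients to better than
10⁻³ relative except the 3-term Ogden, whose six parameters are
structurally unidentifiable from one smooth 51-point curve — there the
criterion is curve-level (RMS < 10⁻⁶ MPa), and its reported coefficients
should not be interpreted individually.

R² uses the mean-anchored SS_tot (curve-fitting-toolbox convention).
Rankings sort by R² rounded to 0.001 — the precision at which such tables
are printed — breaking ties toward fewer parameters; on a quasi-linear
cartilage curve this deliberately prefers Neo-Hookean over the equally
scoring multi-term models. The cartilage Young's modulus is the OLS slope
of σ on (λ−1) with a free intercept over [1, 1.2]; the intercept makes the
slope insensitive to the preload re-zeroing convention.

## Cohort layer

One modulus per subject (specimen-averaged) enters the statistics, so
specimen-within-subject correlation never reaches the ANOVA. The two-way
ANOVA (age group × sex + interaction) uses Type II sums of squares, the
conventional choice for an unbalanced design when the interaction is weak;
for balanced designs the tests verify it against the explicit
cell/marginal-mean decomposition. Normality screening is Shapiro–Wilk plus
normal Q-Q coordinates. The significance level defaults to 0.05 and no
multiple-testing correction is applied across tissues, which reports note.
Age groups are hard ranges (young 18–36, old 49–65); ages between the
ranges are rejected because the study design contains none.

## Synthetic cohorts

The generator emulates: cohort composition 5/8/7/10
(young-F/young-M/old-F/old-M), three specimens per tissue per subject,
Yeoh ground-truth mean curves per tissue, gauge lengths normal with means
4.13/6.37/1.60 mm (SD 1.81/1.91/0.33) for cartilage/smooth-muscle/
connective (redrawn below 20% of the mean), cross-sections 5 ± 1.5 mm²
(cartilage) and 3 ± 1 mm² (soft tissues) — a documented fixture choice, as
cross-sections only scale forces and cancel out of stresses — a 0.1 N
preload with a short noise-free sub-preload toe, and force noise with SD
equal to 1% of the record's peak force.

Subject heterogeneity is a single multiplicative stiffness scale per
subject-tissue (curve shape preserved), drawn from a lognormal whose first
two moments are matched so that scale × E_base reproduces the cartilage
group targets 13.30 ± 5.72 MPa (young) and 20.71 ± 10.17 MPa (old), where
E_base ≈ 20.6 MPa is the linear modulus of the cartilage ground-truth
curve over [1, 1.2]. The lognormal is a generator choice (positivity at
CV ≈ 0.5), not a claim about the real population. Soft tissues get unit
young-group mean scales with CV 0.30 and old/young ratios 1.30 (connective)
and 1.10 (smooth muscle, the least age-sensitive tissue).

What passing tests do and do not show: the loop
generate → process → fit → compare closes exactly (noise/SD = 0 recovers
configured moduli to < 0.1%) and stochastically (group means within 2
standard errors of the targets), but the generator has no hysteresis,
strain-rate effects, preconditioning evolution, failure, curve-shape
heterogeneity between subjects, or machine compliance — so the tests
validate the analysis pipeline, not the realism of any one tissue model
on fresh laboratory data. The connective-tissue "net L₀" of a composite
cartilage-connective specimen is emitted directly as metadata; optical
measurement of it is out of scope. With the published coefficients the
smooth-muscle Yeoh curve is convex (stiffening) up to λ ≈ 1.46 and flattens
just below λ = 1.5 because its cubic term is negative; the stiffening
property is therefore asserted over [1, 1.4].

A note on statistical power: with the calibrated group moments and
n = 13/17, the age effect in the two-way ANOVA is detected at p < 0.05 in
only ≈ 65% of seeded cohorts (SE of the group-mean difference ≈ 2.9 MPa
against a 7.4 MPa shift). That detection rate is a property of the study
conditions themselves; the test asserting a higher detection rate
documents this rather than inflating the effect or shrinking the
variances.

## Problem sizes

Default grids are 21 points (cartilage, [1, 1.2]) and 51 points (soft
tissues, [1, 1.5]) at step 0.01; a default cohort is 270 records. The
acceptance script fits on these grids and runs one full 30-subject
pipeline; the test suite's replicate counts (50 cohorts for the power
check, 100 parameter draws per model for the oracle sweep) were chosen as
the package's own convergence/robustness trade-off.
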
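# tracheamech

Tensile characterization and constitutive modelling of the three
load-bearing tissues of the human trachea — the C-shaped cartilage rings,
the trachealis (smooth) muscle closing their posterior gap, and the
connective tissue between consecutive rings. The package is aimed at
soft-tissue biomechanics work (e.g. selecting material models and target
stiffnesses for tracheal tissue-engineering scaffolds) and turns raw
uniaxial force–displacement records into fitted hyperelastic models and
age/sex cohort statistics.

## What it computes

Each tissue is treated as an isotropic, incompressible hyperelastic
material. Under uniaxial tension with stretch λ = (L₀ + ΔL)/L₀,
incompressibility forces the transverse stretches to λ^(−1/2), so the
strain invariants are I₁ = λ² + 2/λ, I₂ = 2λ + 1/λ², I₃ = 1, and the
measured force T over an initial cross-section A₀ gives the Cauchy (true)
stress σ = (T/A₀)·λ in MPa.

From a strain-energy function W the uniaxial Cauchy stress follows from

    σ₁ = λ₁ ∂W/∂λ₁ − λ₃ ∂W/∂λ₃ = 2(λ² − 1/λ)(∂W/∂I₁ + (1/λ) ∂W/∂I₂).

Seven W's are implemented — Neo-Hookean, Mooney-Rivlin, Yeoh, Fung,
Humphrey, Ogden (3-term) and Veronda–Westmann — each with a closed-form σ(λ)
verified against a central-finite-difference evaluation of the first
identity on W(λ₁, λ₂, λ₃). Coefficients are identified by multistart
Levenberg–Marquardt least squares on stress–stretch curves; models are
ranked by R² = 1 − SS_res/SS_tot. Cartilage is quasi-linear up to λ = 1.2,
so its Young's modulus is the OLS slope of σ on engineering strain (λ − 1).
Group comparisons use a two-way ANOVA (age group × sex, Type II sums of
squares for the unbalanced design) after Shapiro–Wilk/Q-Q normality
screening.

Because no public per-subject data exist for this kind of study, the
package ships a first-class synthetic-cohort generator: 30 subjects
(13 young, ages 18–36: 5 female / 8 male; 17 old, ages 49–65: 7 female /
10 male), three specimens per tissue, Yeoh ground-truth mean behavior per
tissue, lognormal subject-level stiffness scales calibrated so cartilage
group moduli are 13.30 ± 5.72 MPa (young) and 20.71 ± 10.17 MPa (old),
measured gauge-length distributions, a 0.1 N preload reference and additive
force noise.

## Worked example

```python
import tracheamech as tm
from tracheamech.cli_io import RunConfig, process_cohort, \
    tissue_average_curves, fit_report, cohort_report

cohort = tm.generate_cohort(tm.CohortConfig(seed=42))
cfg = RunConfig(seed=42)
curves, moduli = process_cohort(cohort.records, cohort.manifest, cfg)
print(moduli.groupby("age_group")["modulus_MPa"].agg(["mean", "std", "count"]))
stats, anova, norm = cohort_report(moduli, cfg)
print(anova[["sum_sq", "df", "F", "PR(>F)"]].round(4))
r2_table, fits = fit_report(tissue_average_curves(curves, cfg), cfg)
print(r2_table)
```

prints

```
            mean    std  count
age_group
old        23.09  10.53     17
young      13.24   6.91     13
                  sum_sq    df       F  PR(>F)
age_group       721.3371   1.0  8.0964  0.0085
sex              21.4926   1.0  0.2412  0.6274
age_group:sex     9.0298   1.0  0.1014  0.7528
residual       2316.4319  26.0     NaN     NaN
                  cartilage  smooth_muscle  connective
model
neo_hookean           1.000          0.873       0.917
mooney_rivlin         1.000          0.999       0.998
fung                  1.000          0.989       0.997
humphrey              1.000          0.989       0.997
yeoh                  1.000          1.000       1.000
ogden                 1.000          1.000       1.000
veronda_westmann      0.996          0.994       0.999
```

Reading the output: with this seed the recovered young/old cartilage
moduli (13.24 vs 23.09 MPa) straddle the generator's calibration targets
(13.30 / 20.71 MPa); the ANOVA flags age (p = 0.0085) but neither sex nor
the interaction as significant; and the R² matrix shows the stiffening
soft tissues demand a multi-term model (Neo-Hookean drops to ≈0.87–0.92)
while quasi-linear cartilage is fit well by almost everything. The Yeoh
row tops both soft-tissue columns, matching the tissue ground truth.

The same workflow is available from the shell:

```bash
tracheamech simulate --seed 42 --out cohort/
tracheamech report --input cohort/ --out results/
```

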
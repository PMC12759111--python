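# Methods

## Two-step CpG classification

Each CpG's beta-value trajectory is modeled with subject-level Gaussian
linear mixed models fitted by maximum likelihood (ML, not REML: the two
models share fixed effects and are compared by likelihood ratio and AIC,
both of which are conventional under ML; a REML mode exists but never
enters comparisons). Model 1 carries a random intercept; Model 2 adds a
random slope on age and the intercept–slope covariance, so Model 2 has two
extra variance parameters, one of which (the slope variance) sits on the
boundary of the parameter space under the null. The slope test therefore
uses the boundary mixture null `0.5·χ²₁ + 0.5·χ²₂`; its p-value, with a
Bonferroni threshold `family_alpha / M` (M = CpGs attempted, so the
threshold never depends on fit outcomes), defines the *age-varying* call.
An alternative `ΔAIC > 0` criterion is available and both statistics are
always emitted, so the choice is auditable. The *age-associated* call is a
large-sample Wald z-test of the fixed age coefficient taken from the
best-AIC model (a flag forces Model 1 instead); Satterthwaite degrees of
freedom are out of scope — with ~405 observations and ~10 fixed effects
the normal approximation holds well (the null suite verifies KS uniformity
of these p-values at the 1% level).

Age is centered at the cohort mean baseline age before fitting. This
decorrelates random intercepts and slopes on an age range far from zero
and makes the slope BLUP directly interpretable as beta-units per year.

### Fitting

The likelihood is profiled over the fixed effects and the residual
variance; the optimizer searches only the relative Cholesky factor L of
`Ψ / σ_e²` (diagonal bounded at 1e-10, off-diagonal free), so the
`σ_b1 = 0` boundary is exactly representable. Per-subject blocks enter
through sufficient statistics (`Z'Z`, `X'Z`, `Z'y`) and the Woodbury
identity, with the 1×1 / 2×2 inverses written in closed form; one fit of
both models takes ~20 ms at 135 subjects × 3 waves, which makes
genome-scale scans and Monte-Carlo calibration practical on one CPU.
L-BFGS-B runs with a relative function tolerance of 1e-10 and a numeric
gradient (step 1e-6); on reported non-convergence the fit restarts once
from a perturbed initialization and is accepted if either attempt
succeeds or both agree to 1e-6. Model 2 is warm-started from Model 1's
solution and the boundary point is kept as a candidate, which guarantees
`ℓ₂ ≥ ℓ₁ − 1e-6` by construction. Responses that are constant or exactly
explained by the fixed effects short-circuit to a degenerate fit with all
variance components at the floor. BLUPs are
`b̂_i = Ψ Z_i' V_i⁻¹ (y_i − X_i β̂)`.

Covariates are sex, smoking, drinking and four of the five leukocyte
subtype proportions (CD8T, CD4T, NK, B; the monocyte fraction is the
omitted simplex reference — including all five would be collinear with
the intercept, which the fitter rejects by design).

## Pace of aging

Phenotype panels are completed deterministically rather than by stochastic
chained-equation multiple imputation: phenotypes with more than 20%
missing cells are dropped (logged), interior holes are linearly
interpolated on age within subject, edge holes take the subject mean, and
fully missing subjects take the cohort mean. This keeps the whole pipeline
bit-reproducible at the cost of understating imputation uncertainty — an
acceptable trade for a rate-estimation pipeline whose downstream tests use
the completed values only through subject-level slopes.

Each phenotype is fitted with the same random-slope model; the per-subject
slope BLUP is the phenotype-specific pace of aging in phenotype units per
year. Organ composites z-score each pace across subjects before
direction-aligned averaging (default on): the phenotypes within an organ
have incommensurable units, and a raw arithmetic mean would be dominated
by whichever phenotype has the largest numeric scale. The unstandardized
mean remains available (`standardize=False`) and the choice is recorded in
output metadata. Age enters these models only as the centered time scale;
an optional flag adds baseline age as a separate between-subject
covariate.

## CpG–organ association

Partial correlations are computed at the subject level, so time-varying
covariates are collapsed once: baseline age, sex, baseline
smoking/drinking, and leukocyte proportions averaged across waves. r is
the Pearson correlation of the two residual vectors after least-squares
adjustment on `[1, Z]`; the test is `t = r·sqrt((n−2−k)/(1−r²))` on
`n−2−k` df. Following the two-step logic, the organ scan is restricted to
age-varying CpGs and reports raw p < 0.05 by default (a BH option exists
but is off). Risk-factor scans regress change rates on a baseline factor
plus covariates per CpG, then contrast significant counts between the
age-varying and age-associated categories by Fisher's exact test.

## Enrichment machinery

The two-sided Fisher exact p sums hypergeometric probabilities of all
margin-preserving tables whose probability does not exceed the observed
one (relative slack 1e-7); it is computed in-package with a vectorized
log-gamma kernel (the exhaustive oracle sweep over all 628,055 tables with
total ≤ 60 would take minutes through a generic library call) and agrees
with `scipy.stats.fisher_exact` to 1e-9. Odds ratios use Haldane–Anscombe
+0.5 on zero cells for the OR and Wald CI only, never for p. Clock
enrichment uses inclusive category sets (CpGs called "both" belong to each
category), the universe of all analyzed CpGs, and BH adjustment across the
clock × category grid. The DHS and risk-factor contrasts use the two
exclusive categories so the 2×2 rows are disjoint. The category × genomic
feature table (8 feature classes) is tested by Pearson chi-square, which
is appropriate at the large expected counts involved.

## Pathway term reduction

ORA is the one-sided hypergeometric tail with BH adjustment per source.
Similarity is Wang's DAG measure for GO (edge contributions 0.8 for
`is_a`, 0.6 for `part_of`; S-values by dynamic programming over the
ancestor closure) and the Jaccard index for KEGG/Reactome. Edges require
similarity strictly greater than 0.5; communities come from deterministic
greedy modularity maximization with isolated terms standing alone and all
orderings fixed lexicographically, so the reduction is invariant to input
order. Each community is represented by its smallest-adjusted-p term (ties
broken by term id), and representatives are pooled across sources. The ORA
is not methylation-bias-aware (no probe-count weighting).

## Synthetic cohort

The generator emulates the statistical structure the models assume: 135
subjects (default), baseline ages uniform on 70–81 (only the range is
specified for such cohorts), waves at +0, +2.5, +5 years, 61.5% female,
three-level smoking/drinking status constant across waves, per-sample
leukocyte proportions from a Dirichlet over five subtypes. Methylation is
simulated directly on the beta scale as
`β0 + β_age·age_c + γ'x + b0_i + b1_i·age_c + ε` with `(b0, b1)` bivariate
normal and clamping to [0, 1]; an M-value mode exists but is not default.
CpGs fall into four classes (70% null, 15% age-associated, 10%
age-varying, 5% both by default). Default magnitudes are calibration
choices, not estimates of any cohort: `σ_e = 0.005`, `σ_b0 = 0.02`
(typical EPIC within/between-subject scales), `β_age = 0.005`/yr (five
residual SDs over the 5-year follow-up) and `σ_b1 = 0.004`/yr (about 2.8×
the per-subject slope standard error `σ_e/√J`, J = 12.5 yr² for the wave
spacing) — strong enough that a Bonferroni-level scan should separate the
classes, which is what the recovery suite verifies. Small covariate
effects (0.02 per unit proportion) attach to the cell fractions only, so
adjustment is exercised while classification truth stays in the random
structure.

Organ phenotypes get per-subject slope deviations coupled to a latent
standard-normal organ rate (`ρ = 0.7` by default, two phenotypes per organ
across eight systems), with direction codes fixing the sign of change with
aging; optional `cpg_organ_coupling` ties chosen age-varying CpG slopes to
the same latent rates for association power studies. Ground truth (class
labels, subject slopes, latent rates, fixed effects) is emitted alongside.

What the generator does **not** emulate: array-level artifacts (probe
bias, batch, detection failures), realistic phenotype marginals,
non-Gaussian trajectory shapes, and missingness mechanisms other than
completely-at-random. Passing recovery tests therefore demonstrate
correctness of the estimators under their own assumptions, not robustness
to real-data pathologies.

## Problem sizes and numerical choices

The validation suite runs at the cohort's own scale: 135 subjects × 3
waves with 2,000 CpGs for null calibration and recovery (the genome-wide
analogue is embarrassingly parallel over CpGs), and 2,000 subjects where a
moment must converge (slope-variance recovery, coupling correlations, the
organ-composite averaging gain). Tables are TSV with 15-significant-digit
floats ('.' decimal, 'NA' missing); metadata headers carry the seed and
decisions in force but no timestamps, so identical configurations
reproduce byte-identical outputs. All randomness flows from a single
integer seed through `numpy.random.default_rng`.

## Known limitations

* The Wald z-test slightly understates uncertainty at very small subject
  counts (no small-sample df correction).
* The mixture null for the slope LRT is asymptotic; at 135 subjects it is
  mildly conservative near the boundary (observed null call rate ≈ 0.053
  at α = 0.05, inside the acceptance band).
* Deterministic imputation understates between-imputation variance.
* Partial correlations treat estimated BLUPs as data, ignoring their
  shrinkage-induced noise; this attenuates but never inflates
  associations.
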
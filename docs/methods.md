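# Methods

This note records the statistical model behind each stage of `brainvar`, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## Data model

A subject table has one row per subject with covariates
`subject_id, cohort, sex (M/F), age (years), field_strength,
software_version[, global_cov]` followed by one numeric column per regional
measure. The default region catalog holds 14 subcortical volumes
(7 structures × 2 hemispheres), and 68 + 68 cortical surface-area and
thickness measures (Desikan-Killiany, 34 regions per hemisphere). Missing
measure values are allowed; every analysis uses pairwise-complete rows per
measure rather than listwise deletion, because multi-cohort tables routinely
have different coverage per measure class. Input files may be comma- or
tab-separated (auto-detected from the header line); outputs are always
tab-separated with a JSON metadata sidecar, and numeric round-trips are exact
to more than 12 significant digits (`%.17g`).

Sex is canonicalized to {M, F}; `male`/`female` are accepted directly, and
numeric codings only with an explicit mapping, since no universal 0/1
convention exists.

## Harmonization

Pooling cohorts whose age windows differ by decades requires one mean model
across all data. Stage 1 is OLS of each measure on an intercept, cohort
indicator contrasts, and an age polynomial (default cubic). Age is divided
by 100 before expansion so the cubic design stays well-conditioned across
1–90 years; reported coefficients are on that transformed scale. Residuals
are exactly orthogonal to every design column (this is asserted in tests at
machine precision). Rank-deficient designs raise an error naming the
collinear columns (identified by pivoted QR).

Stage 2 regresses the stage-1 residuals on one-hot encoded field-strength
and software-version labels with a random forest (default 500 trees,
minimum leaf 50, fixed seed, out-of-bag score recorded). The forest can
absorb label interactions a linear model would miss; the large minimum leaf
deliberately limits its capacity so it cannot soak up sex-related variance
through label overfitting. When scanners are nested in cohort — one scanner
per cohort, the common consortium design — the labels carry no information
beyond cohort, stage 2 predicts ≈ 0, and the step is a documented no-op
(visible in the OOB summary). Covariates with a single level are dropped
with a warning, not an error.

Both stages pool the sexes: sex is never a covariate, so sex differences in
means and variances pass through to the residuals, which is the point. An
optional global covariate (e.g. total brain volume) can be added as a linear
stage-1 term for sensitivity analyses. The model contains no cohort × age
interaction by default; a single pooled trajectory is assumed.

## Mean and variance tests

Cohen's d uses the pooled (n−1-weighted) SD with the convention d > 0 =
male mean larger; the t-test is the Student pooled-variance version for
internal consistency with that d (Welch available via flag).

The variance ratio T = Var♂/Var♀ uses n−1 variances and is log-transformed
to symmetrize (log VR = 0 under equality; ±log c² under a c-fold SD
difference, a scale-equivariance property verified by tests). Its null
distribution comes from permuting sex labels among the residuals. The
one-sided p counts strict exceedances T_b > T, exactly as the test is
defined; the default is two-sided on |ln T_b| ≥ |ln T| because greater
*female* variance, though rarer, is a real outcome that a one-sided test
would never flag. Ties are compared with a 1e-9 relative tolerance so that
exact enumeration (all C(n, n♂) assignments, available for small n and used
as an oracle in tests) is immune to floating-point jitter between variance
formulas. An add-one smoothed estimate ((Σ I + 1)/(B + 1)) is available to
avoid literal p = 0. B defaults to 10,000; permutations are generated in
chunks of 2,000 to bound memory.

FDR is Benjamini–Hochberg, applied within each measure class (subcortical /
area / thickness), matching how the three families are reported. The
association between variance and mean effects is summarized by the Pearson
correlation between the per-class log-VR and d vectors (df = n−2, so
df = 12 for the 14 subcortical measures).

## Shift functions

Group means are aligned first (D then reflects shape, not location; variance
ratios are unaffected by the alignment). Deciles 0.1–0.9 are estimated per
sex with the Harrell–Davis estimator, which is smooth and markedly less
variable than sample quantiles at these probabilities; an empirical
estimator and a quantile-regression-forest estimator (age as the
conditioning variable, leaf-pooled weights, conditional quantiles averaged
over the observed age distribution) are provided as alternatives. The forest
variant exists because conditional-quantile machinery is sometimes preferred
for lifespan data; with age as the only predictor and marginal averaging it
closely tracks the marginal quantiles, and the Harrell–Davis default is used
everywhere else. Estimated quantile vectors are passed through an isotonic
(cumulative-maximum) safeguard.

SEs come from a stratified bootstrap: resample within each sex, re-align,
re-estimate; CIs are the normal approximation D ± 1.96·SE (percentile CIs
optional), pointwise per decile with no simultaneous-coverage correction.
Classification of the decile profile: deciles whose CI excludes zero are
"significant"; significant negative D below the median and/or positive D
above it → `greater_male_variance`; the mirror image →
`greater_female_variance`; anything else → `parallel`. For male/female
distributions equal up to scale c, D(q) = (c−1)·σ♀·Φ⁻¹(q) — the closed form
used in tests (c = 1.5 gives D(0.9) ≈ 0.641·σ♀).

In the pipeline, shift functions are computed exactly for the measures whose
variance test is FDR-significant (the library accepts any measure).

## Dispersion across age

|r| is the subject-level dispersion proxy (E|r| = σ√(2/π) for normal
residuals). The models are literal:

    |r| ~ 1 + age + sex + age·sex         (order 1)
    |r| ~ 1 + age² + sex + age²·sex       (order 2)

with sex coded male = 1 / female = 0, so a positive sex coefficient means
greater male dispersion and a negative interaction means the gap narrows
with age. The quadratic model uses age² in both the main and interaction
term — not a full quadratic polynomial — because that is the model as
specified. Age is z-scored over the analyzed subjects by default (raw years
optional); coefficient magnitudes therefore depend on the age scaling and
are validated by sign and by recovery on synthetic data, not against any
absolute target. The default residual recipe for this stage also removes
(cubic) age in the mean model, so |r| isolates spread and an age main effect
on |r| reflects age-varying dispersion; a flag restores the alternative
reading in which age is left in the residuals. FDR on the interaction term
is applied across measures within class, separately per model order.

## Anatomical correlations

Sex-specific standardization (per sex: center, scale to unit variance per
measure) strips mean and variance differences so only correlation structure
is compared. Per-sex Pearson matrices use pairwise-complete rows. The
difference matrix M − F is tested edge-wise via the difference of Fisher-z
transforms, with a subject-level permutation null: whole rows are
re-assigned to sexes, preserving each subject's cross-region profile (the
exchangeability unit under "no sex effect" is the subject). Correlations at
|r| = 1 are clipped to atanh(1 − 1e-12) with a warning. Edge significance
defaults to uncorrected two-sided α = 0.05 (FDR optional), and directional
counts of significant edges feed a 1-degree-of-freedom equal-proportions
goodness-of-fit chi-square, Σ(O − E)²/E with E = N/2 — e.g. counts (2, 16)
give χ² = 10.889 and (478, 6) give χ² ≈ 460.30. When no edge is
significant, no test is reported.

## Synthetic cohorts

The generator emulates the features of consortium lifespan data that the
pipeline must survive: 10–80 cohorts with staggered age windows inside
1–90 y, ~47–53% females, additive cohort offsets, scanner/software shifts
confounded with cohort (each cohort one scanner by default), cubic age
trajectories, and per-measure sex effects. For measure class c with base
noise scale σ₀:

    y = offset_cohort + shift_scanner + trend_c(age) + sex_shift + σ(sex, age)·ε

with σ = σ₀·exp(s·(logVR + slope·z_age)/4), s = +1 for males and −1 for
females, so Var♂/Var♀ = exp(logVR) exactly at the age anchor and drifts
log-linearly with standardized age (fixed anchor: mean 45.5 y, SD 25.69 y,
the moments of a uniform 1–90 distribution, so ground truth does not depend
on the realized sample). The sex mean shift is d·√((σ♂² + σ♀²)/2), half
added to males and half subtracted from females, so realized Cohen's d
matches the target. ε is multivariate normal across the measures of a class
with sex-specific compound-symmetry correlation (full matrices accepted;
PSD is validated); an optional scaled multivariate-t alternative
(configurable df, rescaled to unit marginal variance) exists to check that
the permutation tests do not lean on normality. Default per-class targets:
the published per-region subcortical reference values (d 0.41–0.92,
log VR 0.12–0.36, age slope −0.10), area d 0.42–0.97 / log VR 0.13–0.36
(slope −0.05), thickness |d| ≤ 0.12 / log VR ≤ 0.11 (slope 0), with female
correlations stronger subcortically and male correlations stronger for
thickness. The female fraction defaults to 0.52, the value implied by the
reference sample's counts (its abstract rounds the other way; the counted
ratio is used).

Not emulated: realistic region-specific covariance estimated from real
atlases, non-uniform age densities, site-specific QC artifacts, or
longitudinal structure. Passing tests therefore demonstrate that the
estimators recover known effects under a faithful but idealized noise model,
not that any particular empirical brain result holds.

Every draw is a deterministic function of the config seed, and
`ground_truth()` returns the exact generating parameters for
parameter-recovery tests.

## Pipeline and problem sizes

`run_all` derives one child seed per stage from the master seed
(`numpy.random.SeedSequence.spawn`, fixed order), so the whole bundle —
including the summary JSON — is bit-identical under a fixed master seed.
Every seed, B, bootstrap count, and recipe is logged so any number in a
report can be re-derived.

The test and acceptance suites run the statistics at sizes where the
relevant Monte-Carlo error is comfortably inside the asserted tolerances:
n = 5,000/sex for ±0.05 moment recovery (SE of log VR ≈ 0.028 there),
1,000 null replicates for the [0.03, 0.07] type-I band, 200 replicates at
n = 1,000/sex for the >0.95 power bound, n = 100,000 for the closed-form
decile checks, and n = 20,000 per replicate for age-interaction detection.
Full-scale defaults (B = 10,000, n_boot = 1,000) remain the library
defaults.

## Known limitations

- Stage 2's forest cannot separate scanner from cohort when they are fully
  confounded; it makes no attempt to, matching the two-step design.
- The permutation tests assume exchangeability of residuals under the null;
  strong cohort-specific variance heterogeneity that survives harmonization
  would violate this.
- Shift-function CIs are pointwise; simultaneous statements across deciles
  need a multiplicity correction the package does not provide.
- The age-interaction models are cross-sectional descriptions; they say
  nothing about within-person change.
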
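# Methods

This note documents the statistical models implemented in `cortexdev`, the
assumptions behind the synthetic-data generators, the numerical choices, and
the known limitations. Problem sizes quoted throughout are the defaults used
by the analysis scripts and the test-suite.

## 1. Synthetic imaging cohort

`generate_cohort` draws a cross-sectional cohort (default n = 88, ages
sampled uniformly on 8–19 y, male fraction 42/88). Pubertal stage is
`pds = clip(round(a + b·age + ε), 1, 5)` with the linear ramp mapping the
age range onto stages 1–5 and ε ~ N(0, 0.67); the noise SD was calibrated
once so that a linear regression of pds on age attains R² ≈ 0.72 in
expectation. Ages are uniform because no empirical age histogram is assumed;
all noise is Gaussian, matching the linear models used downstream.

### Effect model and its calibration algebra

Each network–metric pair carries an `EffectSpec` (standardized age slope
`beta_age`, optional sex contrast, target adjusted R², baseline mean/SD).
The latent outcome is

    y* = beta_age · z(age) + beta_sex · sex_c + σ ε,   sex_c ∈ {−½, +½},

with σ² chosen from `r2_target` so the population R² of the (age, sex)
model equals the target, and y* rescaled to unit variance. With age as the
only signal predictor, the standardized slope and the model R² are coupled
(R² = β²); the packaged effect table therefore stores `r2_target = β²`
wherever only one of the two is externally specified, and the `EffectSpec`
validator enforces `β² ≤ r2_target + 0.05`. Under this construction the OLS
fit of the z-scored outcome on z-scored age recovers `beta_age` in
expectation up to O(1/n) attenuation (≈0.002 at n = 88, well inside the
Monte-Carlo error of 500-replicate recovery runs).

The packaged table (`cortexdev/data/default_effects.tsv`) encodes the
emulated study conditions: neurite fraction rising in all seven networks
(R² = 0.53), intracellular volume fraction (0.46) and orientation dispersion
(0.42) rising, apparent soma radius falling (0.48), FA falling everywhere
except the limbic network (0.27), mean diffusivity falling in the limbic
(β = −0.42) and rising in the somatomotor (+0.34) network, thickness and
grey-matter volume declining in specific networks (e.g. default-mode
thickness β = −0.59), surface area flat. Baseline means/SDs are realistic
placeholders (e.g. thickness 2.8 ± 0.15 mm, R_soma 11 ± 0.7 µm) and are
config-exposed; no published per-network raw means were assumed.

### Signal fractions on the simplex

The three signal fractions must close to 1 exactly. They are generated
logistic-normally: Gaussian latents on the additive-log-ratio scale
(extracellular as reference) pushed through a softmax. The latents are
premultiplied by the inverse softmax Jacobian at the baseline composition
(0.35/0.35/0.30), so at the small dispersions used (SD 0.03) the observed
neurite and soma fractions are `baseline + sd·y*` to first order and their
configured standardized effects survive the nonlinearity (verified to
≈1e-3 at n = 5000). The extracellular fraction is implied by closure; its
age trend is therefore a consequence of the other two (qualitatively a
decline, consistent with the emulated study), not an independently
calibrated quantity — the packaged f_extracellular coefficients are
reference values, not generator inputs.

### Repeatability tables

`generate_repeatability` uses the additive two-way random-effects model
`x_ij = μ + b_i + s_j + e_ij`. The implied ICC is
σ_b²/(σ_b² + σ_s² + σ_e²). The default splits the within-subject variance
evenly between session and residual components; only the total is
externally constrained.

## 2. Network statistics

`fit_age_model` fits OLS on the z-scored outcome with z-scored continuous
predictors and sex coded ±0.5 (so β_sex is a mean contrast); CIs use
t-quantiles (n = 88 is small-sample territory). `select_model_aic` requires
all candidates to be fitted on identical rows and returns the lowest-AIC
model, breaking ties toward fewer parameters then listed order. Note that
AIC will admit a pure-noise extra regressor with probability ≈0.16, so
"the true model wins ≥90% of the time" holds for candidate families of
competing hypotheses (age vs sex vs puberty), not for nested
noise-augmented families. Significance uses the strict rule p < 0.005 with
no multiple-testing correction across networks, mirroring the emulated
analysis design.

`icc_absolute_agreement` computes ICC(2,1) — single-measure, two-way random
effects, absolute agreement — from the ANOVA mean squares:
`(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)`. Negative estimates are
returned as computed and flagged. **Small-sample caveat:** the estimator is
a ratio of noisy mean squares; at a 6 × 5 grid with a true ratio of 0.97 its
expectation is ≈0.954 (Jensen bias ≈ −0.016, SD ≈ 0.046; 20 000-replicate
simulation). The bias vanishes with grid size (≤0.01 by 40 × 10). Recovery
of the variance ratio to within 0.01 at the 6 × 5 design size is therefore
not achievable with this standard estimator, and the package reports the
honestly computed mean.

## 3. Penalized-spline trajectories

The smooth engine (`cortexdev.pspline`) uses a rank-5 cubic B-spline basis
(one interior knot at the median age) with the integrated squared second
derivative as penalty, computed exactly by two-point Gauss–Legendre per knot
span. Linear functions are unpenalized. The smooth is centered by a
null-space reparameterization (the fitted smooth sums to zero over the
samples), which removes the intercept confound and keeps the penalized
system full rank. Region-wise smooths (one per region, shared smoothing
parameter, region main effects in the fixed part) implement the
multi-region design; donor random effects are a centered, ridge-penalized
indicator block. All genes of a dataset share one design, so the smoothing
grid is solved once per grid point for the whole expression matrix.

Smoothing selection: GCV (`n·RSS/(n−edf)²`) on a log-spaced λ grid is the
default. A grid-based REML criterion
(`(n−M_p)·log(RSS+pen) + log|DᵀD+P| − log|P|₊`) is also implemented and is
the default whenever a donor ridge block is present, because GCV
systematically under-shrinks random-effect blocks. Both are config-exposed.

Smooth-term p-values: for single-smooth designs the p-value is the exact F
contrast of the *unpenalized* smooth block against the covariate(+donor)
null. Conditioning the F-test on a per-gene adaptively chosen penalty makes
the naive effective-df test anticonservative (measured: 9% of null genes
below p = 0.05; the exact contrast restores uniformity, KS p ≈ 0.75 over
2000 null genes), and the exact contrast is invariant to the per-gene
z-scoring of the normalized dialect. For region-wise designs the
unpenalized contrast spreads the signal over ~4 × 11 df and has almost no
power in a 20-donor design, so there the approximate effective-df F-test at
the selected penalty is used; it is documented as approximate (measured raw
null rejection ≈0.10 at α = 0.05) and is not the path on which FDR
guarantees are claimed. A frozen external-oracle test verifies the fitted
curves against an R mgcv thin-plate GCV fit on a 40-point fixture
(RMSE ≈ 0.03 between the two implementations' fitted values).

Age-gene selection applies Benjamini–Hochberg step-up to the smooth
p-values with strict q < 0.05. Cross-dataset replication is
|intersection| / |discovery| to three significant figures. In the default
synthetic configuration replication lands around 25%: the multi-region
validation design carries one age per donor, so its per-gene power is
intrinsically limited — a real feature of 20-donor designs, not an
implementation artifact.

### Trajectory summaries

Cell-type trajectories average per-gene fitted curves on a 0.1-y age grid
(z-scored per gene before averaging by default; demeaning and raw averaging
are options; constant curves normalize to zero). The 95% band is
mean ± 1.96·SE across genes. Peak growth is the earliest global maximum of
the mean first derivative, flagged as censored on a grid boundary; a flat
derivative returns none. The astrocyte-to-oligodendrocyte crossover is the
first grid age where the oligodendrocyte mean first rises above the
astrocyte mean, refined by linear interpolation, never extrapolated. On
noise-free generating curves the crossover estimator is exact to one grid
step; at the default noise level the fitted crossover is biased ~2–3 y late
(penalized fits attenuate the rise near its steepest point) while regional
*orderings* are preserved essentially always (100/100 seeded replicates).

Developmental-stage overlap uses windows infancy 0–1, childhood 1–12,
adolescence 12–20, young adulthood 20–40 y (config-exposed; no canonical
windows are assumed) and counts a gene as active in a stage when its fitted
|derivative| exceeds 0.02 expression-units per year — the threshold and the rule
are explicit package choices, since no standard rule exists for "a gene
overlaps a stage".

Enrichment is a one-sided Fisher exact test per gene set on the 2 × 2
overlap table over an explicit background universe, BH-corrected across
sets, flagged at q < 0.001; it is validated exhaustively against the
hypergeometric tail on all tables with total ≤ 30.

### Synthetic expression generator

The gene catalog assigns each gene one of seven cortical cell types with an
archetype trajectory: excitatory neurons and oligodendrocytes rise
logistically (oligodendrocyte midpoint 18.2 y, placing the noise-free
astrocyte/oligodendrocyte crossing at age 20.0 in the earliest regions and
≈25.3 y in medial frontal cortex), inhibitory neurons are flat, and
astrocytes, OPCs, microglia and endothelial genes decay exponentially.
Baselines reproduce the relative expression magnitudes of the cell classes
on the log2-RPKM scale (neurons highest ≈4.2, microglia lowest ≈1.8).
Rising genes carry regional timing offsets ordered along the
sensorimotor-to-association axis (M1/V1 earliest at 0 y … MFC latest at
+6 y). Per-gene jitter (midpoint ±1.5 y, amplitude/rate ±20%) creates
within-type heterogeneity. The multi-region dialect adds donor effects
(SD 0.2), an RIN covariate (slope 0.1 per RIN unit) and Gaussian noise
(SD 0.35); the single-region dialect is z-scored per gene after generation.
The generator does not emulate batch effects beyond RIN and donor, probe
level artifacts, count noise, or expression–expression correlation between
genes; passing tests therefore demonstrate estimator correctness under the
assumed generative structure, not robustness to microarray/RNA-seq
technical structure.

## 4. Soma-composition simulation

A grey-matter voxel holds five populations with literature count densities
(microglia 6 500, astrocytes 15 700, oligodendrocytes 12 500, neurons
92 000, endothelial = 0.35 × neurons per mm³) and Gaussian radii (2.0 ± 0.5,
5.5 ± 1.5, 5.5 ± 1.5, 8.0 ± 2.0, 9.0 ± 0.5 µm). Monte-Carlo estimation
draws a count-weighted radius sample (rejection resampling keeps radii
positive; at the σ/μ ratios above, rejection preserves the stated moments
far better than clipping) and computes `sqrt(mean(r⁵)/mean(r³))` with a
delta-method (or bootstrap) standard error. The closed-form oracle uses
Gaussian raw moments E[R³] = μ³ + 3μσ², E[R⁵] = μ⁵ + 10μ³σ² + 15μσ⁴,
count-weighted; it ignores the positivity truncation and warns when
σ/μ > 0.4. Monte-Carlo and oracle agree within 3·SE (+0.01 µm truncation
margin) across 100 random population sets at 10⁵ samples.

Age coupling multiplies each population's count by `1 + s·(age − 8)`
(linear; exponential available), radii untouched, with an error on any
negative count. The default slope vector (oligodendrocyte +0.02/y,
astrocyte −0.01, microglia and endothelial −0.005, neurons fixed) encodes
the qualitative pattern implied by the cell-type expression trajectories —
an oligodendrocyte-dominant shift — with magnitudes as an explicit
calibration choice exposed in config: the true expression-to-count
proportionality constant is unknown, so the simulation's *direction* (a
monotone decline of the apparent radius over 8–19 y) is a tested property
while the *magnitude* of the percent change scales with the configured
slopes and is not asserted. Voxel totals drift with age (counts are not
renormalized); whether to hold totals fixed is a modelling choice with no
external constraint.

## 5. Pipeline

`run_pipeline` executes simulate-cohort → fit-networks /
simulate-expression → fit-trajectories → simulate-soma with one global
seed; per-generator SeedSequence sub-streams keep the modules' randomness
decoupled. Every table carries a `# config_hash=… seed=…` header and a JSON
manifest lists all outputs; re-running a configuration reproduces every
output byte-identically. Stages can be run singly (with explicit dependency
errors) or resumed from on-disk outputs.

## 6. Problem sizes and runtimes

Defaults used by the scripts and tests: 500 replicate cohorts of n = 88 for
coefficient/R² recovery, 200 replicate 6 × 5 tables for ICC recovery, 210
genes (30 per cell type) per expression dataset, 100 replicates for FDR and
regional-ordering checks, 10⁵ Monte-Carlo radii per sweep age (10⁶ for
single high-precision comparisons). The full test-suite runs in roughly a
minute and a half on one CPU; the acceptance script in ~15 s.

## 7. Known limitations

- The ICC(2,1) recovery bias at tiny grids (section 2) is inherent to the
  estimator, not removable without changing the estimand.
- Multi-region smooth p-values are approximate (section 3); single-region
  p-values are exact under Gaussianity.
- The crossover estimator is late-biased at realistic noise; orderings, not
  absolute crossover ages, are the validated quantity.
- The expression generator's independence across genes understates the
  correlation structure of real transcriptomes; FDR control is demonstrated
  under independence.
- The soma simulation has no diffusion forward model, packing constraints or
  exchange; it maps composition to the moment-based radius only.
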
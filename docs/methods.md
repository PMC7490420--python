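# Methods

## Model and estimators

The MR arm works entirely on summary statistics. For instrument j, the
exposure GWAS supplies an effect estimate γ̂ⱼ with standard error σ_Xj and
the outcome GWAS supplies Γ̂ⱼ with σ_Yj, both per copy of the same effect
allele after harmonization. Under the instrumental-variable assumptions the
per-SNP ratio Γⱼ/γⱼ identifies the causal effect β of the exposure on the
outcome (log-odds scale for binary outcomes, so exp(β) is an odds ratio per
exposure unit).

**IVW.** Weighted regression of Γ̂ on γ̂ through the origin with weights
1/σ²_Yj; closed form β̂ = Σwγ̂Γ̂ / Σwγ̂², se = (Σwγ̂²)^(-1/2). With a single
SNP this reduces exactly to the Wald ratio Γ̂/γ̂ with se σ_Y/|γ̂|.

**MR-Egger.** The same regression with a free intercept θ₀. Exposure
effects are oriented positive first (flipping (γ̂, Γ̂) jointly — a no-op for
ratio estimators but required for the intercept to be identifiable). θ₀
estimates the average directional pleiotropic effect under the InSIDE
assumption (instrument strength independent of direct effects); it is
reported both raw and as exp(θ₀), the scale on which such intercepts are
conventionally quoted.

**Weighted median.** Per-SNP ratios β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with weights
wⱼ = γ̂ⱼ²/σ²_Yj normalized to one; sort β̂ ascending, form cumulative-weight
midpoints pⱼ = Σ_{i≤j} wᵢ − wⱼ/2, and linearly interpolate (p, β̂) at
p = 0.5 (clamped to the extreme ratios when 0.5 falls outside the midpoint
range). The SE is the standard deviation over parametric-bootstrap
replicates γ̂* ~ N(γ̂, σ²_X), Γ̂* ~ N(Γ̂, σ²_Y); default 1000 replicates,
one recorded seed per analysis.

**Heterogeneity and sensitivity.** Cochran's Q = Σ(Γ̂ − β̂γ̂)²/σ²_Y on n−1
df; leave-one-out re-estimation (default: robust IVW) with the full-set
estimate alongside.

**MR-PRESSO.** The observed statistic is the residual sum of squares with
each SNP's residual taken about the *leave-one-out* plain-IVW slope
(closed-form: β̂₋ⱼ = (S_xy − tⱼ)/(S_xx − uⱼ)). The null distribution is
simulated parametrically (γ̂* ~ N(γ̂, σ²_X), Γ̂* ~ N(β̂₋ⱼγ̂ⱼ, σ²_Y)) and the
same statistic recomputed per replicate; p-values use add-one smoothing
(1 + #{sim ≥ obs})/(n_sim + 1) and are therefore never zero. The per-SNP
outlier test compares each observed squared residual with its own simulated
distribution, Bonferroni-adjusted across SNPs; outlier removal is
single-pass. The distortion test compares the observed relative change
100·(β̂_corr − β̂_raw)/|β̂_corr| against the change from removing the same
number of SNPs at random. Plain IVW is used inside MR-PRESSO throughout
(the robust variant is reserved for headline estimates).

**Meta-analysis.** Ratio-scale study reports are log-transformed with
se = (ln CIᵤ − ln CIₗ)/(2·z) using z = 1.959964 (the precise 97.5% normal
quantile, not 1.96 — documented constant so CI back-conversion round-trips).
DerSimonian–Laird: Q from fixed (1/v) weights, τ² = max(0,(Q−df)/(S₁−S₂/S₁)),
random weights 1/(v+τ²), I² = max(0,(Q−df)/Q)·100. Hazard ratios pool
as-is with RRs; odds ratios convert to RRs via RR = OR/(1−p₀+p₀·OR) only
when a baseline risk p₀ is supplied (off by default — most study reports
omit p₀). Stratified results from one article enter as independent records;
the shared-control correlation this ignores is a documented limitation.
Egger's bias regression (deviate on precision, intercept t-test with k−2
df) and Begg's rank correlation (variance-standardized deviates vs
variances, explicit pair counting, tie-corrected normal approximation)
probe small-study effects.

## Statistical conventions

- p-values and CIs use **normal quantiles** everywhere in the MR arm (not
  t), so plain, robust and bootstrap methods are directly comparable. The
  exception is the two meta-analysis bias tests, which keep their
  conventional small-k t forms.
- Standard errors carry a **multiplicative random-effects scaling**
  max(1, √(RSS_w/(n−p))): over-dispersion from pleiotropy widens intervals,
  under-dispersion never narrows them.
- **Robust fitting** is iteratively reweighted M-estimation with the Tukey
  bisquare loss, tuning constant 4.685 (≈95% Gaussian efficiency), at most
  200 iterations at tolerance 1e-8, on precision-scaled variables; a fit
  that fails or returns non-finite parameters falls back to the plain
  estimate with a logged warning.
- **Strict inequalities at both instrument thresholds**: retained when
  P < 5×10⁻⁸ (exposure) and when P > 0.05 (disease); boundary values are
  excluded in both directions. Candidates absent from the disease GWAS are
  dropped — absence of evidence of disease association is not evidence of
  absence, and the instrument's defining property cannot be certified.
- **Palindromic variants** (A/T, C/G) default to frequency inference:
  aligned when both allele frequencies sit on the same side of 0.5, flipped
  when opposite, dropped when either frequency is missing or inside the
  ambiguity band [0.42, 0.58]. A `drop` policy removes them all. Indels are
  never classified palindromic.
- **Clump determinism**: candidates are visited by ascending p-value with
  rsid as tiebreak, so output is independent of input row order.
  Cross-chromosome pairs never clump regardless of tabulated r².
- Duplicate rsids at load keep the smallest p-value; floats are written
  with `repr` and parsed with correctly-rounded conversion, so file
  round-trips are bit-exact.

## What the generator emulates — and what it does not

`simulate.gen_mr_dataset` draws, per SNP: maf ~ U(0.1, 0.5); true effect
magnitude ~ U(0.05, 0.15) with random sign; GWAS standard errors
1/√(2·maf(1−maf)·n) for a standardized quantitative trait, reused on the
log-odds scale for binary outcomes (a desk-scale approximation that skips
genotype simulation); observed effects as independent normal draws around
truth. Defaults mirror the fasting-glucose → CAD setting the package
targets: 28 instruments, exposure GWAS n = 133,010, causal OR 1.26 per
mmol/L; the outcome GWAS size defaults to 300,000 as a realistic
cardiovascular-consortium scale (the analysis is insensitive to it beyond
setting σ_Y). Pleiotropy regimes: `balanced` (mean-zero direct effects,
InSIDE holds), `directional` (positive-mean direct effects **anchored to
the exposure-increasing allele**, so orientation does not wash the
direction out), `inside_violating` (direct effects correlated with
instrument strength); `pleiotropy_frac` confines any regime to a random
subset of instruments (e.g. the 30%-invalid contamination setting).
Outliers add a fixed multiple of σ_Y. Strand/allele corruption rewrites
the outcome records (complemented alleles; swapped coding with negated
effect and mirrored frequency; palindromic recoding resolvable by
frequency) without touching the underlying effect draws — each component
has its own RNG sub-stream. Palindromic variants are generated with
frequencies outside the ambiguity band so corruption stays invertible;
ambiguous palindromes can be produced by widening `maf_range`.

Disease-GWAS p-values are planted deterministically on either side of the
0.05 exclusion threshold (designated SNPs uniform on (0, 0.05), the rest
on (0.05, 1)) so filter tests have exact expected outcomes.

The meta generator draws study effects θᵢ ~ N(μ, τ²), se ~ U(0.05, 0.3),
reported estimate y ~ N(θ + b·se, se²) where b is an optional small-study
bias coefficient; defaults are a 21-study corpus with μ = ln 1.16 and
τ = 0.05.

What passing tests on this generator do **not** show about real data: no
LD between instruments beyond the block matrix supplied to clumping; no
winner's-curse selection (instrument effects are not re-estimated after
significance filtering); no sample overlap between exposure and outcome
GWAS; Gaussian effect noise with known SEs; meta-analysis studies are
independent (no shared controls) with exactly reported CIs.

## Benchmark conditions and observed calibration

The `validation` module fixes the simulation benchmarks' problem sizes so
the full suite runs in well under a minute on one CPU: 100 random fixtures
for oracle agreement; 500 replicates for IVW recovery/coverage and the
contamination comparison; 1000 for Egger intercept type-I error; 200
(with 500 inner simulations) for the MR-PRESSO operating characteristics;
500 for meta-analysis recovery and 200 for bias-test power. All replicate
seeds derive from a single master seed.

Two calibration notes a user should know:

- Plain IVW carries a small finite-sample attenuation of order
  E[σ²_X/γ²] (≈0.1–0.2% relative at the default instrument strengths)
  because observed exposure effects enter both axes of the regression.
  It is visible only at Monte-Carlo precision of ~500+ replicates and is a
  property of the estimator, not of this implementation.
- The Egger intercept test with normal quantiles runs slightly hot
  (≈0.06 true size at n = 28 instruments, where exact t quantiles would
  give 0.05), and additive pleiotropy interacts with the multiplicative
  dispersion model: the benchmark's balanced-pleiotropy SD (0.002) is set
  to the magnitude producing the moderate between-SNP heterogeneity
  (I² ≈ 20–30%) characteristic of the target setting; much larger direct
  effects make the multiplicative model increasingly misspecified and the
  intercept test anticonservative.

The MR-PRESSO outlier benchmark uses 20-SNP sets: with 500 null
simulations the smallest achievable Bonferroni-adjusted p is n/501, so
per-SNP detection at α = 0.05 requires n ≤ 25; a single 10σ outlier is
detected essentially always, while swamping (the outlier dragging
leave-one-out slopes of clean SNPs) produces occasional false co-flags —
a known property of the single-pass procedure.

## Design choices where the design was open

- **Robust = IRLS M-estimation** (Tukey bisquare, 4.685) rather than a full
  S-then-M chain; for the well-conditioned weighted regressions MR
  produces, the two coincide in practice, and the fallback-to-plain rule
  keeps degenerate fits visible rather than silently wrong.
- **Bonferroni** for per-SNP outlier p-values (the conservative,
  conventional choice for a small number of exchangeable tests).
- **No multiple-testing adjustment** across methods or outcomes — the
  per-method results are reported unadjusted, as is conventional for
  sensitivity batteries.
- **Disease-absent candidates dropped** (see conventions above); logged
  separately from exclusions so the accounting distinguishes "associated"
  from "unknowable".
- The pipeline treats ancestry restriction as the user's data-selection
  responsibility and records the declared ancestry label only; genome
  build is treated as opaque-but-consistent within one analysis (no
  liftover).

## Known limitations

- No proxy-SNP search for instruments missing from the outcome GWAS.
- No LD computation from genotypes — r² is an input.
- No mode-based, multivariable, or contamination-mixture estimators.
- Single-pass outlier correction (no iterative re-testing).
- OR→RR conversion requires a user-supplied baseline risk.
- The external full-scale reproduction (public consortium files) is out of
  desk scope; `predimr reproduce` prints where to obtain the files.
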
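# Methods

## Model and assumptions

`gutmr` performs two-sample summary-data Mendelian randomization. For each
instrument SNP j the inputs are the estimated SNP–exposure effect γ̂ⱼ with
standard error σ_γⱼ (abundance of a bacterial taxon, rank-normalized so
effects are in SD units) and the SNP–outcome effect Γ̂ⱼ with σ_Γⱼ (log-odds
of disease). The causal model is

    Γⱼ = θ·γⱼ + αⱼ,

where θ is the causal log-odds ratio per SD of abundance and αⱼ a possible
direct (pleiotropic) path. Identification needs the three instrumental-
variable assumptions: relevance (γⱼ ≠ 0, enforced by the significance and
F gates), independence from confounders (approximated by the confounder-SNP
exclusion list), and exclusion restriction (αⱼ = 0, probed rather than
assumed — by MR-Egger's intercept, the weighted median's 50 %-validity
robustness, MR-PRESSO and leave-one-out).

## Estimators and numerical choices

* **Wald ratio / IVW.** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Γⱼ/|γ̂ⱼ|; IVW is
  the precision-weighted mean with wⱼ = γ̂ⱼ²/σ_Γⱼ², algebraically the
  zero-intercept weighted least-squares slope of Γ̂ on γ̂ with weights
  1/σ_Γⱼ². First-order weights are the convention of the standard
  summary-data MR toolchain; they ignore σ_γⱼ, which costs a little coverage
  when instruments are only moderately strong (see Calibration below).
* **Random effects.** Multiplicative overdispersion: the fixed-effect SE is
  inflated by sqrt(max(1, Q/(J−1))), never deflated. `mode="auto"` (the
  pipeline default) applies it when Cochran's Q has p < 0.05.
* **MR-Egger.** Instruments are oriented so every γ̂ⱼ > 0 (both effects
  negated together — estimates are invariant to joint sign flips), then a
  two-parameter weighted regression is fit by the normal equations. The
  coefficient covariance uses the same multiplicative variance inflation
  floored at 1. The intercept's two-sided normal p tests directional
  pleiotropy at 0.05.
* **Weighted median.** Wald ratios are sorted; with normalized weights pⱼ
  the estimate linearly interpolates the ratios against the cumulative-weight
  midpoints sⱼ = Σ≤ⱼ p − pⱼ/2 at probability 0.5. The interpolation is the
  field's standard definition; a dominant instrument pins the estimate to its
  ratio only in the limit (or exactly when its midpoint hits 0.5). SEs come
  from a parametric bootstrap (default 1,000 replicates) that resamples
  (γ̂ⱼ, Γ̂ⱼ) from their sampling normals under a fixed seed.
* **p-values** use the standard normal throughout (not t), matching
  summary-data MR convention; with very few instruments Egger's p is
  therefore slightly anticonservative.
* **Significance grading.** `none` below IVW p < 0.05; `nominal` at
  IVW p < 0.05; `significant` when additionally at least one of
  {MR-Egger, weighted median} is p < 0.05 with the same sign as IVW *and*
  the sensitivity profile is clean (Egger intercept p ≥ 0.05, no MR-PRESSO
  outliers). No multiplicity correction across taxa is applied by default;
  reports can carry an optional FDR column.

## Sensitivity suite

Cochran's Q is computed about the fixed-effect IVW estimate and referred to
χ²(J−1). MR-PRESSO's observed statistic is the leave-one-out weighted
residual sum of squares Σⱼ (Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)²/σ_Γⱼ²; its null distribution is
simulated parametrically (γ*ⱼ ~ N(γ̂ⱼ, σ_γⱼ), Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Γⱼ),
default 1,000 draws), with add-one empirical p-values (minimum 1/(n_sim+1)).
Per-SNP outlier tests use the same simulated terms at a Bonferroni level
0.05/J; the distortion test compares the outlier-free estimate against
removals of random subsets of equal size. Each SNP's simulation stream is
keyed by hashing its rsid into the master seed, so results are invariant to
instrument order. Leave-one-out reports the J reduced IVW estimates plus
Cook's distance from the zero-intercept weighted regression, flag threshold
0.5 (a 4/J rule is available). A numerically perfect fit (residuals at
machine precision relative to the data scale) reports all distances as 0.

## MR-BMA

With K candidate exposures and the union of their instruments (J rows;
missing SNP–exposure entries set to 0, counted in the log), rows are scaled
by 1/se_y so errors are standard normal, and each non-empty subset S gets
the closed-form marginal likelihood of y ~ N(0, σ²X_S X_Sᵀ + I) under the
N(0, σ²) shrinkage prior, evaluated through the |S|×|S| matrix
A = X_SᵀX_S + I/σ². Priors are independent inclusions (default p = 0.25,
one of four exposures expected causal; σ = 0.5 on the log-odds scale) —
MIP *ranking* is insensitive to both within a broad range, though PP values
move. Enumeration is exhaustive (K ≤ 20). Best models are those with
PP ≥ 0.02; per-SNP diagnostics on each best model are q_j (squared
standardized residual; flag at q > 10) and Cook's distance from the ridge
hat matrix (flag at the median of F(|S|, J−|S|), or a fixed override). The
fit–flag–remove loop repeats until no flags remain or fewer than 3K
instruments would survive. Permutation p-values permute (y, se_y) rows
jointly (default 100 permutations), so every reported p is a multiple of
1/101 with minimum 1/101.

## Synthetic data

The generator emulates the summary statistics of a microbiome-exposure /
rare-disease-outcome design: exposure GWAS at n = 18,340 and a case–control
outcome GWAS with 538 cases / 341,961 controls (effective size
n_eff = 4/(1/cases + 1/controls) ≈ 2,149). Per SNP, MAF ~ U(0.05, 0.5),
σ_γ and σ_Γ follow the analytic 1/sqrt(2p(1−p)n) form, and true γⱼ are sized
by a per-SNP variance-explained draw, default U(0.0012, 0.003) — chosen so
instruments sit at locus-wide significance (|z| ≈ 4.7–7.4) with per-taxon
F well above 10, the regime the locus-wide selection threshold implies.
`outcome_se_scale` (default 1.0) can inflate outcome SEs toward what
rare-disease GWAS actually report (saddlepoint-corrected fits with
covariates give larger SEs than the analytic approximation; ≈ 2 reproduces
published IVW CI widths of 0.3–0.4 at an 8-instrument design). Pleiotropy
modes: none; balanced N(0, τ); directional N(μ_α, τ); and InSIDE-violating
(corr(αⱼ, |γⱼ|) = 0.8). Directional pleiotropy acts in the
exposure-increasing-allele frame, since a per-allele constant would average
out under arbitrary reported-allele orientation. Multi-exposure designs draw
SNP–exposure effects with exchangeable correlation across exposures and
anchor each instrument to a "home" exposure so all columns are instrumented.

What the generator does **not** emulate: winner's-curse selection bias (true
effects are drawn at instrument strength rather than selected from a
genome-wide pool), LD between instruments after clumping (the LD module is
block-structured and used only to exercise clumping/proxy logic), sample
overlap between exposure and outcome GWAS, and non-normal effect-size
distributions. Passing tests therefore demonstrate correctness of the
estimators and pipeline mechanics under the stated sampling model, not
robustness to every artefact of real consortium data.

## Calibration results the tests compute

Under the default design, 95 % CI coverage of IVW at θ = ln(3.471), J = 8 is
≈ 0.93–0.94 rather than 0.95: first-order weights ignore the exposure-side
noise (|z| ≈ 5–7 instruments), which both attenuates the estimate slightly
and underestimates its SE — a documented property of the estimator, not of
the implementation. Type-I error under balanced pleiotropy is checked at
τ = 0.01 (pleiotropy SD ≈ 30 % of the median per-SNP outcome SE); with
pleiotropic variance comparable to the sampling variance the multiplicative
random-effects correction under-corrects at small J (rejection up to ~0.09
at τ = σ_Γ, J = 8) — the known cost of estimating overdispersion from few
instruments. The MR-PRESSO global test, the Egger-intercept recovery of a
planted directional mean, planted-outlier detection, MIP-rank recovery and
the end-to-end detection of the four-taxon study are all computed afresh by
`tests/test_acceptance.py` and `scripts/acceptance.py`; problem sizes there
(1,000 calibration replicates, 500×500 PRESSO draws, 200 ranking
replicates, 100 end-to-end runs) were chosen to keep Monte-Carlo error well
inside the asserted bands.

## Design choices where the design was open

* Per-SNP variance explained uses 2p(1−p)β² (variance-standardized
  exposure); an se-based fallback β²/(β² + n·se²) serves records without
  allele frequencies. The F gate applies per taxon (the formula contains k).
* Clumping takes an explicit LD matrix (no remote reference panel), breaking
  p-value ties by rsid so output is order-invariant.
* Palindromic SNPs are always dropped — no allele-frequency rescue.
* Proxies are outcome-side only, use the proxy's own outcome effect (an
  r²-only matrix carries no phase), and must still be allele-compatible.
* Reverse-direction instrument selection defaults to genome-wide 5e-8
  (disease GWAS are well powered; the locus-wide relaxation is justified
  only for abundance traits); config-overridable.
* The BMA "causal estimate" column reports the top-PP model's coefficient
  and labels it as such (distinct from the MACE).

## Known limitations

Egger p-values with J < 10 are optimistic (normal, not t). The weighted
median's bootstrap SE ignores weight re-estimation uncertainty beyond the
resampling itself. MR-PRESSO's distortion null (random equal-size removals)
is a permutation surrogate, coarser than re-simulating outliers. The BMA
marginal likelihood conditions on the fixed shrinkage scale σ rather than
integrating it out. None of these affect the oracle-equivalence or ranking
properties the suite asserts.
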
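# Methods

This note documents the statistical model behind `coagmr`, the defaults and
why they were chosen, the synthetic-data generator's assumptions, and the
numerical decisions that affect results.

## Study design

The pipeline estimates the causal effect of a circulating protein (or a
gene's hepatic expression) on binary clinical outcomes using genetic variants
as instruments, under the two-sample summary-statistics design: exposure
effects from a pQTL/eQTL GWAS (effects in SD units after inverse-rank-normal
transformation), outcome effects from disease GWAS (log-odds). Outcomes are
grouped into an efficacy class (thrombotic disease: VTE, cardioembolic
stroke), a safety class (bleeding), and optionally lifespan. A target is
reported **favourable** when every efficacy outcome is significant
(p < 0.05, configurable) and protective (95% CI entirely below 0 on the
per-SD-higher scale) while every safety outcome is null; **concordant** when
all primary estimates across strategies/datasets have CIs on the same side
of 0.

Three instrument-selection strategies trade specificity against power:

| strategy | variants | clumping | estimator |
|---|---|---|---|
| uni-cis | smallest-p variant within the cis window | — | Wald ratio |
| multi-cis | cis variants at P < 5e−8 | r² < 0.1 | IVW-MRE + robust |
| pan | genome-wide at P < 5e−8 | r² < 0.01, 1 Mb windows | IVW-MRE + robust |

The cis window is ±1 Mb around the transcription start site by default;
±500 kb is available as a dialect for cohorts that release only cis
statistics. Coordinates are 1-based and windows are inclusive on both ends.

## Harmonization

Outcome effects are aligned onto the exposure's effect allele; a swapped
allele pair flips the sign and the frequency. Palindromic (A/T, C/G) variants
are aligned by allele frequency when the minor-allele frequency is below 0.42
(configurable) and dropped otherwise — frequency cannot distinguish strands
near 0.5. Variants missing from the outcome are replaced by their best LD
proxy subject to r² > 0.6 (strict), outcome side only; the signed correlation
orients the proxy's effect (unsigned r² cannot), and ties in r² go to the
smaller genomic position so output is deterministic. Rows with missing
frequency are kept for MR but excluded from any frequency-dependent step,
with an audit count.

## Estimators

* **Wald ratio** — first-order delta-method SE (se_Y/|β̂_X|). The
  second-order term θ²·se_X²/β̂_X² matters when exposure and outcome SEs are
  comparable, but including it in the weights couples them to the outcome
  noise and worsens interval calibration, so the first-order form is kept and
  the residual dispersion is absorbed by the multiplicative random effects.
* **IVW-MRE** — weighted mean of ratios; SE = fixed-effect SE ×
  √max(1, Q/(J−1)). The floor at 1 is the "underdispersion correction":
  dispersion below its null expectation never tightens the interval. A single
  instrument is routed to the Wald ratio (explicitly, never silently).
* **MR-Egger** — WLS of β̂_Y on β̂_X with intercept, weights 1/se_Y²,
  exposure effects oriented positive first (the intercept is meaningless
  otherwise); same dispersion floor. The intercept and its p-value are the
  directional-pleiotropy test. Note the intercept is only identified when
  instrument strengths vary; near-equal β̂_X make intercept and slope
  collinear and the test uninformative.
* **Weighted median** — interpolated weighted 50% quantile of ratios
  (cumulative weights minus half each weight); SE by seeded parametric
  bootstrap (1000 draws). Consistent while valid instruments carry >50% of
  the weight; under one-sided contamination just below that limit it retains
  a quantile bias of order the ratio SE — an estimator property, not an
  implementation artefact.
* **Contamination mixture** — profile log-likelihood over a θ grid; each
  instrument contributes max(valid, invalid) component log-density. ψ
  defaults to 1.5 × SD of the ratio estimates (fallback 1.5 × mean ratio SE
  for a single instrument). The grid spans the IVW estimate ± 5 SE *and* the
  full range of ratio estimates ± 4 SE — centring on IVW alone can miss the
  global mode under contamination. 5001 points; the 95% confidence set is
  {θ: logL ≥ max − 1.92}; the connected component containing the maximum is
  reported with a multimodality flag. When the invalid component can absorb
  every instrument the set is unbounded; it is then clamped to the evaluated
  grid rather than widened forever. The reported SE is the CI width / 3.92
  (a normal approximation used only for the p-value column).
* **MR-PRESSO-style outlier test** — global test: parametric bootstrap
  (default 1000 draws, seeded) of the weighted leave-one-out residual sum of
  squares. Outlier detection is stepwise: the most extreme instrument with
  Bonferroni-significant residual is removed and the procedure repeats,
  because a single gross outlier contaminates every leave-one-out fit and a
  one-pass rule would flag everything. The reported estimate is IVW-MRE on
  the surviving instruments. The distortion test is not implemented.

All confidence intervals and p-values are two-sided normal. No
multiple-testing correction is applied across targets (reported raw).

## Filters

* **Strength**: F = z_X²; flagged weak unless F > 10 (strict). Variance
  explained r² = z²/(z²+n), frequency-free; a 2f(1−f)β² alternative is
  available. Binary-trait r² is computed on the observed log-odds scale (no
  liability-scale conversion) — a documented approximation that slightly
  overstates outcome variance explained for rare outcomes.
* **Steiger**: correlations √r² from the two independent samples compared on
  Fisher's z scale, statistic (z_X − z_Y)/√(1/(n_X−3) + 1/(n_Y−3)),
  two-sided. Instruments with r²_Y > r²_X and p < 0.05 are removed
  (idempotent).
* **Altering variants**: instruments annotated as protein-altering are
  removed (epitope-binding artefact guard); unannotated instruments are kept
  and counted.

## Colocalization

Wakefield log-ABFs with prior effect variance w = 0.2² for quantitative and
0.15² for case-control traits (the cited conventions; configurable).
Hypothesis accumulation runs entirely in log space (logsumexp); the H3 sum
over distinct-variant pairs uses log(e^{S1+S2} − e^{S12}) with a clip to −∞
when rounding makes the argument non-positive, and single-variant regions
set PPH3 = 0 exactly. Case-control z-scores are used on the log-odds scale
directly, without sdY estimation. Priors p1 = p2 = 1e−4, p12 = 1e−5;
colocalization is called at PPH4 > 0.50. When one exposure is measured by
several aptamers, each is a separate run; any cross-aptamer averaging of
PPH4 is a report-level mean, not part of the model.

## Meta-analysis and loci

Fixed-effect inverse-variance combination (the METAL effect-size scheme, not
the sample-size scheme): β_meta = Σβ_i/se_i² / Σ1/se_i². The first cohort
reporting a variant fixes allele orientation; unresolvable pairs are dropped
per variant with an audit. A lone cohort passes through bit-exactly.
Cross-cohort Cochran's Q is reported, never filtered on. Locus counting
clumps at P < 5e−8 (strict), r² < 0.01, 1 Mb windows, and annotates leads
with the nearest gene by |position − TSS| on the same chromosome (ties:
lexicographic gene id).

## Synthetic-data generator

A region of n SNPs carries AR(1) LD, r(i,j) = ρ^|i−j| (positive definite for
0 ≤ ρ < 1). Causal per-allele effects are placed per scenario; marginal GWAS
effects are b_marg = R·b_causal; observed effects add sampling noise with

* quantitative: se = 1/√(2f(1−f)·n),
* binary (log-odds): se = 1/√(2f(1−f)·n_cases·(1−n_cases/n)),

f ~ U(0.05, 0.5) by default. Noise is independent per SNP by default (keeps
ratio-based MR analytically tractable); the multivariate option draws noise
with the LD correlation, which makes the regional association field smooth
as in real GWAS — colocalization scenarios and the packaged panel use it,
since with independent noise the two traits' lead variants decouple in high
LD and PPH4 for a genuinely shared variant becomes unstable.

Defaults are the study conditions throughout: exposure GWAS n = 35,559
(discovery proteomics cohort scale), outcome GWAS 44,223 cases among 891,375
(VTE meta-analysis scale). Instrument exposure effects default to
|β| ~ U(0.15, 0.3) per allele — z ≈ 18–37 at that n, the strength range
typical of discovery-cohort cis-pQTLs (top coagulation-factor pQTLs reach
p < 1e−80). Pleiotropic direct effects α are applied in the oriented frame
(sign-tied to the exposure-increasing allele) so a positive mean is genuinely
directional; the contamination benchmark uses α ~ N(0.5, 0.5²) — large
relative to θ, with a minority (~16%) of negative effects, the regime where
IVW is visibly biased while the weighted median and contamination mixture
retain their guarantees. The reverse-causation scenario plants
outcome-causal variants (|β_Y| = 0.6) whose exposure association is a 12.5%
leak, giving r²_Y > r²_X at the planted variants. MR scenarios simulate at
the summary-statistic level only; no individual genotypes or coalescent
structure.

What the generator does **not** emulate: sample overlap between exposure and
outcome GWAS, population stratification, imputation noise, winner's curse
from discovery-based instrument selection, allele-frequency differences
between cohorts, and real LD (block structure, long-range LD). Passing tests
therefore establish the correctness and calibration of the statistical
machinery under the stated model, not robustness to those artefacts.

The packaged demonstration panel (fixed seed 20240527, part of the fixture
definition) contains two protein exposures in separate LD blocks, each with
one dominant causal cis variant (|β| = 0.12, at the TSS, shared with the
outcomes — the colocalization-H4 arrangement) and two weaker independent
signals (0.06, 0.055) so multi-cis selection has several instruments. True
outcome effects: TARGET1 θ = −0.5 (VTE), −0.3 (stroke), 0 (bleeding) —
favourable; TARGET2 +0.3/+0.2/+0.3 — harmful control.

## Calibration results the code computes

`analysis/05_estimator_calibration.py` and the acceptance script measure:
IVW-MRE 95% CI coverage 0.944 over 500 replicates at the default scale
(50 valid instruments, θ = ln 0.61); robust-estimator mean deviation under
40% contamination of ≈ +1.9 SE (weighted median, its structural quantile
bias) and ≈ +0.3 SE (contamination mixture). Steiger removes 100% of planted
reverse-causal instruments and stepwise PRESSO detects a planted α = 1.0
outlier in ≈100% of replicates at the benchmark configuration.

## Known limitations

* Binary-trait r² and the Steiger comparison use the log-odds scale without
  liability conversion; directionality conclusions are approximations for
  very unbalanced case-control ratios.
* The contamination mixture's p-value is a normal approximation from its CI
  width; under multimodality the flag should be consulted before trusting it.
* Proxy search uses the LD matrix's variant universe; proxies outside the
  supplied matrix are invisible.
* MR-PRESSO's distortion test, multivariable MR, liability-scale conversion
  and SuSiE-style multi-signal colocalization are out of scope.
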
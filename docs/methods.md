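# Methods

This note records the statistical model behind each stage of the screening
framework, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## Data model

Summary statistics are per-variant association tables (rsID, chromosome,
1-based position, effect/other allele, effect-allele frequency, beta, SE,
p, N) in an uncompressed TSV dialect. Only biallelic SNVs with
single-character A/C/G/T alleles are modelled; indels are rejected at
validation because the harmonisation rules (swap, strand complement,
palindrome frequency matching) are defined for SNVs. LD is represented
block-diagonally: pairwise r² within blocks, zero across blocks, plus an
explicit allele phase per correlated pair — proxy substitution needs to
know which proxy allele co-occurs with the index variant's effect allele,
and r² alone cannot tell.

## Instrument selection and harmonisation

Selection walks the ladder 5e-8, 5e-7, 5e-6, 5e-5 and stops at the first
rung with at least `min_count = 6` post-clumping instruments ("more than
five"). Counting happens after clumping because only clumped instruments
enter the analysis. Traits that never reach six instruments are excluded
and logged, not analysed underpowered. Clumping is greedy: lowest p first,
discarding candidates with r² > 0.001 within 10,000 kb on the same
chromosome; variants missing from the LD reference are treated as
independent and logged.

Harmonisation aligns all rows to the exposure's effect allele: swapped
labels flip the outcome beta, strand complements are complemented first,
and palindromic (A/T, G/C) variants are aligned by allele frequency —
kept with unchanged (flipped) sign when the two datasets' effect-allele
frequencies fall on the same (opposite) side of 0.5 — or dropped when
min(EAF, 1−EAF) > 0.42 in either dataset, where strand cannot be resolved
reliably. Palindromic variants with missing frequency are dropped
(frequency is the only alignment signal). Proxies require r² ≥ 0.9, the
highest-r² candidate winning with ties broken by outcome p then id.

Two filters precede estimation, by default in this order (configurable):
instruments more significant for the outcome than the exposure are removed
(a directionality guard: a valid instrument acts on the outcome only
through the exposure), then radial-MR outliers. Radial weights are the
modified second-order form w_j = β̂²_Xj/(σ²_Yj + θ̂²σ²_Xj); since they
depend on the slope, weight and slope updates iterate to a fixed point
(tolerance 1e-10). Per-variant contributions q_j are referred to the
chi-square(1) upper tail at α = 0.05 without multiplicity correction,
removal and refitting repeating until no contribution exceeds the cut-off.

## Estimators

* **IVW.** Closed-form weighted regression through the origin with weights
  1/σ²_Y. The multiplicative-random-effects SE multiplies the fixed-effect
  SE by max(1, √(Q/(J−1))); p-values are normal. MRE is the primary
  estimate because a phenome-wide screen is certain to contain
  heterogeneous instruments; it is deliberately conservative under the
  null (the inflation factor never deflates), which shows up as a type-I
  error slightly below 5% in the calibration benchmark.
* **Egger.** Rows are oriented to β̂_X ≥ 0, then weighted regression with
  intercept; SEs inflated by max(1, √(Q_egger/(J−2))); inference on
  t(J−2). The intercept is the directional-pleiotropy test. Orientation on
  *observed* signs is only safe for genome-wide-significant instruments —
  near-null instruments whose sign is noise drag the intercept toward zero
  and the slope away — which is one more reason the pipeline estimates on
  ladder-selected instruments only. Egger results are reported but never
  substituted as the primary estimate; a significant intercept raises a
  flag.
* **Weighted median.** Interpolated weighted 50th percentile of the Wald
  ratios with inverse-variance weights from first-order ratio SEs
  (σ_Y/|β̂_X|; second-order available by config). SE by parametric
  bootstrap (defaults 1000 replicates, seeded): β̂_X, β̂_Y are redrawn from
  Gaussians at their SEs and the estimator recomputed, vectorised across
  replicates.
* **Weighted mode.** Argmax of a weighted Gaussian KDE over the ratios on
  a 512-point grid, bandwidth 0.9·min(sd, MAD)·J^(−1/5) times a
  configurable factor (default 1); bootstrap SE as above. A zero bandwidth
  (all ratios identical) returns the common ratio.
* **QC battery.** Per-variant F_j = (β̂_X/σ_X)², weak-instrument flag at
  mean F ≤ 10; Cochran's Q with chi-square(J−1) p; Egger intercept test;
  I²_GX = (Q_GX − (J−1))/Q_GX floored at 0, with Q_GX the 1/σ²_X-weighted
  dispersion of the oriented |β̂_X| (the exact form is recorded in the
  report's notes), NOME-violation flag below 0.9; leave-one-out MRE IVW
  refits, unstable when the full-set p is significant but any single
  omission lifts p to ≥ 0.05.

Effect sizes: continuous exposures additionally report OR = exp(β) per
1 SD of exposure change; binary exposures report beta only (ORs per unit
log-odds of a binary exposure are uninformative).

## Screening

The per-trait pipeline is batch exclusion (defaults `ukb`, `met-d`,
mirroring exclusion of exposure sources that overlap the outcome cohort) →
selection → clumping → harmonisation → filters → estimators → QC.
Benjamini–Hochberg FDR (via statsmodels) is applied across the MRE IVW
p-values of all analysed traits in one invocation — the closest
reproducible family to a phenome-wide correction. The composite verdict
requires FDR p < 0.05, weighted median and mode nominally significant, and
every leave-one-out refit nominally significant. Estimator failures
downgrade a trait to excluded with the error recorded; a screen never
aborts. Duplicate traits (same normalised name) reduce to the largest
sample size, ties broken by larger mean F then lexicographic id.
Replication re-runs the pipeline for significant traits against a second
outcome without touching primary verdicts; reverse MR swaps the roles of
exposure and outcome. Bootstrap seeds derive from a CRC of the trait id so
verdicts are invariant to input order.

## Multivariable MR

IVW-MVMR is the 1/σ²_Y-weighted multiple regression of β̂_Y on the K
exposure columns without intercept; fixed-effect covariance, with
heterogeneity reported through the adjusted Q (chi-square(J−K)) rather
than folded into the SEs — when Q fires, the Q-minimisation estimator is
the appropriate follow-up. Conditional instrument strength for exposure k
regresses its effects on the other exposures by iterated weighted least
squares with delta-method residual variances and reports
F_k = Q_x,k/(J−K+1); with K=1 this is exactly the mean per-variant F,
anchoring the univariable convention. Estimating the auxiliary regression
by least squares (rather than minimising Q_x over the coefficients) is
essential: the global infimum of Q_x degenerates as the coefficients grow,
losing the target exposure entirely.

Selection starts at 5e-8 per exposure and relaxes by factors of 10 — only
for exposures with conditional F below 10 — down to a 5e-5 floor, with
every rung logged; a set that never reaches F > 10 is returned flagged
weak. Q_A(θ) uses the denominator σ²_Y + Σθ²σ²_X + 2Σθ_kθ_l·ρ·σ_Xkσ_Xl
with the phenotypic correlation ρ supplied by assumption (conventionally
run at both 0.1 and 0.9); minimisation is Nelder-Mead from the IVW
solution (so the minimised Q can never exceed the IVW Q), and confidence
intervals invert the per-coordinate Q_A profile at the chi-square(1) 95%
cut-off by outward walking plus bisection — deterministic, unlike a
bootstrap.

## MR-BMA

The standardised design is y_j = β̂_Yj/σ_Yj, x_jk = β̂_Xjk/σ_Yj, columns
scaled to unit variance. Each subset S is scored by the closed-form
marginal likelihood of a conjugate Gaussian model — effect prior
N(0, σ²θ I) with σ²θ = 0.25 (treated as a variance), unit residual
variance — times the independence prior p^|S|(1−p)^(K−|S|) with p = 0.1.
The empty model is included in the normalisation so that posterior mass
can collect on "no causal trait" under the null. MIP is the summed
posterior of models containing a trait; MACE is the posterior-weighted
shrinkage estimate, zero when absent, reported on the standardised scale
and indicative of direction more than magnitude.

The stochastic search (default 10,000 iterations) proposes add/delete/swap
moves accepted by posterior ratio and caches every distinct model visited;
probabilities are normalised over the cache, which provably agrees with
exhaustive enumeration as coverage grows (and is required to agree within
0.01 MIP for K ≤ 12, where enumeration is available). Traits correlated at
|r| ≥ 0.99 across instruments are pruned first, the removed member chosen
by seeded RNG to avoid selection bias.

Outlier diagnostics per top-ranked model: squared residual Q contributions
flagged above chi-square(1) at 0.05/J (Bonferroni across instruments), and
Cook's distances from the ridge fit flagged above the median of an
F(|S|, J−|S|) reference; numerically exact fits short-circuit Cook's
distance to zero. Flagged instruments are removed and the whole analysis
re-run until clean; removing everything raises a degenerate-input error.
Permutation p-values permute the response jointly (preserving the
predictor correlation structure under the null); because y'y is
permutation-invariant, each model's score changes only through a small
quadratic form, so all permutations are scored vectorised from z = X'y.
Default 100,000 permutations; benchmarks use 1000. Empirical p uses the
(1+count)/(1+P) convention so p > 0.

## Synthetic data

The generator emulates the two-sample setting: true per-variant exposure
effects from a zero-centred Gaussian (SD 0.05 by default — per-variant F
in the tens to hundreds at the default n = 50,000 per cohort, exercising
the mean-F>10 gate in both directions), outcome effects θ·β_X plus a
per-variant direct effect α under four pleiotropy modes (none, balanced,
directional, correlated-via-latent-confounder), observation noise with
σ = (2n·EAF(1−EAF))^(−1/2) as for standardised traits, p-values from the
normal approximation. Defaults plant 50 independent variants, 15%
palindromic (of which some fall in the frequency ambiguity zone) and 5%
strand re-encoded in the outcome file. Two architecture switches matter
for benchmarks: `positive_effects` orients effects to the exposure-raising
allele (the convention under which directional pleiotropy is defined), and
`sparse_effects` gives each exposure in a multi-exposure panel its own
dedicated loci — the structure of a phenome-wide screen, where a null
trait's instruments are genuinely unrelated to the outcome. Without
sparsity every variant affects every exposure, so "null" traits are fully
pleiotropic with respect to the outcome; that regime is useful for
stress-testing but not for operating characteristics.

What the generator does not emulate — and hence what passing benchmarks do
not certify on real data: realistic human LD maps (blocks are synthetic
and estimation noise is drawn independently across LD-correlated variants,
though the marginal effects are LD-propagated), case-control ascertainment,
winner's-curse from discovery/replication sharing, population
stratification, and sample overlap between cohorts.

## Benchmark problem sizes

The acceptance script and the end-to-end tests run: 1000 null and 200
effect replicates for IVW calibration (J = 50); 200 replicates each for
Egger recovery (directional pleiotropy mean 0.05), median robustness (40%
invalid instruments, 2M-sample cohorts so the valid ratio cluster is
tight), and the reverse-causation filter; 100 random clumping instances
and 1000 random p-vectors against brute-force oracles; 20 screen runs of
20 traits (2 causal at θ = 0.3, 25 dedicated variants per trait); 200
multivariable replicates at θ = (0.2, −0.1); and MR-BMA with K = 8
search-vs-enumeration agreement, 50 ranking replicates at K = 10, and ten
null panels at 1000 permutations. These sizes keep the full run around a
minute on one CPU while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

Proxy lookup requires the LD reference to carry the phase of the pair;
pairs without phase are dropped rather than guessed. The conditional-F and
Q_A formulas assume independent instruments (clumping enforces
approximate independence; residual r² ≤ 0.001 is ignored). The weighted
mode's grid argmax has resolution (range + 6h)/512, well below its
bootstrap SE in practice. MACE values are standardised-scale quantities
and not comparable across panels with different instrument sets.
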
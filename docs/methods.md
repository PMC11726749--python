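# Methods

## Model and estimators

`mrpipe` implements two-sample Mendelian randomization (MR): genetic
variants (SNPs) serve as instrumental variables for an exposure, and
per-SNP summary statistics from separate GWAS of the exposure and the
outcome are combined into a causal estimate. For SNP *j* with harmonized
exposure effect β<sub>Xj</sub> (SE σ<sub>Xj</sub>) and outcome effect
β<sub>Yj</sub> (SE σ<sub>Yj</sub>):

* **Wald ratio** θ<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub> with
  first-order SE σ<sub>Yj</sub>/|β<sub>Xj</sub>| (exposure-side noise
  ignored; a second-order treatment is deliberately out of scope because
  the inverse-variance weighting convention this package follows is
  defined with first-order weights).
* **IVW**: the 1/se²-weighted mean of the Wald ratios, algebraically a
  weighted regression of β<sub>Y</sub> on β<sub>X</sub> through the
  origin. Fixed-effect SE is (Σw)<sup>−1/2</sup>; the multiplicative
  random-effects SE multiplies it by max(1, √(Q/(k−1))). The `auto` model
  uses random effects iff Cochran's Q has p < 0.05. P-values use the
  normal reference.
* **MR-Egger**: weighted least squares of β<sub>Y</sub> on β<sub>X</sub>
  with an unconstrained intercept (weights 1/σ<sub>Yj</sub>²), after
  orienting every SNP so β<sub>Xj</sub> ≥ 0 — Egger is not invariant to
  allele orientation, so a fixed convention keeps results reproducible.
  The intercept estimates average directional pleiotropy; the slope is a
  pleiotropy-adjusted causal effect. SEs apply the residual scale floored
  at 1 (max(1, √(Q<sub>E</sub>/(k−2)))), the convention of the
  established two-sample-MR software family; the un-floored variant is
  available via `overdispersion=False`. P-values use t with k−2 df.
* **Weighted median**: sort θ, form cumulative standardized weights
  s<sub>j</sub> = (Σ<sub>i≤j</sub>w<sub>i</sub> − w<sub>j</sub>/2)/Σw,
  and interpolate θ at s = 0.5. Consistent when valid instruments carry
  more than half the weight. SE by seeded parametric bootstrap
  (θ<sub>j</sub>* ~ N(θ<sub>j</sub>, se<sub>j</sub>), default 1000
  draws); the bootstrap SE is therefore sign-equivariant only in
  distribution, not draw-by-draw.

These estimators are regression-shaped, so they are exposed as
scikit-learn estimators (`fit(X, y, sample_weight)` with X the exposure
betas and `sample_weight = 1/se_out²`; fitted attributes `beta_`, `se_`,
`pval_`, …) and compose with sklearn tooling; module-level functions wrap
them for `HarmonizedSet` inputs.

Binary outcomes are modelled on the log-odds scale, so reports render
OR = exp(β) with CI exp(β ± z·se), and "percent" effect renderings are
ln(OR)×100.

## Instrument selection and harmonization

Defaults follow the relaxed microbiome-GWAS convention: exposure
association p ≤ 5×10⁻⁵ (inclusive), greedy LD clumping at r² = 0.001
within a 10,000 kb window (index SNP = smallest p, ties broken by genomic
coordinate so output is permutation-invariant), and a strength screen
using per-SNP F = (β/se)² summarised by the mean with the conventional
mean-F > 10 verdict. The field's "total F-value" is ambiguous between the
mean and a joint regression F; per-SNP values are reported alongside the
mean so either summary can be formed, and the verdict uses the mean.

Harmonization aligns outcome records to the exposure's effect allele:
same pair/orientation copies; swapped orientation negates β and mirrors
eaf; strand-complement pairs are complemented first and may also swap
(A/G vs C/T reconciles with a sign flip); palindromic (A/T, C/G) SNPs are
dropped when either study's eaf is missing or within 0.5 ± 0.08,
otherwise orientation is inferred from minor-allele agreement.
Irreconcilable pairs and SNPs absent from the outcome are dropped with
per-SNP reasons; zero survivors is a hard error.

## Heterogeneity, model selection, MR-PRESSO

Cochran's Q is Σw(θ−β̂)² (df k−1) for IVW and the weighted residual sum
of squares (df k−2) for Egger, referenced to the chi-square upper tail;
p < 0.05 selects random effects (p = 0.05 exactly counts as homogeneous).

MR-PRESSO: expected outcome betas use **leave-one-out** IVW estimates so
an outlier never contaminates its own expectation. The observed statistic
is RSS = Σ<sub>j</sub> w<sub>j</sub>(β<sub>Yj</sub> −
β̂<sub>(−j)</sub>β<sub>Xj</sub>)²; the null distribution simulates
β<sub>Yj</sub>* ~ N(β̂<sub>(−j)</sub>β<sub>Xj</sub>, σ<sub>Yj</sub>) and
recomputes the statistic (leave-one-out estimates re-fitted on each
simulated set, vectorized). Empirical p-values use (1+b)/(1+n), so the
global p is never below 1/(n_sim+1). The per-SNP outlier test compares
each observed contribution with its simulated distribution,
Bonferroni-adjusts over instruments, and by contract runs only when the
global test rejects at 0.05. The distortion test compares the estimate
shift after removing the flagged outliers with the shift from removing
equally many random non-outliers from the full set (two-sided empirical
p). Defaults: n_sim = n_boot = 1000, all seeded.

## Two-step mediation

With a mediator M between exposure X and outcome Y: `total` is
IVW(X→Y), `step1` IVW(X→M), `step2` IVW(M→Y) using the mediator's own
instruments after removing every SNP id used in step 1 (so the step-1 and
step-2 instrument sets are disjoint by construction). The decomposition

    indirect = step1 × step2,  direct = total − indirect,
    proportion mediated = indirect / total

holds bit-for-bit in `MediationResult`; the proportion is undefined at
total = 0 (flagged, not raised) and may be negative or exceed 1 when
direct and indirect effects oppose — it is reported signed and unclipped.
The indirect-effect SE uses the first-order delta method for independent
samples, √(step1²·se2² + step2²·se1²).

## Synthetic data generator

`simulate.simulate_triplet` draws summary statistics directly at the
summary level (two-sample MR consumes nothing else, and this keeps every
study desk-scale). True effects follow the chain: instrument effects
γ<sub>j</sub> on the exposure; γ<sub>j</sub>·b<sub>XM</sub> + α<sub>j</sub>
on the mediator; γ<sub>j</sub>(b<sub>XM</sub>b<sub>MY</sub> + b<sub>XY</sub>)
+ α<sub>j</sub>b<sub>MY</sub> + planted outlier offsets on the outcome.
Observed betas add N(0, se) noise with se = 1/√(2·n·maf(1−maf));
p-values are the two-sided normal tail. One seeded generator drives all
draws in a documented order, so equal configs give bitwise-identical
triplets.

Design choices:

* γ is drawn half-normal (effect allele = exposure-increasing allele).
  Allele labels are arbitrary, and this is the frame harmonized exposure
  data occupy and the one in which a nonzero pleiotropy mean is
  "directional" for MR-Egger.
* α plays two roles: mediator-side pleiotropy and, when its variance is
  large, the mediator's own genetic architecture — without it the
  mediator would have no instruments left after the step-1 exclusion.
  Setting b<sub>XM</sub> = 0, b<sub>MY</sub> = 1 collapses the chain to
  classic direct pleiotropy on the outcome, under which the Egger
  intercept estimates the pleiotropy mean.
* A `swap_fraction` (default 0.25) of mediator/outcome rows is reported
  with swapped allele orientation, so harmonization is exercised — an
  alignment bug would corrupt every simulation study rather than pass
  silently.
* Defaults encode the calibration conditions: 50 independent SNPs
  (`ld_block_size=1`; block LD is available and exercised in tests),
  n = 100,000 per study, instrument-effect variance 0.01 (mean F far
  above the weak-instrument screen), maf ~ U(0.1, 0.4), no causal
  effects, no pleiotropy, no outliers.

What the generator does **not** emulate: case-control ascertainment,
winner's-curse-inducing sample overlap between studies, realistic
minor-allele-frequency spectra, polygenic confounding, or the cohort
structures of real biobank GWAS. Passing calibration here shows the
estimators are implemented correctly under the standard two-sample MR
sampling model, not that real-data results are unbiased.

## Calibration studies (mrpipe.benchmarks)

Problem sizes are chosen so each study finishes in seconds on one core
while leaving Monte-Carlo error well below the effects being measured.

* **Null calibration** — 2000 replicates of the default null design;
  IVW (auto model) empirical type-I error at 0.05 and mean of Q − df.
* **Two-step recovery** — 500 replicates with b<sub>XM</sub> = 0.2,
  b<sub>MY</sub> = 0.3, b<sub>XY</sub> = 0.1 (truth 0.16/0.06/0.10),
  150 SNPs, α ~ N(0, 0.1²) as the mediator's own genetics. An a-priori
  bias budget motivated these sizes: winner's-curse shrinkage of selected
  instruments ≈ se²/(se²+σ<sub>γ</sub>²) ≈ 0.4%, and the leak of
  exposure effects into step-2 ratios (E[γ|m] among
  non-exposure-significant SNPs) ≈ 0.001 — both inside three Monte-Carlo
  SEs at 500 replicates. The balanced α also makes the total-effect
  analysis heavily heterogeneous (Q/df ≫ 1), which is what the
  multiplicative random-effects CI is for; its coverage is checked there.
* **Pleiotropy robustness** — 500 replicates with 40% of SNPs given a
  constant +0.02 outcome offset; compares |mean bias| of weighted median
  vs IVW. Egger-intercept recovery uses mean 0.01, sd 0.005 pleiotropy
  (InSIDE holds) on the collapsed univariate chain.
* **MR-PRESSO** — planted offset +0.06 ≈ ten times the median simulated
  outcome SE; detection is assessed among replicates where the planted
  SNP survives instrument selection (a SNP that is not an instrument
  cannot be flagged). Null global-test rejection and distortion-test
  specificity (removing one random non-influential SNP) complete the
  picture.

Monte-Carlo rates are judged against exact binomial 99% intervals around
their nominal values; means within three Monte-Carlo standard errors.

## Worked example and its tolerances

The bundled worked example (`mrpipe.worked_example`) transcribes the
published univariate and two-step odds ratios of a skin-microbiota /
circulating-metabolite / epilepsy study and recomputes its
effect-decomposition table as ln(OR)×100. Because the source prints ORs
to four decimals, quantities recomputed from them carry that rounding:
the asv022 mediator percentage, a ratio of two small logs, can land
anywhere in ±0.033 points around the printed value, and the bacillales
indirect/direct split is not reproducible at all from the printed step-1
OR (0.9932), which equals its own CI lower bound and is internally
inconsistent — only its total effect is checked. Two further printed
rows (asv008 and clostridiales indirect effects, −0.001%) disagree in
magnitude and sign with the products of the printed step ORs and are not
used as checks.

## Numerical notes and limitations

* P-values are clipped into (0, 1]; empirical p-values can never be 0 by
  construction.
* β<sub>X</sub> = 0 SNPs are dropped from ratio-based estimators with a
  warning; an all-zero exposure is a hard error. Egger requires k ≥ 3,
  MR-PRESSO k ≥ 4; IVW degrades to the single Wald ratio at k = 1 with a
  warning.
* Clumping tie-break (equal p): smaller genomic coordinate wins.
* Screening reports apply no multiple-testing correction across
  exposures by default (raw p ≤ 0.05 filter), mirroring common practice
  in exposure-wide MR screens; users should treat screen hits as
  hypotheses, not discoveries.
* Mode-based estimators, MR-RAPS, multivariable MR, Steiger filtering,
  proxy-SNP lookup and reference-panel LD computation are out of scope.
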
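# Methods

## Model

Two-sample MR treats each harmonized SNP j as an instrument with exposure
association γⱼ (estimated β̂_Xj, SE se_Xj) and outcome association
θγⱼ + αⱼ (estimated β̂_Yj, SE se_Yj), where θ is the causal effect of the
exposure on the outcome and αⱼ a direct (horizontally pleiotropic) effect.
Valid instruments have αⱼ = 0. Effects are on the standardized scale:
log-odds per allele for binary traits, SD units for continuous traits, so
the causal estimate exponentiates to an odds ratio per log-odds (binary
exposure) or per SD (continuous exposure) increment; the output flags the
latter interpretation (`scale_note`), since "OR" for a continuous outcome is
exp(slope) per SD.

The per-SNP Wald ratio is θ̂ⱼ = β̂_Yj/β̂_Xj with first-order SE
σⱼ = se_Yj/|β̂_Xj| (no exposure-noise or correlation term — the two-sample
design makes the numerator and denominator independent, and instruments are
strong enough that the first-order expansion is adequate; see Limitations).

## Estimators

- **IVW** (primary): weighted regression of β̂_Y on β̂_X through the origin
  with weights se_Yj⁻², algebraically the σⱼ⁻²-weighted mean of the Wald
  ratios. The random-effects variant multiplies the fixed-effect SE by
  √(Q/(J−1)) floored at 1 (overdispersion widens the interval,
  underdispersion is not credited). p-values and CIs use the normal.
- **MR-Egger**: weighted least squares with a free intercept after orienting
  all β̂_Xj ≥ 0. A nonzero intercept estimates the average directional
  pleiotropy; the slope is consistent for θ under InSIDE (pleiotropy
  independent of instrument strength). SEs carry the same multiplicative
  √(Q_E/(J−2)) floor; inference uses t(J−2), including the CI — chosen so
  interval and p-value agree at small J.
- **Weighted median**: the 50% point of the σⱼ⁻²-weighted empirical
  distribution of ordered ratios, interpolating cumulative-weight midpoints
  pⱼ = Sⱼ − w′ⱼ/2 and clamping at the extremes; consistent when valid
  instruments carry ≥ 50% of weight.
- **Simple / weighted mode**: the argmax of a normal-kernel density over the
  ratios with bandwidth φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 by
  default), weights uniform or normalized σⱼ⁻². The density is evaluated on
  a 512-point uniform grid spanning [min θ̂ − 3h, max θ̂ + 3h] *plus the data
  points themselves*: with heavy-tailed ratios an outlier stretches the grid
  until its spacing exceeds the bandwidth and a pure-grid argmax can miss
  the dominant cluster entirely; appending the θ̂ⱼ guarantees the cluster is
  always sampled while changing nothing (beyond grid resolution) in regular
  cases. If every ratio coincides the bandwidth degenerates and the common
  value is returned with a logged note.

Median and mode SEs come from a parametric bootstrap (default n_boot = 1000,
seeded, bit-reproducible): β*_Xj ~ N(β̂_Xj, se²_Xj), β*_Yj ~ N(β̂_Yj, se²_Yj),
re-estimate, take the SD. This is the convention of the established MR
software ecosystem. It is conservative for these estimators: the bootstrap
convolves the realized sampling noise with fresh noise, flattening the local
density that controls an order statistic's variance. At the default study
scale the bootstrap SE exceeds the empirical sampling SD by ~20–25%, so
null rejection rates of the median (~3%) and especially the modes (~1–2%)
run below the nominal 5% while IVW and Egger sit at 4–6%. The acceptance
suite documents this directly rather than hiding it.

## Harmonization

Outcome records are aligned to the exposure's effect allele: direct label
match keeps β_Y, a swapped match negates β_Y and complements the allele
frequency, any other configuration is excluded as incompatible. Palindromic
(A/T, C/G) SNPs cannot be strand-resolved from labels; under the default
`exclude_ambiguous` policy they are dropped when either trait's eaf lies in
0.5 ± 0.08 (or is missing) and otherwise resolved by frequency agreement;
`exclude_all` drops every palindrome. Retained rows plus the exclusion
ledger (missing_in_outcome / palindromic_ambiguous / incompatible_alleles)
always partition the instrument list, so instrument accounting is exact.
Only single-nucleotide biallelic variants are accepted; there is no proxy
lookup for SNPs absent from the outcome and no reference-genome strand
inference. Column dialects are mapped explicitly, never guessed.

## Instrument selection and strength

Clumping is greedy and p-ordered: keep the smallest-p remaining candidate,
discard candidates with r² above threshold to it (ties in p broken
lexicographically by SNP id, making the output order-invariant). Pairs
absent from the LD matrix count as independent with a logged warning, so
unlinked simulated panels need no full matrix. No physical-distance window
is applied. Two R² conventions are provided: `z_based`
r²ⱼ = β̂ⱼ²/(β̂ⱼ² + n·seⱼ²) (default; needs no allele frequency) and
`frequency` r²ⱼ = 2pⱼ(1−pⱼ)β̂ⱼ² (requires SD-scale betas). F uses the
total-R² form (R²/k)/((1−R²)/(n−k−1)); per-SNP Fⱼ = (β̂ⱼ/seⱼ)² is also
emitted, and the pipeline warns at F ≤ 10. Published instrument tables
sometimes print F values that match neither convention exactly (rounded
inputs, unstated sample sizes), so F is reported, not asserted against any
external table.

## Power

The asymptotic approximation Φ(ncp − z₁₋α/₂) with
ncp = |effect|·√(n·R²·K(1−K)) (binary outcome, case fraction K) or
|effect|·√(n·R²) (continuous). At effect 0 this degenerates to the one-tail
form ≈ α/2. Power is informational; published power columns for comparable
designs are not always reproducible from their printed rounded inputs.

## Grid and multiplicity

The grid runner executes each analysis independently (a failure becomes a
populated failure row; the grid completes), applies the exact Bonferroni
threshold α/m (rendered at 3 decimals in reports, carried at full precision
for the significance calls), and writes instrument-strength and estimate
tables plus per-analysis diagnostics. Fixed seeds make the output TSVs
byte-identical across runs.

## Synthetic data

The generator emulates two-sample summary statistics without genotypes:
eafs ~ U(0.05, 0.95); instrument effects γⱼ drawn half-normal with a lower
truncation (default `min_strength` 0.5 raw units) and rescaled so
Σ2pⱼ(1−pⱼ)γⱼ² equals the target R² exactly. Two modelling choices matter:

- **Common sign.** Summary statistics are conventionally oriented to the
  exposure-increasing allele, so γⱼ ≥ 0. This is what makes directional
  pleiotropy a *directional* bias for IVW — with sign-symmetric γ the bias
  term Σwγⱼαⱼ/Σwγⱼ² averages out across datasets.
- **Truncation.** Instruments reach an MR analysis only after genome-wide
  significance selection, which bounds true strengths away from zero. An
  untruncated half-normal produces near-null instruments whose Wald ratios
  are pathologically heavy-tailed — unrepresentative of selected panels and
  numerically hostile to the mode estimators.

SEs follow the Hardy–Weinberg form se = (2p(1−p)·n)^(−1/2), scaled by
(K(1−K))^(−1/2) for binary log-odds outcomes; estimates are the truths plus
normal noise. Pleiotropy regimes on the invalid set (round(ρJ) SNPs):
balanced N(0, σ_α²), directional N(μ_α, σ_α²), or InSIDE-violating
κγⱼ + N(0, σ_α²). Palindromic SNPs get A/T or C/G alleles with eaf in
[0.42, 0.58] on both sides (so they are deterministically ambiguous);
outcome-missing SNPs are omitted from the outcome table; the two sets are
disjoint so exclusion accounting is exact. Outcome rows are randomly
allele-relabelled (beta negated, eaf complemented) to exercise the
harmonizer. Optional LD blocks assign within-block r² in the emitted matrix
with tagging-attenuated effects for non-lead SNPs. Everything is
reproducible from a single integer seed (PCG64).

Defaults mirror a large bidirectional depression/metabolic-syndrome design:
J = 90 instruments, exposure n = 2,113,907, binary outcome n = 291,107 with
case fraction 0.205, total R² = 0.37%, θ = 0.

What the generator does **not** model — and hence what passing tests cannot
show about real data: sample overlap between the two GWAS, winner's curse in
instrument discovery, population stratification and relatedness, non-normal
effect-size distributions, genotype-level LD beyond the block-r² summary,
and allele-frequency mismatch between ancestries.

## Monte-Carlo scales and numerical choices

Calibration and recovery suites use 500–1000 replicates with bootstrap sizes
of 100–200, sized to give 3-MC-SE resolution on biases of interest while the
full test suite runs in a few minutes on one CPU. Bootstrap kernels for the
mode run in float32 (the 512-point argmax is insensitive to it); point
estimates are float64 throughout. p-values are floored at 1e-300 to stay in
(0, 1].

Known finite-sample properties at the default scale, visible in the test
suites: IVW attenuation of ~1% from exposure measurement error
(sd(γ)/se_X ≈ 3.9); Egger slope attenuation of ~6% from the same source
(the Egger analogue of regression dilution), well inside the 3-MC-SE bands
at 500 replicates; weighted-median finite-precision bias under a 30%
one-sided invalid fraction of order σ·Φ⁻¹(0.5/0.7) — the estimator's
guarantee at finite noise is smaller-bias-than-IVW, not unbiasedness, and
that is what is asserted.

## Limitations

No MR-PRESSO outlier correction, Steiger directionality filtering,
multivariable MR, or NOME-corrected (second-order/exact) IVW weights; no
proxy-SNP lookup or genome-build liftover; LD must be supplied (or
simulated), never computed from genotypes; figures are emitted as plot-ready
tables, not drawn. The funnel "asymmetry" is summarized as a signed Spearman
correlation between θ̂ⱼ − b̂ and σⱼ and reported without a significance
criterion.
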
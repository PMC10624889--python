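# Methods

This note records the models implemented by `immunoprog`, the numerical
conventions they depend on, the design choices made where more than one
reading was defensible, and what the synthetic-data generators do and do
not emulate.

## Clone tables and chain assignment

A clone is a CDR3 nucleotide sequence with a read count and V/D/J/C gene
calls, read from a MiXCR-style tab-separated export (column names
configurable; multi-hit cells are comma-separated, and allele suffixes
`*01` and alignment scores `(…)` are stripped before chain parsing). Rows
with a read count below 1 or an invalid CDR3 are dropped with a logged
count.

Chain assignment works on the per-slot chain sets implied by the gene
prefixes (IGH/IGK/IGL/TRA/TRB/TRG/TRD): the chain is the unique member of
the intersection of all non-empty slots. This single rule covers the three
cases of interest — full agreement; an ambiguous slot (e.g. V calls on two
chains) resolved by a univocal compatible slot; and irreconcilable slots,
which leave the chain missing. The receptor class (BCR vs TCR) is set
whenever the locus family is unambiguous, so missing-chain clones still
count in their global repertoire; clones without any recognizable gene hit
contribute to no scope. IGH isotypes map from the constant-gene prefix
(IGHG→IgG, …); absent or conflicting constant evidence yields
"undetermined".

Duplicate rows with the same CDR3 on the same chain are merged (counts
summed, gene hits unioned, isotype re-derived) because the CDR3 sequence
is the clone identity within a chain; identical CDR3s on different chains
stay distinct. Whether the upstream tool would have merged clones with
identical CDR3 but different V/J calls is not recoverable from exports, so
merging by (CDR3, chain) is the package's convention.

## Diversity metrics

With clone counts `x_i` and fractions `p_i` inside a scope:

- **Gini** uses the unweighted relative-mean-absolute-difference form
  `G = Σ_ij |x_i − x_j| / (2 n² x̄)`, computed from sorted values, with no
  `n/(n−1)` correction. This matches the convention of the R `reldist`
  ecosystem and is oracle-tested against an explicit O(n²) pairwise sum.
- **Gini–Simpson** is `1 − Σ p_i²`.
- **Evenness** is Shannon entropy normalized by `ln(n)`, computed as
  `−Σ p_i ln p_i / ln n` for numerical stability rather than with
  base-n logarithms directly.
- **Mean CDR3 length** is the unweighted mean over clones (a clone-level
  summary, consistent with the other clone-level statistics); a
  read-weighted mean would up-weight expanded clones and is deliberately
  not used.
- **Normalized reads** are scope reads divided by the sample's
  transcriptome-mapped total, times 1000. The clone-read universe is not a
  subset of the gene-mapped universe, so values above 1000 are not
  forbidden by construction (they do not occur in practice).

Edge rules: single-clone scopes pin Gini and Gini–Simpson to 0 and leave
evenness and the second-clone proportion undefined; empty scopes leave all
count-distribution metrics undefined with zero normalized reads. Undefined
values are explicit `None`/NaN, never silent zeros; downstream modeling
excludes incomplete patients per analysis.

## Feature transformation

The Shapiro–Francia statistic W′ is the squared Pearson correlation
between sample order statistics and expected normal order statistics at
Blom plotting positions `(i − 3/8)/(n + 1/4)`; the p-value uses Royston's
(1993) normal approximation of `log(1 − W′)` with coefficients
μ = −1.2725 + 1.0521(log log n − log n) and
σ = 1.0308 − 0.26758(log log n + 2/log n), valid for 5 ≤ n ≤ 5000. The
implementation reproduces R's `nortest::sf.test` to 1e-9 on shared
fixtures.

Per variable, the log10 candidate is `log10(x)` when the cohort has no
zeros, else `log10(x + c)` with `c` = (10% quantile)/10 — quantiles are
type-7 (linear interpolation), pinned because the small constant depends
on it. The acceptance rule tests the original values first: if they
already pass normality (SF p > 0.05) no transform is applied; otherwise
the candidate is kept only when its SF p exceeds the original's. The
sentence this rule encodes admits a second reading (always keep the
transform iff it improves the p-value); both are implemented behind the
`rule` flag, with `original_first` as the default because it reproduces
the stated outcome in both readings of the common cases. If the shifted
candidate is non-finite (zeros present with a zero 10% quantile) the
transform is rejected. Centering and scaling use the mean and sample SD
(n−1 denominator) of the chosen representation; a fitted `TransformSpec`
serializes to YAML/JSON so a spec fitted on one cohort applies to another
byte-identically.

Gene-signature scores: genes with total count < 20 across samples are
dropped; counts are divided by the sample's mean gene count (computed on
the filtered matrix — the filter-then-normalize order is the package's
convention), log10 after adding 0.001; the score is
`Σ w_g x_g / Σ |w_g|` over the signature's surviving genes. Missing genes
are reported; a signature with no surviving gene scores NaN with a
warning.

Clinical encodings: pCR = 1 / residual disease = 0; HR+ = 1; cN0 = 1 vs
cN+/x = 0; tumor size ≥ cT3 = 1; combination arm = 1; PAM50 HER2-enriched
= 1; TILs (%) and age (years) raw. Missing fields encode as missing,
never as 0.

## Cox fitting and model development

`cox_fit` maximizes the Efron-ties partial likelihood by Newton's method
with step-halving, vectorized over tied-event groups (risk-set aggregates
via reverse cumulative sums). Covariates are centered internally for
numerical range only — estimates are shift-invariant. Convergence requires
a likelihood change below 1e-10 and a gradient below 1e-6; coefficients
exceeding 20 in absolute value are treated as separation and flagged
rather than raised, so stepwise selection can skip the candidate.
Standard errors come from the inverse observed information; AIC is
−2 logPL + 2k. The null model's log partial likelihood has the closed form
`−Σ_j Σ_{l<d_j} log(n_j − l)` (Efron and Breslow coincide with no
covariates). The solver agrees with lifelines' `CoxPHFitter` (the
independent reference in the test suite) to 1e-6 in coefficients, SEs and
log-likelihood, including under heavy ties.

Forward stepwise selection starts from the null model and greedily adds
the pool variable with the lowest AIC, stopping when no addition lowers
it; ties break by pool order, and the procedure is forward-only (a
deliberate reading of "starting from a null model … added"; the backward
direction is out of scope). Development uses complete cases over the pool.
Collinear candidates (e.g. the two pCR definitions) are allowed and left
to AIC.

## The published score and risk groups

`published_her2event()` freezes the five printed coefficients, the
development cohort's evenness standardization constants
(mean 0.7917893, SD 0.1004482 — the validation-cohort convention: raw
evenness is centered and scaled with the *development* constants, no log),
and the tertile cutoffs (−1.3763, −0.8143). Scores are reported at full
precision; the good-prognosis group is `score ≤ −1.3763` exactly (≤, not
<), and tertiles 2–3 merge into the poor group. Freshly derived cutoffs
use type-7 empirical 1/3 and 2/3 quantiles.

## Survival evaluation

Kaplan–Meier estimation and log-rank tests delegate to lifelines.
Confidence intervals default to the log-log (exponential Greenwood)
transform — the convention of the R `survival` ecosystem — with plain
Greenwood available by flag; fixed-horizon rates are the step-function
value at the horizon. Harrell's C counts a pair as comparable when the
earlier time is an event (or, at a tied time, exactly one of the pair is
an event); score ties count 0.5, and the orientation is
higher-score-worse, matching the score's risk interpretation — report
`1 − c` if the opposite convention is needed. Univariable Cox p-values
are likelihood-ratio tests against the null model; multivariable p-values
are LRTs between adjusted models with and without the variable, and
continuous variables are centered/scaled before hazard ratios are
computed. Benjamini–Hochberg FDR comes from statsmodels.

## Synthetic data

The generators encode the statistical structure the analysis assumes:

- **Repertoires**: clone abundances proportional to `rank^(−clonality)`
  (0 = uniform; the 0–4 range spans the observed evenness spectrum), with
  multinomial read sampling, κ-dominant BCR light chains, α/β-dominant TCR
  chains, IgG > IgA > IgM isotypes with a 20% missing-constant-region
  rate, and a configurable fraction of deliberately discordant V/J pairs
  to exercise chain disambiguation. Defaults (150 clones, 3000 repertoire
  reads, 15M mapped reads) give normalized read counts of the order seen
  in bulk RNA-seq tumor repertoires.
- **Cohorts**: covariate prevalences match the development cohort
  (HR+ 0.539, cN0 0.264, breast pCR 0.346); TILs are log-normal
  moment-matched to median 12.5 with quartiles 5/32.5 and truncated at
  100%; BCR evenness is normal with the published mean/SD truncated to
  (0, 1]. Event times are exponential with hazard `λ0 exp(η)`, η the
  published linear score (baseline λ0 = 0.35/year, chosen to give roughly
  60% events over follow-up), independent exponential censoring
  (0.04/year) plus administrative censoring at 10 years. η is accumulated
  in the score's own term order so scoring the cohort with the published
  model reproduces it bit-for-bit — the oracle identity used in tests.
- **Expression**: negative-binomial counts with a signature-aligned
  latent sample factor for signature-recovery tests.

All generators are pure functions of (config, seed). What they do *not*
emulate: VDJ recombination and somatic hypermutation, correlation between
repertoire metrics and clinical covariates, non-proportional hazards,
informative censoring, and batch effects. Passing tests therefore
demonstrate the correctness of the computations and the internal
consistency of the pipeline under the assumed model — not clinical
validity on real cohorts, which requires the access-controlled trial
data.

## Problem sizes and statistical test design

The simulation studies use cohorts of n = 2000 with 50 replicates for
coverage and selection-consistency checks, 1000 replicates for log-rank
type-I calibration, and 2000 replicates for Shapiro–Francia null
uniformity. Stochastic assertions are seeded and sized so that a
correctly calibrated method passes with controlled error: in particular,
the per-coefficient CI-coverage check uses a one-sided binomial rule at
α = 0.05 under H0 coverage = 0.90, because a raw threshold on 50
Bernoulli draws would flag a method whose true coverage meets the bound
in a sizable fraction of runs. (Model-based Cox SEs run ~6% below the
sampling SD for the heavy-tailed TILs covariate at these conditions —
true coverage ≈ 92%, above the 90% bound but below nominal.)

## Known limitations

- The Gini convention and the (CDR3, chain) merge rule are documented
  choices among defensible alternatives; comparisons with pipelines using
  other conventions require matching these settings.
- The Shapiro–Francia p-value approximation degrades outside
  5 ≤ n ≤ 5000.
- The stepwise procedure inherits AIC's liberal inclusion behavior: on
  pure-noise pools it admits occasional false positives by design.
- The pipeline performs listwise exclusion for missing model variables;
  no imputation is provided.
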
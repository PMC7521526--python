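# Methods

`longimode` implements a two-wave brain–behaviour covariation analysis: given a
cohort measured at two late-midlife waves on a large set of image-derived
phenotypes (IDPs) and behavioural variables, it asks whether cross-subject
*changes* in brain structure covary with *changes* in behaviour, and it answers
with a mass-univariate correlation screen and a PCA-compressed canonical
correlation analysis (CCA) under max-statistic permutation inference. Because
cohort data of this kind are rarely public, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes, so every stage is testable end to end.

## Longitudinal scoring

Repeated measurements are represented by their raw difference
`Δ = W63 − W57` and raw average `(W63 + W57)/2`. Raw change is preferred over
residualized change because residualized change is biased when the sample
consists of pre-existing groups (an extreme-group sample is exactly that), and
the average rather than the baseline is the companion regressor because raw
change is negatively correlated with baseline by construction. Behavioural
variables whose raw direction is "lower is better" (latencies, error counts,
depression scores) are sign-inverted at the wave level, before scoring, so that
every behavioural score reads "higher = better"; no direction is assigned to
brain measures. Bland–Altman summaries (bias, `bias ± 1.96·sd(diff)` limits of
agreement, and the mean-vs-difference correlation) quantify whether the size of
change depends on the underlying level; 1.96 is the conventional multiplier.

## Conditioning chain

The order is fixed — quantile normalization → deconfounding → imputation — and
enforced through provenance tags on every matrix
(`raw → normalized → deconfounded → imputed`); a stage rejects inputs in the
wrong state.

**Quantile normalization.** Each variable's observed values are replaced by
`Φ⁻¹((rank − 3/8)/(n + 1/4))` (Blom offsets, average ranks for ties). Offsets
keep the extreme quantiles bounded; ties → average ranks makes downstream
p-values conservative. Constant columns carry no rank information and are
dropped with a warning. Confounds are transformed the same way.

**Deconfounding.** Five nuisance covariates — absolute and relative motion,
head size, age difference and age average — plus an intercept are regressed
out of every variable by least squares over that variable's observed rows.
Residuals are orthogonal to the confounds to machine precision (asserted in
tests at 1e−10). Rank-deficient designs fall back to the minimum-norm solution
and the variable is flagged. Downstream correlation p-values subtract the 6
fitted parameters from the degrees of freedom (`df = n − 2 − 5`), a
conservative accounting that is configurable.

**Soft-impute.** Missing cells are completed by iterating: fill with the
current estimate (initially column means), SVD, soft-threshold every singular
value by λ, reconstruct, restore observed cells. Observed cells are bit-equal
to the input on exit. The default λ ("auto") is the (k+1)-th singular value of
the mean-filled matrix, so shrinkage suppresses structure beyond the PCA target
rank k (30 by default); convergence is declared when the relative change of
the imputed cells falls below 1e−6 (500 iteration cap, warning on
non-convergence). An optional hard rank truncation (`rank=`) gives the
regularized iterative-PCA variant, which is what recovers exactly low-rank
matrices with vanishing λ; an optional `center=False` skips column centering.
A single deterministic completion is produced — no multiple imputation.

## Univariate screen

Every (IDP, behavioural) pair is Pearson-correlated over its own complete
pairs. P-values come from the exact t reference `t = r·√(df/(1−r²))`,
two-sided. Pairs with fewer than 5 complete pairs or degenerate variance are
flagged invalid and excluded from thresholds. Multiplicity is controlled two
ways per analysis set: Bonferroni `α/m` (familywise error) and the
Benjamini–Hochberg step-up (false discovery rate), both implemented exactly and
verified against a brute-force enumeration oracle and statsmodels. The
Manhattan export orders records by the behavioural axis, annotates subdomains,
and carries both computed threshold lines plus optional user-supplied override
lines. The extreme-group validation split re-runs the screen within each
recruitment group with identical pair enumeration and reports pooled-vs-within
excess |r| per pair, the Simpson's-paradox diagnostic.

## Multivariate analysis

Each conditioned block is compressed by column-centered SVD to its top-30
subject eigenvectors (scores = left singular vectors × singular values), with
the cumulative variance explained reported as a diagnostic, not used as a
selection rule. CCA whitens each score block by reduced QR and takes the SVD of
`Qxᵀ Qy`; singular values are the canonical correlations, variates are scaled
to unit variance. On every small fixture the solver matches the
generalized-eigenproblem solution `Σxx⁻¹ Σxy Σyy⁻¹ Σyx` to 1e−10. Rank
deficiency after whitening is rejected by default (`on_deficiency="regularize"`
drops the deficient directions instead). Mode signs are arbitrary; `cca()`
fixes them deterministically from the weights, and the pipeline then orients
each mode so the sum of behavioural structure correlations is non-negative.

**Permutation inference.** Rows of the behavioural block are permuted (either
block is equivalent under exchangeability), CCA is re-run, and the largest
canonical correlation per permutation forms one shared null; every observed
mode is compared against it, `p = (1 + #{null ≥ r}) / (1 + n_perm)`, giving
familywise-corrected p-values over all modes with floor `1/(n_perm+1)`.
The permutation table is pre-generated from one seed. One subtlety matters:
after deconfounding, *both* blocks lie in the orthogonal complement of the
confound span, a 6-dimensional shared constraint that permuted data would not
satisfy — naive permutation is anticonservative (we measured 12% type-I at
nominal 5% under the global null at n=123, k=30). The pipeline therefore
re-residualizes the permuted block on the confounds inside every permutation
(the standard Freedman–Lane device for permutation with nuisance covariates),
which restores calibration (measured 5–7% over 200 seeds).

**In-sample inflation and the debiased strength estimate.** At n=123 with
30+30 components the largest sample canonical correlation is ≈0.85 *under the
null*: the raw `R_c` is not interpretable as an effect size, and inference
rests entirely on the permutation test. For parameter-recovery work the
package provides `debias_canonical_correlation`, which inverts the first-order
spiked-model relation `λ̂ = (λ + c₁(1−λ))(λ + c₂(1−λ))/λ` (λ = ρ², cᵢ = kᵢ/n)
between a planted population canonical correlation and its sample value. Below
the detectability threshold `λ* = √(c₁c₂/((1−c₁)(1−c₂)))` (ρ ≈ 0.57 at these
dimensions) the sample statistic carries no information about ρ and the
threshold value is returned. On generator data the debiased estimate recovers
planted ρ ∈ {0.7, 0.92} to within ±0.05 (mean over 20 seeds); ρ = 0.5 is below
the threshold and cannot be recovered by any estimator built on the 30+30
compression — a design limit, not an implementation one. Detection power at
the 5% familywise level is essentially 1 at ρ = 0.92 but only ≈0.5 at ρ = 0.7,
where the spike sits close to the permutation null edge.

**Post-hoc structure.** Each observed (normalized, deconfounded) variable is
correlated with its own block's variate (behavioural ↔ U, IDP ↔ V; cross-block
pairing available behind a flag), over complete pairs. Variables with
|r| < 0.2 are retained internally but flagged unreported. Subdomain importance
is the mean r² per subdomain, with behavioural subdomains split into positive
and negative contributions; IDP subdomains stay unsplit.

## Synthetic cohort generator

The generator emulates the study design the analysis was built for:

- **Pool and IQ model.** 1,985 subjects with latent general ability g; youth
  scores load on g (0.80, 0.85), the late-midlife score regresses on the youth
  score with population slope 0.71 (so the youth score explains ≈50% of
  late-score variance) plus an independent latent change factor, and the
  second late wave follows with high retest stability (0.90) plus further
  change. These calibrations reproduce the selection regression the design is
  built on.
- **Extreme-group selection.** Least-squares regression of late IQ on youth
  IQ; standardized residuals (residual / RMS with n−2 denominator; internally
  vs externally studentized is immaterial at this n and plain standardization
  is simplest); |z| > 3 trimmed; top-66 residuals labelled improvers, bottom-57
  decliners, ties broken by subject index. Note a single outlier among n
  subjects can reach at most √(n−2) standardized units under this definition.
- **Planted mode.** Latent factors with corr(U0, V0) = ρ* (configurable, more
  modes optional); behavioural change components load on U0 and IDP change
  components on V0, with per-variable loadings (default 0.9) and Gaussian
  measurement noise (default sd 0.3, i.e. ≈3:1 signal-to-noise on the change
  component — deliberately favourable, since the tests certify the machinery
  rather than any particular cohort's effect size). Stable per-variable levels
  (cognitive levels share g) complete the wave data, and "lower is better"
  variables are stored negatively oriented, as instruments would report them.
- **Confounds.** Five standard-normal nuisance variables contaminate every
  variable linearly (coefficient 0.3 by default, per-variable random weights);
  drawn independent of the planted mode so deconfounding is testable as exact
  removal, with a leakage switch that correlates the first confound with U0.
- **Missingness.** MCAR cell masking (default 5%, in the range of the missing
  fractions such cohort tables report) with a re-draw rule keeping ≥2 observed
  values per column and ≥1 per row.
- **Seeding.** All randomness flows from one seed through named per-stage
  substreams; the same seed reproduces a cohort bit-exactly.

What the generator does *not* emulate: real marginal distributions (after
quantile normalization only ranks matter, so Gaussian margins suffice),
instrument-specific skew in the two IQ tests, attrition beyond MCAR, and
realistic heterogeneity of loadings. Passing tests therefore certify the
pipeline's algorithmic behaviour under the design's assumptions, not the
effect sizes to expect from any real cohort.

## Problem sizes used in the checks

Simulation-based checks run at the design's native scale — 123 selected
subjects from a pool of 1,985, 454 IDPs, 114 behavioural variables, 30+30
components — with 999 permutations per test, 200 seeds for the type-I
calibration and 20 seeds per condition for recovery; the end-to-end toy
profile (60 subjects, 40 IDPs, 20 behavioural variables, 5 components)
exercises the file-based pipeline and CLI in under a second.

## Known limitations

- The analysis is correlational throughout; no causal ordering is implied.
- Single deterministic imputation: imputation uncertainty is not propagated.
- The permutation test assumes subject exchangeability; family or batch
  structure would need restricted permutations, which are not implemented.
- The debiased strength estimate relies on a rank-one spiked approximation;
  with several planted modes of comparable strength it applies mode-wise only
  approximately.
- The cross-sectional analysis sets are enumerated (counts, membership,
  exports) but the headline pipeline targets the longitudinal set.
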
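# longimode

Two-wave brain–behaviour covariation analysis, with a synthetic cohort
generator for testing every stage end to end.

## The problem

Longitudinal ageing studies measure a cohort twice in late midlife on hundreds
of image-derived phenotypes (IDPs — regional grey-matter volumes, white-matter
hyperintensity load, tract diffusivity, …) and on a wide battery of cognitive,
demographic, health and lifestyle variables. The scientific question is whether
cross-subject *changes* in brain structure covary with *changes* in behaviour —
and through which variables. `longimode` implements the full analysis chain for
that question, for statisticians and imaging researchers who have (or simulate)
such two-wave tabular data:

1. **Scoring** — every repeated measurement becomes a raw change score
   `Δ = W63 − W57` and a raw average `(W63 + W57)/2`; "lower is better"
   behavioural variables are sign-inverted first.
2. **Conditioning** — rank-based inverse normal transformation
   `Φ⁻¹((rank − 3/8)/(n + 1/4))`, least-squares removal of five nuisance
   covariates (motion ×2, head size, age difference, age average), and
   soft-shrinkage iterative-PCA imputation of missing cells.
3. **Univariate screen** — Pearson correlation of every IDP with every
   behavioural variable over complete pairs, with Bonferroni (FWE) and
   Benjamini–Hochberg (FDR) control and a Manhattan-plot export, plus an
   extreme-group validation split that exposes Simpson's-paradox artefacts.
4. **Multivariate core** — each block is PCA-compressed to 30 subject
   eigenvectors and CCA extracts paired variates `U = X a`, `V = Y b`
   maximizing `corr(U, V)`; each observed canonical correlation `R_c` is
   compared to the permutation null distribution of the *largest* canonical
   correlation (rows of one block permuted, with re-residualization on the
   confounds inside each permutation), giving familywise-corrected p-values
   over all modes. Post-hoc structure correlations and per-subdomain mean r²
   map a significant mode back onto the observed variables.

A key statistical point the package makes explicit: at ~120 subjects and 30+30
components the largest *in-sample* canonical correlation is ≈0.85 even for
independent blocks. The permutation p-value carries the inference, and a
debiased strength estimate (inverting the spiked-model relation between
population and sample canonical correlations) is provided for effect-size
reading.

Because cohorts like this are rarely public, the `simulate` module generates
two-wave cohorts with the design's structure: a recruitment pool with youth and
late-midlife IQ, extreme-group selection on the standardized residual of late
IQ regressed on youth IQ (66 "improvers" + 57 "decliners" = 123 of 1,985), a
planted cross-block covariation mode of configurable strength ρ*, confound
contamination, and MCAR missingness — with ground truth retained for
validation.

## Worked example

```python
from longimode import CohortConfig, generate_cohort
from longimode.pipeline import RunConfig, analyze_cohort

cohort = generate_cohort(CohortConfig(rho_star=0.92, seed=7))
res = analyze_cohort(cohort, RunConfig(), n_perm=999, seed=7)
```

Running `python examples/05_cca_permutation.py` (which does the above and
prints the mode summary) gives:

```
mode 1 canonical correlation : 0.949
mode 1 debiased strength     : 0.896 (planted 0.92)
mode 1 p_fwe                 : 0.001 (999 permutations)
null max correlation (mean)  : 0.850 <- in-sample inflation under the null
mode 2 p_fwe                 : 0.947 (no second planted mode)
```

Read: the raw mode-1 correlation (0.949) is inflated — the null itself averages
0.850 — but the permutation test pins the planted mode at the smallest
attainable p (0.001 with 999 permutations), the debiased estimate recovers the
planted strength 0.92 to within sampling error, and the second, unplanted mode
is correctly non-significant. The same script then lists the behavioural
variables most correlated with the mode (|r| ≥ 0.2 reporting filter) and the
mean r² importance of each of the six IDP subdomains.

The other examples cover cohort generation (`01`), longitudinal scoring and
Bland–Altman agreement (`02`), the conditioning chain (`03`), and the
univariate screen with multiplicity control and the extreme-group split
(`04`). The same pipeline runs from the shell on TSV files:

```bash
longimode run --profile toy --seed 0 --out run/
longimode simulate --seed 0 --out sim/   # stage by stage: simulate, scores,
                                         # preprocess, screen, cca
```

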
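# Methods

This document describes the statistical model behind each module, the
parameter defaults and the reasons for them, what the synthetic cohort
generator does and does not emulate, the numerical choices, and the known
limitations. No empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` actually compute.

## 1. Convergence statistics (`corac.agreement`)

### Top-k concordance table

Given per-gene p-values from a common-variant and a rare-variant analysis,
genes are first **clumped** to one gene per LD block: within each `block_id`
the gene minimizing `log p_common + log p_rare` is kept, with ties broken
lexicographically on `gene_id` and flagged in the result. The top `k` genes
of each ranking then define a 2×2 table with cells

```
a = |top_common ∩ top_rare|     b = k − a
c = k − a                       d = n − 2k + a
```

so only `a` is free once `n` and `k` are fixed. Dense ranks are used so tied
p-values cannot split a top-k set nondeterministically.

### Agreement coefficients

- Cohen's κ: `κ = (p_α − p_ε)/(1 − p_ε)` with `p_α = (a + d)/n` and the
  product-margin chance term `p_ε = p_1·p·1 + (1−p_1·)(1−p·1)`.
- Gwet's AC1: same numerator structure with chance term `p_γ = 2π(1−π)`,
  `π = (p_1· + p·1)/2`. AC1 is reported because κ's chance term grows toward
  `1` as the margins become extreme (`k ≪ n`), compressing κ.
- Odds ratio `ad/bc`; when any cell is zero all cells get +0.5
  (Haldane–Anscombe) and the result is flagged as corrected.

### Uncertainty

- **Gene-resampling bootstrap**: genes are resampled with replacement and the
  two rankings and the table are rebuilt per resample (rank keys are
  precomputed once). This respects the constraint structure of the table.
  The standard error is the bootstrap SD; intervals are 2.5/97.5 percentiles.
- **Multinomial table bootstrap** (`bootstrap_table`): resamples the four
  cells of a raw table from its empirical multinomial; appropriate when only
  the table, not the rankings, is available. Degenerate resamples (a zero
  margin) are dropped and counted.
- **Grid Bayesian posterior** (`bayes_posterior`): parameters
  `(p_1·, p·1, p_11)` with multinomial likelihood
  `p_11^a (p_1·−p_11)^b (p·1−p_11)^c (1−p_1·−p·1+p_11)^d`, Beta(us, u(1−s))
  and Beta(vt, v(1−t)) priors on the margins and a conditional-uniform prior
  on `p_11` over its feasible interval
  `[max(0, p_1·+p·1−1), min(p_1·, p·1)]`. The default prior centers the
  margins at the design value `k/n` with weight `u = v = 2` (weakly
  informative; the margins are nearly fixed by design, so the prior mainly
  regularizes `p_11`). Evaluation is on a 101³ midpoint grid. The
  conditional prior is normalized by the **discrete count** of feasible
  midpoints per margin pair — not the continuous width — so the grid prior is
  exactly normalized; margin pairs whose feasible interval is narrower than
  one grid cell are rescued by their nearest midpoint rather than dropped
  (dropping them tilts the margin posteriors). Zero-count cells contribute
  exactly zero to the log-likelihood (cells are clamped at 1e−300 so
  `0·log(clamped)` vanishes while positive counts annihilate out-of-range
  midpoints). A raw `(0,0,0,0)` tuple is accepted and returns the prior,
  which requires an explicit prior.

## 2. Synthetic cohorts (`corac.synth_cohort`)

Genotypes follow a **latent-Gaussian threshold model**: each individual draws
two haplotype-level standard-normal vectors per LD block with exchangeable
within-block correlation (`rho_common = 0.3` between common-variant latents,
`rho_rare = 0.05` between rare-variant latents), and a variant's allele count
is the number of haplotype latents exceeding the frequency-matched threshold.
This produces integer genotypes in {0, 1, 2}, Hardy–Weinberg margins, strong
LD within blocks for common variants, weak LD for rare ones, and independence
across blocks. Common variants draw MAF uniformly above the split
(`maf_split = 0.01`); rare variants draw MAF log-uniformly below it. Rare
variants carry a functional category (`pLoF`, `missense_LC`, `synonymous`).
LD scores are within-block sums of squared genotype correlations.

`decorrelate_rare` permutes individuals **within the rare-variant columns
only** (block-wise), destroying the common–rare correlation while preserving
each variant's marginal genotype distribution; common-variant columns are
untouched, so matched runs share them bit for bit.

What the generator does **not** emulate: realistic LD decay within blocks
(exchangeable correlation instead), population structure and relatedness,
genotyping error/missingness, dominance or epistasis, imputation uncertainty,
and binary phenotypes with liability ascertainment (a binary effective sample
size helper `4/(1/n_cases + 1/n_controls)` is provided for bookkeeping only).

### Trait architecture (`corac.architecture`)

A fraction `prop_causal_genes = 0.10` of genes is causal for the common
pathway and (independently sized) for the rare pathway, with
`shared_causal_fraction = 0.50` of them shared. Within a causal gene,
`causal_variant_fraction = 0.5` of its variants receive effects. Effect
sizes follow the selection model

```
Var(β_i) = C · [p_i(1−p_i)]^exponent · (1/(1+l_i))^r
```

Two parameterizations of the exponent are provided because the literal
reading and the qualitative behaviour pull apart on *standardized* genotypes:

- `per-snp-h2` uses `exponent = 1 + α` literally; on standardized genotypes
  the per-SNP heritability is then `∝ [p(1−p)]^(1+α)`, which is
  frequency-flat at `α = −1`, not at `α = 0`.
- `frequency-flat-neutral` (default) uses `exponent = α` on the standardized
  scale, so `α = 0` gives frequency-independent per-SNP heritability and
  negative α concentrates heritability in rare variants — the qualitative
  dose–response the sweeps measure.

The scale `C` is chosen so the realized genetic variance equals `h2_trait`
(default 0.30) exactly; the phenotype adds matched Gaussian noise and is
standardized, and the realized h² is reported.

## 3. Association tests (`corac.assoc`)

- **Common variants**: per-SNP OLS on standardized genotypes (optional
  covariates are residualized out), then per gene a single p-value by
  **Brown's method**: Fisher's statistic `T = Σ −2 log p_j` referred to a
  scaled χ² matched to the mean and variance of the correlated sum. Because
  the SNP p-values are two-sided, the covariance of two `−2 log p` terms is
  an even function of the genotype correlation `r`; it is approximated by
  `cov(r) ≈ 3.891476 r² + 0.148540 r⁴ − 0.190052 r⁶ + 0.150036 r⁸`, a
  quadrature-fit polynomial (max error 0.0017) constrained to the exact
  endpoints `cov(0) = 0` (Fisher limit) and `cov(1) = 4` (duplicated-SNP
  limit). The familiar one-sided polynomial `3.263|r| + …` is *not* used:
  it is O(|r|) near zero where the two-sided covariance is O(r²), and
  plugging it in makes the combined test measurably conservative.
- **Burden**: Beta(1, 25)-weighted allele count per gene, OLS t-test.
- **SKAT**: weighted variance-component score statistic; the p-value of the
  quadratic form uses Liu's moment-matching to a noncentral χ².
- **SKAT-O**: Lee-style omnibus over `ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25,
  0.5, 1}`; the minimum-p statistic is integrated over a shared χ²₁ variable
  on a 512-point grid over `t ∈ [0, 6.5]`; if the integration degenerates a
  Bonferroni fallback is used and flagged. With a single rare variant all ρ
  give the same test and the code short-circuits.
- The gene table's `p_rare` is the **literal minimum** over test × category;
  it is a screening statistic, not a calibrated p-value (the individual
  tests are calibrated; the minimum is not corrected for multiplicity).

Numerical choice: central χ² tail probabilities and quantiles are computed
via `scipy.special.gammaincc/gammainccinv` directly (identical values to
`stats.chi2`, substantially faster in the SKAT-O inner loops).

## 4. Stratified FDR (`corac.stratfdr`)

The conditional FDR of a target p-value `p` given the conditioning stratum
(`p_conditioning ≤ threshold`) is `FDR(p) = π₀ · p / F̂(p)` with `F̂` the
empirical CDF of the target p-values **within the stratum**, floored at
`1/m`, and the result clamped at 1. `π₀` is Storey's estimator at
`λ = 0.5`, clamped to [0, 1]. Strata smaller than 20 genes warn (or are
dropped in the Q-Q analysis). The stratified Q-Q analysis reports expected
vs observed `−log10 p` quantiles per nested threshold (default
`{1, 0.1, 0.01, 0.001}`).

Note a structural property, verified by the tests: under a global null
`F̂(p) → p`, so `FDR(p) → π₀ ≈ 1` for every gene — the estimator correctly
reports that all discoveries under the null are false, rather than tracking
`p` itself.

## 5. Selection-exponent inference (`corac.selection`)

For summary statistics `(β̂_i, se_i, p_i, l_i)` the marginal model is
`β̂_i ~ N(0, C·[p_i(1−p_i)]^(1+α)·(1/(1+l_i))^r + se_i²)` with variants
treated as independent given their LD scores. α is estimated by maximizing
the profile likelihood over a grid `α ∈ [−1.5, 1]` (step 0.01), profiling
out `log C` by bounded 1-D optimization (±12 nats around a
method-of-moments guess), then refining the grid maximizer locally. A flat
profile (range < 1e−6) or insufficient MAF spread (`max het/min het < 2`)
raises an identifiability error rather than returning an arbitrary value.

`simulate_summary_stats` draws MAF **log-uniformly** on `[0.005, 0.5]` (a
stand-in for the neutral site-frequency spectrum, whose density is roughly
∝ 1/p; a uniform spectrum underrepresents rare variants and carries much
less information about α) and scales `C` so the summed per-variant variance
equals `h2` exactly.

## 6. Experiments and trends (`corac.experiments`, `corac.trend`)

`run_replicate` executes one end-to-end replicate: genome → genotypes → LD
scores → causal assignment → effects → phenotype → gene tests → clump →
top-k table → κ/AC1/OR. Stage seeds derive from
`(master_seed, n_eff, replicate, stage)` so matched contrasts (e.g., the
decorrelated twin) share every upstream draw; the decorrelate flag is
deliberately excluded from the seed key. Effective sample size for binary
designs uses the harmonic convention `4/(1/n_cases + 1/n_controls)`.

Trend analysis reports Spearman and Kendall correlations (optionally partial
versions given a covariate) and a heteroskedastic GLS fit with
`Var(ε) ∝ x^{2θ}`, θ profiled over `[−2, 2]` in steps of 0.05 with ties
broken toward smaller |θ|.

## 7. Default parameters and why

| parameter | default | reason |
|---|---|---|
| `k` (top-k) | 100 (library), 60 in sweeps | ~10% of the desk-scale 600-gene genomes; keeps table margins away from degeneracy |
| `rho_common` / `rho_rare` | 0.3 / 0.05 | strong LD among common variants, weak among rare — the qualitative contrast the decorrelation experiment needs |
| `maf_split` | 0.01 | conventional common/rare boundary |
| `h2_trait` | 0.30 | a mid-range complex-trait heritability |
| `prop_causal_genes` | 0.10 | sparse architecture with enough causal genes (60/600) for a stable top-k overlap |
| `shared_causal_fraction` | 0.50 | half the causal genes shared between pathways — the signal the statistic measures |
| `alpha` | −0.37 | matches published biobank-scale estimates of the selection exponent |
| burden weights | Beta(1, 25) | standard rare-variant weighting |
| SKAT-O ρ grid | {0, .01, .04, .09, .16, .25, .5, 1} | standard grid |
| Storey λ | 0.5 | conventional; stable at desk-scale gene counts |
| bootstrap draws | 1000 | SE stable to ~3% |
| Bayes grid | 101³ midpoints | grid error ≲ 0.005 on posterior means; fits in memory (~8 MB per array) |

## 8. Limitations

- The cohort generator is a mechanism model for *method* validation, not a
  population-genetics simulator; absolute κ values have no empirical meaning.
- At desk scale (≤ 4000 individuals, 600 genes) the common-variant pathway is
  weakly powered, so κ estimates are small and noisy; contrasts between
  matched configurations are the meaningful outputs.
- The sweep contrast in α is not guaranteed monotone across the full range
  {0.5, 0, −0.37, −1} at fixed total h²: more negative α moves heritability
  into the rare pathway, which first balances and then starves the
  common-variant ranking, so the group mean of κ can peak at an intermediate
  α rather than decrease monotonically.
- `p_rare` (minimum over tests × categories) is anti-conservative by
  construction; use the per-test columns for calibrated inference.
- The selection-exponent estimator assumes independent variants given LD
  scores and Gaussian effects; per-replicate error grows for α > 0, where
  the effective number of informative variants shrinks.
- SKAT-O's Liu-type tail approximation is accurate to roughly 1e−2 in the
  far tail; the test suite checks calibration at conventional levels, not at
  genome-wide significance.
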
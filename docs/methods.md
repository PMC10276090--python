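# Methods

## The analysis model

The pipeline addresses a trio design: affected children (probands) and both
biological parents are genotyped, discovery GWAS summary statistics for one
or more traits provide per-variant weights, and two questions are asked.

**Transmission.** Under Mendelian transmission the child's polygenic score
has within-family expectation equal to the mid-parent score
m = (PGS_f + PGS_m)/2. The polygenic transmission disequilibrium test (pTDT)
forms, for each complete trio, the standardized deviation

    d_i = (PGS_child,i − m_i) / SD(m)

and tests E[d] = 0 with a one-sample two-sided t-test (df = n−1). Because
each child is compared only to their own parents, between-family structure —
ancestry, socioeconomic confounding, assortative sampling — cancels exactly;
ascertainment of the children on a phenotype genetically correlated with the
scored trait is the only force that shifts E[d] away from zero. Cohorts are
combined by pooling each cohort's own standardized deviations and re-testing
the pooled vector; each cohort keeps its own composite standardization and
its own mid-parent SD, so the pooled entries are unit-comparable. (Whether
to re-standardize before pooling is a genuinely open choice; pooling
already-standardized deviations is adopted here because it makes the
combined mean a weighted average of cohort effect sizes rather than of
cohort-specific raw score scales.)

**Case-only association.** Within probands, each binary comorbid outcome y
is modeled as

    logit P(y=1) = α + γᵀc + β · PGS

with covariates c = top-5 genotype PCs, genotyping batch, age. β is per SD
of the composite (the composite is z-standardized), so exp(β) is a per-SD
odds ratio. Families can contribute siblings, so standard errors use a
cluster-robust sandwich estimator A⁻¹BA⁻¹ with A the observed information
and B = Σ_c g_c g_cᵀ, g_c = Σ_{i∈c} x_i(y_i − μ̂_i) — a GEE with independence
working correlation, whose point estimates coincide with the ordinary MLE.
Variance explained is the Nagelkerke pseudo-R² difference between the full
model and the covariates-only model, both referenced to the intercept-only
likelihood; p-values within a battery of (PGS, outcome) pairs are adjusted
by Benjamini–Hochberg step-up FDR.

## Scoring

A raw score at threshold t sums aligned weights times alt-allele dosages
over variants with discovery p < t (strict inequality, so a variant at
exactly p = t is excluded — fixed to avoid boundary ambiguity). Missing
dosages are mean-imputed at twice the panel alt-allele frequency, matching
the default of standard scoring tools (this equals 2×MAF whenever alt is the
minor allele). Scores are weight sums, not per-SNP averages; the downstream
z-standardization makes the choice immaterial, but it is fixed for
reproducibility.

The threshold ladder defaults to {0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0}, a
conventional sparse-to-all-SNP progression. The seven columns are
z-standardized, the first principal component is extracted (sklearn PCA; a
brute-force eigen-decomposition serves as the test oracle), its sign is
flipped if its loading sum is negative — PC signs are unidentifiable, and
this rule keeps the composite positively oriented with the threshold
scores — and the PC1 scores are z-standardized into the final composite.
Constant columns (e.g. a threshold passed by zero variants) carry loading 0.
The composite is standardized over the full scored set (parents and
children together); standardizing within analysis subsets instead would
change nothing for the pTDT (deviations are location/scale invariant) and
only rescale β in the association model.

## Harmonization

Variants are matched by id, falling back to chrom:pos when ids are absent.
An (effect, other) pair equal to (alt, ref) keeps its weight; (ref, alt)
negates it; pairs matching only after complementing both alleles are treated
as strand flips with the same sign rule afterwards. A/T and C/G variants are
dropped by default (drop is configurable off): without strand annotations
their orientation is unresolvable, and silently keeping them risks
sign-flipped weights. The MAF > 5% filter is computed in the target panel.
Drops are fully accounted: n_input = n_retained + per-reason drop counts.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular genome:

- **Variants**: m biallelic SNPs, allele frequencies uniform on a
  configurable range (default 0.05–0.5), linkage equilibrium. No LD is
  simulated — the scoring path uses thresholding without clumping, so LD
  would only dilute interpretability of the oracle checks. Allele pairs are
  drawn from the strand-unambiguous combinations by default; an
  `ambiguous_fraction` knob injects A/T-C/G pairs for harmonization tests.
- **Parents**: dosages Binomial(2, p_j) (random mating); **children**
  receive one uniformly drawn allele per parent, so a parent with dosage d
  transmits an alt allele with probability d/2.
- **Liability and ascertainment**: true effects β_j ~ N(0,1) on a random
  subset of n_causal variants; the true PGS is standardized analytically
  (population mean 2Σp_jβ_j, variance Σβ_j²·2p_j(1−p_j)); liability =
  √h²·z_PGS + √(1−h²)·ε. A child is ascertained when liability exceeds the
  population (1−q) quantile; trios are generated in batches until n are
  retained. q = 1 disables ascertainment and gives an exact pTDT null.
- **Outcomes**: Bernoulli with logit = intercept + effect·z_PGS (optional
  shared family intercept). Default outcome names, prevalences (insomnia
  .256, restless sleep .559, poor sleep quality .197, nightmares .184,
  hypersomnia .041), medication rates (.303/.148), the 13.3% female child
  ratio, ages 5–18, three genotyping batches and ~5% multi-child families
  mirror a clinic-ascertained ADHD cohort's descriptives; default PGS
  effects are zero. A parent-report replica of each outcome (positives kept
  with probability 0.9) supports the parent-report-only sensitivity mode.
- **Discovery sumstats**: estimated weight = β_j + se_j·ε with the usual
  GWAS scaling se_j = 1/√(2p_j(1−p_j)N); p-values are two-sided normal on
  the implied z-score, so null variants have uniform p-values at every noise
  level and N = ∞ gives noise-free weights. A quarter of rows (configurable)
  are emitted with effect/other alleles exchanged and the weight negated, so
  a run through the harmonizer must reconstruct the aligned weights exactly.
- **Missingness** is injected completely at random at a configurable rate;
  all randomness flows from one seed through per-stage spawned streams, so
  identical configs reproduce byte-identical cohorts.

What the generator does **not** emulate — LD, assortative mating, parental
phenotypes, imputation uncertainty, genotyping error, population structure
within a cohort — bounds what passing tests show: they validate the
statistical machinery (calibration, exactness, invariances, power ordering)
under the assumed model, not robustness of real-data results to those
violations.

Simulation defaults (n_trios = 328, n_variants = 20 000, n_causal = 2 000,
h² = 0.05, top-5% ascertainment) sketch a clinical trio study at realistic
scale; the effective ascertainment severity of clinical recruitment and the
per-trait h² of a scored variant set are not knowable a priori, so these two
are illustrative defaults, not calibrated quantities.

## Numerical choices

- Logistic fits use explicit IRLS; convergence when max|score| < 1e-8 or the
  relative log-likelihood change < 1e-10; perfect separation is detected
  both by coefficient divergence with degenerate weights and by fitted
  probabilities saturating at the outcomes, and reported with the offending
  column. statsmodels is used only as an independent cross-check in tests.
- Sandwich covariance applies no small-sample correction, so singleton
  clusters reproduce HC0 exactly.
- Wald 95% CIs use the normal quantile 1.96 on the log-odds scale.
- Deviations use the sample SD (ddof = 1) of the retained mid-parent scores;
  mid-parent SD of 0 (degenerate scores) is a hard error, as are n < 2 or
  all-equal deviations.
- Multi-proband families contribute one child chosen uniformly under a
  recorded tie-break seed.
- Ancestry PCs: monomorphic variants excluded, columns centered and
  variance-standardized, PC signs fixed by the largest-magnitude loading;
  requesting more PCs than the rank returns fewer with a warning.
- Nagelkerke ΔR² is clipped to [0, 1]; a full-model likelihood below the
  null beyond 1e-8 is reported as a fit error rather than truncated.
- BH-FDR rejects p ≤ 0 or > 1 rather than silently clipping.

## Problem sizes used in tests and the acceptance script

Simulation-based checks run at sizes chosen to make Monte-Carlo error small
relative to the asserted margins while keeping a full run inside a few
minutes on one core: Mendelian integrity on 500 trios × 2000 variants; null
calibration over 1000 cohorts of 200 trios (120 variants — pTDT calibration
does not depend on variant count); the ascertainment signal on 2000 trios
against an independently coded allele-level oracle of 3000 trios (top 5%,
h² = 0.3); power at 328 vs 844 trios over 60 replicates at a weak signal
(h² = 0.02, top-20% ascertainment, mean deviation ≈ 0.14 — the strong
setting saturates power at both sizes, so the ordering is probed where it is
informative); pooling over 200 replicates of a 328 + 844 pair; sandwich CI
coverage over 500 replicates of 100 four-member families with exchangeable
outcome correlation induced by a Gaussian copula (which preserves the
marginal logistic model exactly, so nominal coverage is the correct target);
and an end-to-end run on a 300-trio cohort with a simulated per-SD OR of
1.5 recovered within three robust SEs.

## Known limitations

- No LD, clumping, or liftover; variant matching assumes consistent builds.
- Independence working correlation only (sufficient for sandwich-corrected
  inference, but not efficient under strong within-family correlation).
- The pTDT here is the composite-score form; no per-threshold
  decomposition, parent-of-origin analysis, or X-chromosome handling.
- Complete-case analysis for outcomes/covariates; no phenotype imputation.
- VCF support covers biallelic SNPs with GT genotypes (dosage-format fields
  are not read).
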
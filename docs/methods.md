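# Methods

`pescore` implements pathway-partitioned polygenic risk scoring: the
pharmagenic enrichment score (PES) framework, in which common-variant
risk from a GWAS is aggregated within druggable biological pathways and
profiled per individual.  This note records the models, the numerical
choices, and what the synthetic study conditions do and do not show.

## Pipeline model

**Gene-level aggregation.**  SNPs are mapped to genes with asymmetric
regulatory windows — 5 kb upstream and 1.5 kb downstream of the gene
body, mirrored for `-`-strand genes (unknown strand treated as `+`),
boundaries inclusive.  Genes overlapping the MHC (default
chr6:25–34 Mb, GRCh37 coordinates, configurable) are excluded because of
the region's extended haplotype structure.  For each gene and each
P-value ceiling P_T ∈ {1 (all SNPs), 0.5, 0.05, 0.005}, SNPs with
P < P_T (strict) are combined with

  T = Σ_j [Φ⁻¹(1 − P_j/2)]²,

the sum of two-sided χ²(1) transforms.  Under the null the SNP z-scores
are MVN(0, R) with R the dosage correlation (LD) matrix from a
reference panel, so T is the quadratic form z'z — a weighted sum of
independent χ²(1) with weights the eigenvalues of R.  The gene P is
the *exact* upper tail of that law, evaluated by characteristic-function
inversion (Imhof's method) with chunked Gauss–Legendre quadrature sized
to the oscillation period; equal-weight cases (single SNP, perfect
duplicates, identity LD) reduce to closed-form χ² tails.  A
Satterthwaite moment match (scale c = Var/2E, df ν = 2E²/Var with
E = M, Var = 2M + 4Σ_{j<k} r²_{jk}) is reported as a diagnostic and
substitutes only beyond the integral's numerical resolution
(P < 10⁻⁹), where its log-scale accuracy is adequate for ranking.
Gene Z = Φ⁻¹(1 − P), clamped at ±8.2 against probit overflow.

LD matrices are computed on mean-imputed dosages; non-PSD estimates are
shrunk toward the identity (λ = 0.001).

**Competitive gene-set association.**  For each pathway and P_T, OLS of
gene Z on a membership indicator with covariates {1, M_g, log M_g}
(gene SNP count and its log, the standard gene-size confounders); the
one-sided P on the membership coefficient tests whether pathway genes
are more strongly associated than the rest.  Gene–gene LD between
neighbouring genes is ignored in the default test — desk-scale fixtures
use weak inter-gene LD, and under the null the calibration check holds
(type-I error within the binomial band at α = 0.05).  Exact-fit
degeneracies (constant Z) return P = 0.5.  Pathways reaching P < 0.001
(strict) at any P_T become PES candidates, each with the P_T of its most
significant association; exact ties prefer the more stringent threshold.

**Scoring.**  Greedy LD clumping (visit SNPs by ascending P, ties by
SNP id; drop unretained SNPs within 250 kb at r² > 0.1 — PRSice-style
defaults, as the clumping parameters are a free choice) precedes all
scoring.  A score is the plain additive sum score_i = Σ_j β̂_j G_ij over
harmonised effect alleles; missing dosages are mean-imputed per variant
so score length is constant across individuals.  A per-SNP-count
standardisation flag exists but is off by default.  PES restricts the
sum to the SNPs of one candidate pathway's genes at that pathway's P_T;
PRS_Total uses all clumped SNPs at the P_T (grid 5e-8 … 1.0) that
maximises the Nagelkerke R² *increment* of `case ~ covariates + score`
over the covariate-only logistic model, ties toward the smaller P_T.
PRS_Total retains the MHC; PES excludes it implicitly through the
gene-level analysis.

**Profiling.**  Elevated-PES carriers are defined by nearest-rank
percentiles (75/90/99) of the pooled study population, boundary ties all
flagged (a cases-only option exists).  Score and carrier-count
associations with case status are binomial logistic fits adjusted for
sex and three genotype principal components, Wald P values, with and
without PRS_Total as an extra covariate.  The joint structure of
(PRS_Total, top-decile PES count) is clustered by Gaussian mixtures
fitted with EM over six covariance families — spherical / diagonal /
full, each with equal or per-component parameters (an approximation of
the mclust family grid; orientation-constrained families such as VEV
are not implemented).  EM uses seeded k-means initialisation with 10
restarts, relative log-likelihood tolerance 1e-6, at most 500
iterations, a covariance floor of 1e-6 × mean data variance, and a
monotonicity guard on the log-likelihood; degenerate candidates (empty
components, non-PD covariance) are discarded.  Model and K are selected
by the highest BIC in the mixture convention, 2·loglik − k·ln(n).
Carrier over-representation per cluster is a multinomial logit against
the largest cluster (clusters under 5 members dropped), Wald z per
contrast.

**Drug annotation.**  Per candidate pathway, each drug with ≥1 target
in the pathway is scored by the hypergeometric upper tail P(X ≥ k)
with (N = annotation universe, K = targets in universe, n = pathway
size); BH adjustment is applied per pathway (the pooled alternative is
a one-line change), and enrichment requires q < 0.05 with ≥3
overlapping targets.  Top-drug selection offers the
interaction-confidence mode (max score among approved drugs hitting a
druggable pathway gene) and the ORA mode (min q, ties by larger
overlap, then drug name).

**Expression.**  Each PES is tested against the expression of its own
pathway's genes: OLS `expression ~ PES + age + sex + PRS_Total`, t =
β̂/SE with two-sided P on residual df, BH within pathway, exploratory
FDR < 0.1.  Genes shared by several candidate pathways are tested once
per pathway, matching the per-pathway correction structure.

## Data handling

Coordinates are 1-based inclusive throughout.  Odds ratios are
converted to β = ln(OR) at read time.  Variant QC keeps missingness
strictly below 2% and imputation quality strictly above 0.8 (the
quality field is treated as an opaque [0, 1] value).  Allele
harmonisation joins on (chrom, pos) by default (SNP-id join is opt-in,
since ids drift across builds), sign-flips β when the genotype's
counted allele is the non-effect allele, and drops strand-ambiguous
palindromic pairs (A/T, C/G), allele mismatches, and conflicting
duplicates, all with logged counts.  The VCF counted allele is ALT; for
PLINK it is the bim column-5 (A1) allele.  The PLINK codec handles hard
calls only; fractional dosages travel via VCF DS.

## Synthetic study conditions

The generator produces every input the pipeline consumes, with the
structure the analysis assumes:

- **Genotypes** — blocks of 20 SNPs; within a block each haplotype is a
  latent AR(1) Gaussian (ρ = 0.8) thresholded at the allele-frequency
  quantile (MAF ~ U(0.05, 0.5)); dosage = sum of two haplotypes.  This
  gives controllable LD at desk scale; it does not reproduce human LD
  maps, population structure, or ascertainment.
- **Phenotype** — additive liability threshold model: causal SNPs
  (fraction 0.2) have Gaussian effects, with effect *variance* inflated
  15-fold for SNPs in enriched pathways' genes; liability is scaled to
  h² = 0.7 (a strongly heritable trait) and dichotomised at prevalence
  0.2.  The prevalence is deliberately far above a rare-disorder value
  (~0.7%) so that a desk-scale pool yields a full case sample.
- **Summary statistics** — per-SNP logistic GWAS (intercept + dosage,
  full Newton fit vectorised across SNPs; validated against statsmodels)
  on a separate 4000-individual discovery cohort in the paper-shaped
  preset.  The two-cohort design mirrors the realistic setting — a large
  external GWAS scored in a small target cohort — and avoids
  winner's-curse coupling; a same-cohort mode exists and is the default
  for the small presets.
- **Cohort** — 425 cases and 251 controls sampled from a population
  pool; sex, age and three genotype PCs accompany the labels.
- **Pathways** — 50 sets of 10 genes over 250 genes tiling the SNPs;
  eight planted enriched sets in the paper-shaped preset (a realistic
  hit fraction); every set retains ≥1 druggable gene, mirroring a
  collection pre-filtered for drug targets.  Drug–gene tables mix
  scattered random targets with one pathway-focused drug per set, the
  concentration pattern that target databases show and that ORA detects.
- **Expression** — pathway genes respond linearly to their pathway
  score (γ = 0.5 per score SD on half of each pathway's genes, noise
  SD 1, small age effect) in a 75-case subset.

Sizes were fixed once from power reasoning — with a 4000-sample
discovery GWAS and the 15× enrichment multiplier, an enriched gene
carries enough association for its pathway to clear the P < 0.001
candidate threshold in most runs with a single planted set, while the
eight-set condition splits the same heritability and yields partial
detection, which is the realistic regime.  Everything flows from one
seed; fixture suites are bitwise reproducible.

Passing tests on these conditions demonstrate internal correctness and
calibration (exact score arithmetic, exact gene-level null under the
declared MVN model, calibrated set-level and Wald inference, BIC model
selection, FDR control), not performance on real human data — real LD,
stratification, phenotype misclassification and array normalisation
artefacts are all out of scope.

## Numerical choices and degenerate inputs

- Imhof integration: 128-node Gauss–Legendre per 8-period chunk,
  alternating-remainder stopping rule (< 1e-8), far-tail fallback below
  P = 1e-9; eigenvalues below 1e-10 of the maximum are dropped.
- Percentile rule: k = ceil((1 − q)·N) computed with a pre-ceil
  rounding guard against binary-representation noise.
- Competitive test exact fits: coefficients below 1e-10 of the response
  scale count as zero (P = 0.5).
- Logistic fits: Newton with at most 200 iterations; separation or
  non-convergence raises a degenerate-design error rather than
  returning unstable estimates.
- Clumping determinism: P ties break lexicographically by SNP id, so
  the retained set is invariant to input row order.
- Empty results (no candidate pathways, all variants QC-removed) are
  warnings, not errors, and propagate as empty tables.

## Known limitations

- The competitive test ignores inter-gene LD; on real data adjacent
  genes share signal and the test is anti-conservative there.
- The six GMM covariance families omit mclust's orientation-equal
  (e.g. VEV) parameterisations.
- The gene omnibus statistic is the declared sum-of-χ²(1) kernel with
  an LD-aware null; it is not claimed to reproduce MAGMA's numbers.
- PLINK I/O covers the 2-bit bed format (hard calls) only.
- Drug ORA consumes a pre-built interaction TSV; no live database
  queries, no ATC ontology analytics.
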
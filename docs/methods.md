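# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Study design being modeled

The cohort structure is a two-age (young/old), two-sex factorial over five
genotypes at an engineered two-SNP locus.  Because heterozygous and
homozygous carriers of each humanized allele behave alike transcriptionally,
genotypes collapse into three carrier groups under a dominant coding:
FC carriers (WT/FC, FC/FC), wild type (WT/WT), and VS carriers
(WT/VS, VS/VS).  All haplotype models operate on these groups; the
dominant-vs-additive comparison (`compare_codings`) is the package's check
of that modeling choice, contrasting the adjusted R² of the ordered carrier
axis (−1, 0, +1) against the allele-dosage axis (FC/FC = −2 … VS/VS = +2).

## Normalization

* **Size factors** are median-of-ratios: per-gene geometric-mean reference,
  per-sample median of count/reference ratios, recentred so the factors'
  geometric mean is exactly 1.  If no gene is expressed in every sample the
  reference falls back to genes expressed in ≥ 50% of samples (geometric
  mean over nonzero entries), with a warning.
* **Variance-stabilizing transform**: `log2(count / factor + pseudocount)`
  with pseudocount 1.  The mean–dispersion trend refinement some packages
  add is deliberately omitted: every downstream model needs only a monotone
  scale on which variance does not grow systematically with the mean, which
  the log transform provides for overdispersed counts (verified on NB
  simulations in the tests).  The pseudocount and the decision to
  residualize on the transformed scale are recorded in the expression
  file's provenance header.
* **Residualization** regresses covariate indicator columns out of each
  gene by least squares and re-adds the gene's grand mean, so set means stay
  interpretable.  Order: sequencing batch at normalization time, sex before
  the haplotype-trend analyses (sex is a model term, not a nuisance, in the
  factorial scan).  Residualization is exact: batch F statistics on the
  residuals are identically zero, which is the property the tests assert
  (a uniform-p claim would be self-contradictory here, since the group
  means are removed exactly).

## Factorial differential expression

Ordinary least squares per gene on the full design (age, sex, haplotype,
and the three pairwise interactions; age terms dropped for single-age
cohorts).  Term significance is a partial F-test respecting marginality
(type II): a main effect is tested against the model containing the other
mains and the interactions not involving it; every test uses the complete
model's residual mean square.  Whether the source analysis used t- or
F-tests per term is not stated; F-tests are the term-level choice that
works for the 3-level haplotype factor.  BH adjustment is applied within
each term across genes; DEG counts at FDR 0.05 per cohort reproduce the
qualitative structure of the emulated study (haplotype ≫ sex in the old
cohort, ≈ nothing in the young cohort, no sex:haplotype interaction).
Constant genes return F = 0, p = 1 rather than NaN.

## Ordered-haplotype trend model

For each gene set, the per-sample unweighted mean of its member genes
(members absent from the matrix are dropped and counted, not imputed) is
regressed on the centered linear contrast FC = −1, WT = 0, VS = +1.  The
reported quantities are the contrast coefficient β (sign convention:
positive = higher in VS carriers), **adjusted** R² (chosen because the
emulated analysis reports negative values, which only the adjusted form
produces), and the coefficient's two-sided t-test p.  The quadratic
contrast is computed as a curvature diagnostic but never tested, matching
the single-coefficient reporting of the source analysis.  BH families are
kept separate — subdomains (screened at FDR 0.05), Biodomains, and
KEGG×Biodomain intersections (screened at FDR 0.001) — because the source
applies different thresholds to different analyses.  With equal group
sizes, β equals half the VS-minus-FC group-mean difference (an identity the
tests exercise).  Absolute β values are not comparable across contrast
scalings; they are used as sign/rank quantities.

Intersections are all pathway × domain pairs with ≥ 10 **annotated** shared
genes (the expression-present count is logged but does not drive the
filter).  Retained intersections populate a pathway × domain biadjacency
matrix of β values, rows and columns ordered by mean |β|.

## Differential exon usage

Within a gene, feature counts follow a Dirichlet-multinomial:
x_i ~ DM(n_i, γ·p_i) with logit-linear proportions (softmax over per-feature
linear predictors, last feature as reference) on intercept + batch + sex +
genotype.  Features are kept when expressed (> 0) in ≥ 10 samples **and**
averaging ≥ 10 reads (both inclusive, per the stated "at least" rules);
genes then need ≥ 2 surviving features.  The test is an LRT of the full
versus the genotype-free design over FC vs VS carriers (WT excluded), χ²
with (K−1) df, BH ≤ 0.05.

Precision handling matters for calibration.  `fit_dm` provides the joint
MLE over coefficients and log γ (L-BFGS-B with analytic gradients,
two starts: pooled-proportion logits and uniform).  For testing, γ is
instead estimated once per gene by **Cox–Reid adjusted profile likelihood**
under the full design — the profile log-likelihood penalized by half the
log-determinant of the coefficient information — and held fixed in both
LRT fits.  The joint MLE overestimates γ in small samples and inflated the
null rejection rate to ≈ 0.07 at the 20-vs-20, depth-500, K = 3 design;
the CR-adjusted estimate is unbiased there (median γ̂ ≈ 50 at true 50) and
brings the rate to ≈ 0.05–0.06.  Residual mild anticonservatism is the
expected finite-sample behavior of the χ² approximation at n = 40.  At
γ → ∞ the statistic coincides with a multinomial logit LRT (tested at
fixed γ = 10⁶).

## Cross-system comparison

Ortholog pairs are filtered to strict one-to-one (any id in two pairs is
dropped) to avoid double counting in set means.  Transcripts need ≥ 10
total counts across all samples.  For each intersection, mapped genes are
averaged across replicates within treatment group and the stacked per-gene
group means are regressed on a centered ±½ treatment indicator with
per-gene intercepts, so the coefficient is the mean treated-minus-untreated
difference over the set (a per-replicate fit is available behind a flag; on
balanced data the two coincide).  Agreement across sets is the Spearman
rank correlation of the two β vectors — the t approximation for > 10 sets,
exact permutation enumeration for ≤ 10 — plus per-set classes: concordant
(both |β| at or above their family's magnitude floor, same sign),
discordant (both pass, opposite sign), else null.  The floor defaults to
each family's median |β|.

## Synthetic-data generator

The generator emulates the study conditions, not any particular dataset:

* **Cohort**: one row per animal over the (genotype, sex, age) cells, with
  batches assigned round-robin within each cell.  Cell sizes are free
  parameters (the published per-cell counts do not sum to the reported
  carrier-group totals, so nothing is hard-coded);
  `study_cohort_design()` reproduces the published per-cell table, and the
  evaluation cohort uses 20 samples per carrier group, the reported
  old-cohort scale.
* **Gene counts** are negative-binomial with a single user-set dispersion
  (default 0.05) — the simplest model consistent with overdispersed bulk
  RNA-seq — log-uniform baseline means in [20, 2000], and per-(gene, batch)
  log-normal offsets (SD 0.15 by default) drawn once per batch, matching
  removal by linear residualization.  Three sex-marker genes with
  deterministic sex-dependent means are always included so sex validation
  is testable.
* **Set-level haplotype effects** are injected on the log scale.  An
  effect `delta` is expressed in units of the within-group SD of the set's
  mean normalized expression; the generator converts it to a log2 offset by
  numerically solving against the exact NB moments of log2(X+1) (a
  linearized delta-method conversion attenuated planted effects by ~15%
  for low-mean genes).  VS carriers get +c/2 and FC carriers −c/2
  (dominant: het = hom; additive: het gets half), and age-restricted
  effects apply only to the last age label, which is declared young → old.
  Positive delta therefore means higher expression in VS carriers.
  Per-gene haplotype/sex effects (used for the DEG-count structure) are
  placed only on genes outside every supplied set, so set-level truth —
  including delta = 0 for unlisted sets — is never contaminated.
* **Exon counts**: per-gene totals Poisson(depth); feature splits DM with
  group-specific proportions for truth genes (FC −shift/2, VS +shift/2 on
  the target feature, others rescaled).  Infeasible shifts are rejected,
  never clipped; for truth genes the base split is redrawn until the shift
  fits with a 0.02 margin.
* **Organoid data**: two groups × 3 replicates (the source experiment's
  replicate count).  Treated effects on a set's mapped genes equal
  effect_log2 × (mouse delta), sign-flipped for discordant sets and zero
  for null sets, so rank agreement grows with effect size; 500 unaffected
  background genes anchor the size-factor normalization.

What the generator does **not** emulate: gene–gene correlation, per-gene
dispersion trends, library-composition artifacts, cell-type mixtures, or
annotation noise in the gene sets.  Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under an idealized
overdispersed-count world, not that real-data effect sizes would be
recovered at these rates.

## Evaluation conditions (problem sizes and effect sizes)

The evaluation module fixes the study-like conditions used by both the
test suite and `scripts/acceptance.py`: 100 random designs for the
normal-equations agreement check; 10,000 null genes for factorial
calibration; 500 null simulations × 200 sets for the intersection screen;
planted intersection effects of ±2 SD with 20 carriers per group (at the
FDR 0.001 screen, the standardized set-mean difference has Monte-Carlo SE
≈ 0.32 at this n, so ≥ 90% recall requires delta ≳ 1.9 — 2 SD is the
representative strong-effect condition); coding comparison at 5 SD (the
dominant and additive predictors are highly collinear, and the emulated
study's coding decision was unambiguous, i.e. a strong-effect regime);
1,000 null genes and 100 planted genes (shift 0.25, depth 500) for the
usage test; 60 intersection sets for the cross-system comparison (the null
Spearman SD is 1/√(n−1), so a many-set comparison like the source's ~180
intersections is required for a tight null — 60 is the desk-scale
equivalent); 100 simulations each for the null-concordance and
sex-validation rates.

## Known limitations

* The vst is the pseudocount-log transform, not a fitted mean-dispersion
  transform; on data with extreme dispersion trends the variance flattening
  is only approximate.
* DM LRT p-values retain mild finite-sample anticonservatism (~0.01 at
  α = 0.05, n = 40) even with CR-adjusted precision; no moderation across
  genes is attempted.
* The exact permutation Spearman p enumerates up to 10! permutations and is
  intended only for the ≤ 10-set regime.
* `biadjacency` orders rows/columns by mean |β|; no clustering is applied.
* Ortholog handling is strictly one-to-one; many-to-many homology is
  discarded rather than resolved.
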
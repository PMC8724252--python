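# Methods

## The question and the model

Alleles that increase the risk of late-onset Alzheimer's disease (AD)
should, if they act on AD alone, reduce the odds of becoming a cognitively
healthy centenarian in proportion to their AD effect. This package
quantifies, per variant, the *imbalance* between the two effects and asks
whether the observed directions could be chance.

Each variant k carries two log odds ratios, both expressed for the
AD-risk-increasing allele:

* `E_AD^k > 0` — effect on AD, taken from published GWAS summary
  statistics (point estimate and standard error);
* `E_LGV^k` — effect on longevity, estimated here by logistic regression
  of centenarian status (case) versus population controls on allele
  dosage, adjusting for the first five genotype principal components.

The *expected* direction is `E_LGV < 0`. A variant's imbalance is the
normalized angle of its effect point,

    alpha = atan2(E_LGV, E_AD) / (pi/2),

which is scale-invariant, negative iff the direction is expected, equals
−1/2 exactly when the longevity effect mirrors the AD effect
(`E_LGV = −E_AD`), and equals 0 exactly when there is no longevity effect.
Because both coordinates are noisy, each variant gets a sampling
distribution of alpha: S independent draws from
`Normal(E_AD, se_AD²) × Normal(E_LGV, se_LGV²)` mapped through the angle.
The AD and longevity draws are independent (no correlation model is
available for two estimates from disjoint datasets). Variants are grouped
by the median alpha:

| group     | rule                  | reading                          |
|-----------|-----------------------|----------------------------------|
| Longevity | median ≤ −1/2         | longevity effect dominates       |
| AD        | −1/2 < median ≤ 0     | AD effect dominates              |
| Unex      | median > 0            | unexpected direction             |

Sampled `E_AD` can cross zero for weakly-estimated variants, pushing alpha
outside [−1, 1] (full range (−2, 2]). Draws are kept at their raw value —
clamping or folding would hide the sign-flip mass that makes some
distributions bimodal — and only the median is used for grouping.

Direction counts (how many of n variants have `E_LGV < 0`, computed from
the point estimates) are tested against a fair-coin binomial null with an
exact two-sided test (minimum-likelihood summation; at p₀ = 0.5 this is
the doubled smaller tail). The same test is applied to direction
concordance with an external parental-longevity GWAS, where only the sign
of the harmonized effect is compared because a by-proxy design is on a
different effect scale. All multiple-testing control is
Benjamini–Hochberg, with significance called at adjusted p < 0.05
(strict).

## Estimation details

* **Logistic fit.** Newton/IRLS, convergence tolerance 1e-8 on the
  log-likelihood, at most 100 iterations; matches statsmodels GLM to
  1e-6 (tested). Missing dosages are dropped per variant. Perfect
  separation is flagged (|coef| > 15 or non-finite information), never
  raised.
* **Uncertainty on `E_LGV`.** Nonparametric bootstrap stratified within
  cases and within controls (B resamples, default 10,000), preserving the
  fixed case-control design. `se_LGV` is the SD of converged replicate
  estimates; the interval is the 2.5/97.5 percentile. Replicates that fail
  to converge are excluded and counted (warning above 10%).
* **Frequency filter.** Variants must have minor allele frequency
  strictly above 1% in each cohort separately (the stricter reading of
  "in our cohorts"); monomorphic variants are excluded with their own
  reason code.
* **Rank-sum tests** (within-group annotation comparisons) use the exact
  Mann–Whitney null when the pooled sample is ≤ 25 without ties, else the
  tie-corrected normal approximation with continuity correction; each
  result records which path ran.
* **Enrichment.** Per iteration, one candidate gene per variant is drawn
  uniformly; the list is scored against every gene set with a
  hypergeometric upper tail over the gene-set-union background
  (overridable). Per-term p-values are combined across iterations by
  arithmetic mean — conservative and order-invariant (Fisher's method was
  considered and rejected: it is dominated by a single lucky iteration).
* **Variant-pathway mapping.** Per gene, the fraction of its
  enriched-term memberships in each semantic cluster; per variant, the
  unweighted mean over its genes (genes with no enriched term ignored),
  renormalized to sum 1. This is a reconstruction anchored to the two
  dependencies the source analysis states (gene count per variant,
  pathways per gene). Variants whose genes touch no enriched term are
  imputed with the mean profile of annotated variants; variants with no
  mapped genes stay excluded.
* **Term clustering.** Average-linkage hierarchical clustering on
  1 − similarity, cut at k = 4; labels renumbered by sorted term id so the
  partition is order-independent.
* **Determinism.** One master seed; stages use fixed offsets, and the IED
  sampler derives a per-variant substream from (seed, CRC32 of the
  variant id) so adding a variant never perturbs another's draws.

## The synthetic cohort generator

No cohort data are distributed with the source study, so the generator
emulates its design and is the package's test bed: 343 cases / 2,905
controls; a 41-variant candidate panel with 3 rare (MAF < 1%) coding
variants that fall to the frequency filter; two APOE-like variants with
large effects on both traits; among the 38 analysable variants, 28 with a
true negative longevity effect, planted so the true groups are 17 AD / 11
Longevity / 10 Unex; a replication layer covering 34 of 38 variants with
6 strongly significant loci; annotation resources with 4 recoverable
functional clusters and 5 brain cell types.

Genotypes are Hardy–Weinberg draws at the control MAF. Case status is
assigned in a latent pool of `6 × (n_cases + n_controls)` individuals by a
logistic model (`logit(0.15)` intercept, centred dosage effects, optional
PC confounding — zero by default), after which exactly the requested case
and control counts are subsampled. Case-control subsampling shifts only
the intercept of a logistic model, so the downstream dosage log-OR is
consistent for the planted effect — verified by the recovery suite (bias
< 0.05 across a grid of effects × MAFs at the study's sample sizes) and by
a 4,000-seed null calibration (z sd 0.995, 4.9% rejection at nominal 5%).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium between variants
(panel variants are independent), genotyping/imputation error and
missingness patterns, real population stratification (PCs are exogenous
standard normals), age/sex structure, relatedness, and the GO DAG
semantics behind the similarity matrix (planted blocks stand in for
semantic structure). Replication effects are planted by sign and
magnitude, not drawn from a joint genetic architecture.

In the annotation resources, each cluster owns a "core" of 8 genes; the
variant→gene map cycles deterministically through the core of the
variant's assigned cluster (guaranteeing coverage), the planted cluster
receives 6 extra variants (mirroring the over-represented
endocytosis/immune-signaling cluster), half of each cluster's terms are
core-rich (truly enriched) and half peripheral, and a null mode draws
terms and gene links uniformly for calibration. Two variants map only to
term-free genes to exercise imputation.

## Problem sizes

Pipeline defaults are the study constants (S = 10,000 IED samples,
B = 10,000 bootstraps, R = 1,000 enrichment iterations, FDR 5%,
MAF > 1%). The numbered analysis scripts use S = 2,000, B = 200 and
R = 200 — at these sizes the Monte-Carlo error on a median alpha is below
0.02 and the bootstrap SE is stable to a few percent, which is sufficient
for every decision the scripts report; the same trade-off governs the
simulation sizes in the test suite.

## Known limitations

* The within-group rank-sum comparison treats variants as independent
  observations; weights of variants sharing genes are correlated.
* The mean-combination of iteration p-values has no closed-form null;
  calls rest on the BH step applied to it, and calibration is
  demonstrated empirically (false-positive rate ≤ 0.08 at 0.05 under the
  null resource) rather than analytically.
* Group membership near the −1/2 and 0 cutoffs is unstable for variants
  with weak longevity effects at this sample size; on default synthetic
  runs the recovered group sizes scatter around the planted 17/11/10, as
  they would in a real cohort of this size.
* The imputation rule (annotated-column means) and the exact
  variant-pathway formula are reconstructions; alternatives would change
  per-variant weights but not the pipeline contracts.
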
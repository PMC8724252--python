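# adlongevity

Do alleles that raise the risk of Alzheimer's disease (AD) also lower the
odds of becoming a cognitively healthy centenarian — and by how much,
variant by variant? `adlongevity` implements a complete, reproducible
pipeline for that question, aimed at statistical geneticists working with
case-control cohorts of long-lived individuals: per-variant longevity
effect estimation with bootstrap uncertainty, the *imbalance of effect
direction* (IED) statistic and its sampling distribution, variant
grouping, exact binomial direction tests, replication concordance against
a parental-longevity GWAS, and functional/cell-type annotation scoring.
Because centenarian cohort data are rarely shareable, the package ships a
first-class synthetic-data module that emulates the full study design
(343 cases vs 2,905 controls, a 41-variant AD panel) so every stage runs
and is testable end to end.

## The statistic

Each variant k has two log odds ratios for its AD-risk-increasing allele:
`E_AD^k > 0` on AD (published summary statistics) and `E_LGV^k` on
longevity (logistic regression: centenarians vs population controls,
adjusted for PC1–5). Its imbalance is the normalized angle

    alpha_k = atan2(E_LGV^k, E_AD^k) / (pi/2)

with `alpha < 0` iff the direction is expected (risk allele lowers
longevity odds), `alpha = -1/2` when the effects mirror each other, and
`alpha = 0` when there is no longevity effect. Sampling S Gaussian effect
pairs per variant yields an IED distribution; the median groups variants
into a Longevity-group (median ≤ −1/2), AD-group (−1/2 < median ≤ 0) and
Unex-group (median > 0). Direction counts are tested with an exact
two-sided binomial at p₀ = 0.5; all multiple testing uses
Benjamini–Hochberg FDR at 5%. See `docs/methods.md` for the full model.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort and write their tables to `results/` (bulky per-sample
files go to `scratch/`):

```
python analysis/01_simulate_inputs.py
python analysis/02_fit_longevity_effects.py
python analysis/03_ied_grouping.py
python analysis/04_replication.py
python analysis/05_functional_annotation.py
```

Output of steps 02–05 (seed 2026):

```
analysed 38 variants after the frequency filter
29/38 longevity effects in the expected (negative) direction
FDR<5% associations: rs9100000, rs9100851

group sizes: {'Longevity': 17, 'AD': 12, 'Unex': 9}
direction test (all): 29/38 expected, binomial p = 0.0017
direction test (excluding_apoe): 27/36 expected, binomial p = 0.0039

replication records matched: 34 (missing: 4)
  expected: 20/26 concordant (77%), binomial p = 0.00936
  unexpected: 7/8 concordant (88%), binomial p = 0.0703
FDR<5% in the replication layer: rs9100000, rs9100037, rs9100185,
rs9100666, rs9100925, rs9100962

enriched terms (FDR<5%): 32/60
terms per functional cluster: {0: 8, 1: 8, 2: 8, 3: 8}
variants annotated directly: 36, imputed: 2
```

Reading this: of the 41 candidate variants, 3 are too rare (MAF ≤ 1%) and
38 are analysed. 29 risk alleles associate with *lower* odds of longevity
— far more than the 19 expected by chance (p = 0.0017) — and the two
strongest hits at FDR < 5% include the APOE-like variant
(`rs9100000`, log-OR −1.19). Direction agreement with the synthetic
parental-longevity layer is high for expected-direction variants (77%,
close to the generator's planted 81% concordance), and the six variants
planted as replication-significant are exactly the six recovered. The enrichment
stage finds the 32 truly core-rich gene-set terms, clusters them into the
four planted functional clusters, and imputes the two variants whose
genes carry no annotation.

The same pipeline runs from a single entry point (`adlong run-all
--seed 2026 --out-dir myrun`), stage by stage (`adlong assoc ...`), or on
your own files (VCF + phenotype TSV + summary-statistics TSVs + GMT) via
`--vcf/--pheno/--ad-summary/...` flags; `adlong validate` checks inputs
first.

## Layout

```
src/adlongevity/    stats_core, synthetic_data, longevity_assoc, ied,
                    replication, annotation, pipeline, cli
analysis/           numbered narrative drivers (01..05)
tests/              pytest suite incl. brute-force oracles & acceptance
docs/methods.md     model, assumptions, generator fidelity, limitations
```
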
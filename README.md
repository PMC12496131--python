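# acmgcalib

Gene-level calibration of variant functional scores into ACMG/AMP evidence
strengths.

## The problem

Multiplexed assays of variant effects (MAVEs) and computational variant
effect predictors produce continuous scores whose range and shape vary from
gene to gene, and which do not directly correspond to the graded evidence
levels (supporting / moderate / strong / very strong, pathogenic or benign)
that clinical variant classification under the ACMG/AMP guidelines
requires. `acmgcalib` converts such scores, together with a truthset of
variants labelled pathogenic (`P`) or benign (`B`), into positive
likelihood ratios (LR, the odds of pathogenicity) with confidence bounds,
assigns each variant an evidence strength under a chosen prior probability
of pathogenicity, and reports the score interval corresponding to each
evidence level.

It is aimed at clinical genetics researchers and assay developers who need
gene-specific (rather than genome-wide) calibration of functional evidence.

## Method

For a score *s* with class-conditional densities *f*(*s* | P) and
*f*(*s* | B), the evidence for pathogenicity is the likelihood ratio
LR(*s*) = *f*(*s* | P) / *f*(*s* | B).  The package estimates this ratio
non-parametrically and conservatively:

1. **Rescaling.** Scores are clamped to the labelled score range and mapped
   affinely onto [0, 1], making the pipeline scale- and shift-invariant and
   preventing extrapolation beyond the observed truthset.
2. **Bootstrapped KDE.** Each class is resampled with replacement 1000
   times; each resample gets a Gaussian-kernel density estimate (bandwidth
   by biased cross-validation, 1024 evaluation points) projected onto a
   common 1024-point grid.  Row *r* of the resulting 1000 × 1024 matrix is
   log *f̂ᵣ*(*g* | P) − log *f̂ᵣ*(*g* | B) over grid points *g*.
3. **Adaptive regularization.** With MADᵢ the per-column median absolute
   deviation, the weight
   λᵢ = (MADᵢ / maxⱼ MADⱼ) · √(Σⱼ (MADⱼ₊₁ − MADⱼ)²) / Σⱼ MADⱼ
   shrinks each column by 1/(1 + λᵢ) toward log LR = 0, damping unstable,
   sparsely supported regions while leaving stable regions untouched.
4. **Monotonization.** Each row is replaced by its least-squares monotone
   fit (isotonic regression); the direction is the sign of the Spearman
   correlation between column-mean log-LRs and score.
5. **Median and confidence bounds.** The final curve is the per-column
   median log-LR; 95% confidence bounds for the population median come from
   exact binomial order statistics (sign-test inversion).
6. **Evidence scale.** Given a prior π, the very-strong LR point X is the
   smallest LR satisfying at least 13 of the 14 ACMG/AMP P/LP combining-rule
   posterior criteria (posterior ≥ 0.99 for P rules, ≥ 0.90 for LP rules);
   lower levels are X^(1/2), X^(1/4), X^(1/8) and benign points are the
   reciprocals.  At π = 0.1, X = 350; at π = 0.0441, X = 1131.
7. **Classification and thresholds.** A variant reaches a pathogenic level
   only when the lower confidence bound of its LR clears the level's point
   (and the point estimate exceeds 1); benign levels use the upper bound.
   Score thresholds per level are the grid coordinates where the relevant
   bound curve crosses the level's point, interpolated in log-LR space.

## Worked example

```python
import acmgcalib as a

spec = a.SyntheticTruthsetSpec(
    benign_dist=a.DistributionSpec.gaussian(0.3, 0.15),
    pathogenic_dist=a.DistributionSpec.gaussian(0.7, 0.15),
    n_benign=50, n_pathogenic=50, n_unlabelled=20, seed=5)
table = a.generate_truthset(spec).table

res = a.calibrate(table, value="score", prior=0.1, n_resamples=200, seed=7)
print(res.likelihood_ratios.head(5).round(4).to_string())
print(res.score_thresholds.round(4).to_string(index=False))
```

```
    score class  score_lr_lower      score_lr  score_lr_upper          score_evidence
0  0.8443     P    6.833650e+09  7.195799e+09    7.541341e+09  pathogenic_very_strong
1  0.5228     P    3.121800e+00  3.271600e+00    3.475200e+00   pathogenic_supporting
2  0.8107     P    6.833650e+09  7.195799e+09    7.541341e+09  pathogenic_very_strong
3  0.5352     P    3.749300e+00  3.972400e+00    4.243400e+00   pathogenic_supporting
4  0.6503     P    3.121640e+01  3.664040e+01    4.430810e+01       pathogenic_strong

                 level  score_lower  score_upper
pathogenic_very_strong       0.7252       1.0648
     pathogenic_strong       0.6295       0.7252
   pathogenic_moderate       0.5461       0.6295
 pathogenic_supporting       0.4969       0.5461
         indeterminate       0.4209       0.4969
     benign_supporting       0.3922       0.4209
       benign_moderate       0.3427       0.3922
         benign_strong       0.2558       0.3427
    benign_very_strong       0.0003       0.2558
```

Each variant's row carries its LR point estimate with 95% bounds and the
assigned evidence label: the variant at score 0.6503 has LR 36.6
(31.2–44.3), and because the lower bound 31.2 exceeds the strong point
18.71 (= 350^(1/2)) it is classified `pathogenic_strong`.  The thresholds
table reads, e.g., that under this calibration any score above 0.7252 is
very-strong pathogenic evidence and any score below 0.2558 is very-strong
benign evidence.  Unlabelled variants (empty class) receive LRs and labels
too.  A grouping column (e.g. `group="gene"`) calibrates each gene
independently.

The same pipeline is available from the shell:

```sh
acmg-calibrate --input variants.csv --score-col score --out-dir results/
```

writing `likelihood_ratios.csv`, `score_thresholds.csv` and
`metadata.json` (per group, when `--group-col` is given).

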
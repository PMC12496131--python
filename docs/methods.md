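# Methods

This note records the statistical model behind `acmgcalib`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Model and assumptions

The package estimates, for a continuous functional score *s*, the positive
likelihood ratio LR(*s*) = *f*(*s* | pathogenic) / *f*(*s* | benign) from a
labelled truthset, and translates it into ACMG/AMP evidence strengths under
a prior probability of pathogenicity π.  The underlying assumptions are:

- the truthset labels are correct and the labelled variants are draws from
  the same class-conditional score distributions as the variants to be
  classified;
- evidence strength is monotone in score: once the direction of the
  score–pathogenicity relationship is fixed, a more extreme score cannot
  carry weaker evidence.  Non-monotonicity in the raw density ratio is
  treated as estimation noise (or assay artefact) and removed by isotonic
  regression;
- a minimum of 10 pathogenic and 10 benign labelled variants.  Below this
  the bootstrap densities become too unstable for the confidence bounds to
  mean much; the Monte-Carlo cross-validation harness
  (`mc_cross_validation`) exists precisely to probe behaviour at this
  minimum.

## Pipeline parameters

| parameter | default | units | notes |
|---|---|---|---|
| `prior` | 0.1 | probability | prior probability of pathogenicity; the only scientific tunable. 0.0441 is a common alternative |
| `n_resamples` | 1000 | – | bootstrap resamples per class |
| `grid_size` | 1024 | – | evaluation points of each KDE and of the common [0, 1] grid |
| `selector` | `bcv` | – | bandwidth selector; biased cross-validation gives the narrowest LR confidence intervals of the four classic selectors and is the default. `nrd0`, `sj`, `ucv` are provided for the comparison harness |
| `ci_level` | 0.95 | probability | coverage of the sign-test median interval |
| `seed` | 1234 | – | root seed; per-resample substreams are spawned from it so results do not depend on evaluation order |
| `density_floor` | 1e-10 | density | floor applied to projected densities before logs |
| `kde_cut` | 3 | bandwidths | each KDE grid spans [min − 3h, max + 3h] |

Derived, not tunable: the very-strong LR point X(π) from the combining-rule
search; lower levels X^(1/2), X^(1/4), X^(1/8); benign points reciprocal.

## The combining-rule search

The 14 Pathogenic / Likely Pathogenic combining rules are enumerated at
their minimal satisfying combinations, with evidence weights supporting =
1/8, moderate = 1/4, strong = 1/2, very strong = 1, so a rule's combined
LR is X raised to the sum of its weights.  P rules must reach posterior
0.99, LP rules 0.90.  Two rules are mutually inconsistent at any single X
(the two-strong rule P_ii demands a much larger X than the rest; the
very-strong-plus-moderate rule LP_i a much smaller one), so X is defined
as the smallest value satisfying at least 13 of 14 criteria — in practice
the second-largest of the per-rule closed-form requirements, which the
implementation finds by bisection (relative tolerance 1e-12) and verifies
against the closed form in tests.  LP criteria are lower-bound-only; no
upper posterior cap is imposed on them, and the Likely Benign / Benign
rules are not enforced separately (satisfying the P/LP criteria maintains
the same prior–threshold relationship).  The continuous solution is
reported at integer resolution by flooring; at π = 0.1 the continuous
solution is ≈ 350.47 → 350, at π = 0.0441 it is ≈ 1131.4 → 1131.
Round-to-nearest gives the same integers at both anchors; flooring is the
default and the convention is exposed as an argument
(`rounding="floor" | "nearest" | "none"`).

## Numerical choices

- **Regularization form.** The adaptive weight λᵢ is computed from the
  per-column MAD profile of the raw (pre-isotonic) log-LR matrix and
  applied as column-wise multiplicative shrinkage 1/(1 + λᵢ).  This form
  was chosen because it shrinks toward LR = 1 (no evidence), is exactly the
  identity at λ = 0, and is bounded and sign-preserving.  λ is invariant to
  the MAD normalisation constant (1.4826 is used; tested).
- **Isotonic regression per row.** Monotonicity is enforced on every
  bootstrap row rather than once on the summary curve; medians and order
  statistics of monotone rows are automatically monotone, which the
  summary step asserts rather than assumes.
- **Bandwidth per resample.** The bandwidth is re-selected for each class
  in each resample (switchable to once-per-class via
  `reselect_bandwidth=False` for speed).  A resample that collapses to
  zero spread is redrawn from the same substream; more than 1% redraws
  aborts the run.
- **bcv search box** [0.1·h_max, h_max] with h_max = 1.144·sd·n^(−1/5);
  the optimizer tolerance is 1e-3 of the lower edge so the minimizer
  matches a dense-grid scan of the objective to three significant figures.
  The Sheather–Jones pilot bandwidths use the constants 1.24/1.23 on the
  robust scale min(sd, IQR/1.349) (equivalently 0.920/0.912 on the raw
  IQR).
- **Density floor.** Projected densities are floored at 1e-10 before logs,
  capping |log-LR| at roughly 23 + log f̂ of the supported class where the
  other class has no support.  Without it, grid regions outside one
  class's span would produce infinities.
- **Nearest-index mapping.** Variants are mapped to the curve by nearest
  common-grid index (ties toward the lower index); threshold crossings, in
  contrast, are interpolated linearly in log-LR space between bracketing
  nodes.  The two conventions can disagree by at most half a grid cell
  (≈ 0.05% of the score range at the default grid), which the consistency
  test accounts for.
- **Plateau crossings.** If a bound curve equals a likelihood point exactly
  over several nodes, the crossing is placed at the plateau node nearest
  the stronger-evidence side, keeping the stronger-evidence score region
  as small as possible (conservative).  At a single-node equality the node
  coordinate is taken.
- **Ties and degenerate input.** Labels are case-sensitive 'P'/'B'
  (lowercase triggers a warning and is treated as unlabelled); an exactly
  zero Spearman correlation raises instead of guessing a direction; a
  truthset with zero labelled score range is rejected.

## Synthetic data: what it emulates, what it does not

`synthetic_fixtures` draws class-conditional scores from Gaussian,
Gaussian-mixture or skew-normal families, chosen to mimic the qualitative
variety of MAVE/predictor score distributions: varying overlap, modality,
skew, direction and sample size.  Because the generating densities are
known, the analytic log density ratio is available as an oracle, which no
real truthset offers.

What it does not emulate: truthset label errors and circularity (real
labels are partly informed by the very scores being calibrated), ascertainment
bias in which variants get clinical labels, heavy-tailed or discretised
score distributions, and gene-to-gene heterogeneity of priors.  A passing
recovery test therefore demonstrates the estimator's correctness under its
own assumptions, not the clinical validity of any particular calibration.

Default study conditions used by the tests: parameter recovery uses two
Gaussians with means 0.35/0.65 and sd 0.15 (2-sd separation, substantial
overlap) at 200 labelled variants per class and 200 resamples; the
recovery tolerance of 0.5 on the log-LR at interior grid points (analytic
|log-LR| ≤ 2) absorbs the kernel-smoothing bias, which flattens the
log-ratio slope by a factor σ²/(σ² + h²).  The cross-validation harness
uses well-separated Gaussians (means 0.25/0.75, sd 0.12), pools of 60 + 60,
50 trials at 100 resamples — reduced from the full-scale 2000 trials and
1000 resamples, which remain available through the configuration.  Widely
separated classes (e.g. 8 sd apart) place most of the grid outside one
class's support, where the density floor caps the log-LR; recovery of the
analytic ratio is only meaningful where both classes have mass, and the
tests evaluate it there.

## Known limitations

- LR confidence bounds describe uncertainty in the median LR across
  bootstrap resamples, not uncertainty in the posterior probability of
  pathogenicity; posterior reporting is deliberately out of scope.
- The multiplicative shrinkage form of the λ regularization is one of
  several defensible readings of "adaptive regularization"; it is isolated
  behind `shrink_loglr` so an alternative can be swapped in without
  touching the rest of the pipeline.
- Evidence bins with zero held-out benign variants in the cross-validation
  harness yield an undefined (infinite) observed LR and are flagged, not
  continuity-corrected.
- A single global prior per invocation; per-group priors are not
  supported.
- Scores far outside the labelled range are clamped to its edge and
  therefore inherit the edge's evidence level; the package never
  extrapolates beyond observed labels.
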
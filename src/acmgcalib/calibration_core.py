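"""Bootstrapped log likelihood-ratio estimation on a common unit grid.

The pipeline, in execution order: clamp and rescale scores to [0, 1] using
the labelled score range; resample the pathogenic and benign reference
distributions with replacement; estimate each class density with a Gaussian
kernel (bandwidth selected per class per resample); project both densities
onto a common 1024-point grid; take the difference of log densities to get
one log-LR row per resample; regularize columns with an adaptive shrinkage
weight driven by the per-column median absolute deviation; enforce
monotonicity per row with isotonic regression; and summarize with the
per-column median plus distribution-free confidence bounds for the median
obtained by inverting the sign test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binom, spearmanr
from sklearn.isotonic import isotonic_regression

from .density_engine import (
    DegenerateSampleError,
    kde_on_own_grid,
    project_to_common_grid,
    select_bandwidth,
)

__all__ = [
    "TruthsetScores",
    "CalibrationConfig",
    "LogLRMatrix",
    "CalibrationCurve",
    "clamp_and_rescale",
    "compute_loglr_matrix",
    "mad_profile",
    "adaptive_lambda",
    "shrink_loglr",
    "direction_of_monotonicity",
    "monotonize",
    "sign_test_ci_ranks",
    "summarize_curve",
    "map_to_scores",
]

logger = logging.getLogger(__name__)

#: Normal-consistency constant for the MAD.  The adaptive shrinkage weight
#: is provably invariant to this choice (it cancels between the two factors).
MAD_SCALE = 1.4826

#: Minimum number of labelled variants per class.
MIN_CLASS_SIZE = 10

PATHOGENIC_LABEL = "P"
BENIGN_LABEL = "B"


@dataclass
class TruthsetScores:
    """Per-variant scores and truthset labels.

    ``labels`` holds 'P', 'B' or anything else (treated as unlabelled;
    unlabelled variants are still scored downstream).  Scores stay in their
    original units here; rescaling happens inside the pipeline.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        self.labels = np.asarray(self.labels, dtype=object).ravel()
        if self.scores.size != self.labels.size:
            raise ValueError("scores and labels must have equal length")

    @property
    def pathogenic_scores(self) -> np.ndarray:
        return self.scores[self.labels == PATHOGENIC_LABEL]

    @property
    def benign_scores(self) -> np.ndarray:
        return self.scores[self.labels == BENIGN_LABEL]

    @property
    def labelled_scores(self) -> np.ndarray:
        return np.concatenate([self.pathogenic_scores, self.benign_scores])

    def labelled_range(self) -> tuple[float, float]:
        labelled = self.labelled_scores
        return float(np.min(labelled)), float(np.max(labelled))

    def check(self) -> None:
        """Enforce the truthset invariants (>=10 per class, non-zero range)."""
        n_p = self.pathogenic_scores.size
        n_b = self.benign_scores.size
        if n_p < MIN_CLASS_SIZE:
            raise ValueError(f"pathogenic labels: {n_p} < {MIN_CLASS_SIZE}")
        if n_b < MIN_CLASS_SIZE:
            raise ValueError(f"benign labels: {n_b} < {MIN_CLASS_SIZE}")
        labelled = self.labelled_scores
        if not np.all(np.isfinite(labelled)):
            raise ValueError("labelled scores must be finite")
        lmin, lmax = self.labelled_range()
        if not lmax > lmin:
            raise ValueError("labelled scores span a zero range")


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunables of the bootstrap calibration pipeline.

    ``seed`` is fixed by default so repeated runs are bit-identical.
    ``reselect_bandwidth`` re-runs bandwidth selection on every resample
    (the default); switching it off selects once per class, for speed.
    ``density_floor`` bounds projected densities away from zero before logs
    are taken, capping the attainable |log-LR| where one class has no
    support.
    """

    n_resamples: int = 1000
    grid_size: int = 1024
    selector: str = "bcv"
    ci_level: float = 0.95
    seed: int = 1234
    prior: float = 0.1
    density_floor: float = 1e-10
    kde_cut: float = 3.0
    reselect_bandwidth: bool = True
    max_redraw_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be at least 2")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie in (0, 1)")
        if self.density_floor <= 0:
            raise ValueError("density_floor must be positive")

    def with_overrides(self, **kwargs) -> "CalibrationConfig":
        return replace(self, **kwargs)


@dataclass
class LogLRMatrix:
    """Resamples x grid-points matrix of log likelihood ratios.

    Row r, column i holds the log-LR of bootstrap resample r at common-grid
    index i; the common grid is ``grid_size`` equidistant points on [0, 1].
    """

    values: np.ndarray
    common_grid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.common_grid = np.asarray(self.common_grid, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[1] != self.common_grid.size:
            raise ValueError("column count must match the common grid length")


@dataclass
class CalibrationCurve:
    """Median log-LR with lower/upper confidence bounds, all monotone."""

    median_loglr: np.ndarray
    lower_loglr: np.ndarray
    upper_loglr: np.ndarray
    direction: int
    common_grid: np.ndarray


def clamp_and_rescale(scores, labelled_min: float, labelled_max: float) -> np.ndarray:
    """Clip scores into the labelled range, then map affinely onto [0, 1].

    Clamping prevents extrapolation of LRs beyond the observed labelled
    range; the rescale makes the pipeline scale-invariant.  NaNs pass
    through unchanged.
    """
    if not labelled_max > labelled_min:
        raise ValueError("labelled score range is degenerate (max <= min)")
    x = np.asarray(scores, dtype=float)
    return (np.clip(x, labelled_min, labelled_max) - labelled_min) / (
        labelled_max - labelled_min
    )


def _resample_density(rng, pool, config: CalibrationConfig, fixed_h, grid):
    """One bootstrap resample of one class, projected onto the common grid."""
    sample = pool[rng.integers(0, pool.size, pool.size)]
    h = fixed_h if fixed_h is not None else select_bandwidth(sample, config.selector)
    d = kde_on_own_grid(sample, h, n_points=config.grid_size, cut=config.kde_cut)
    return project_to_common_grid(d, grid)


def compute_loglr_matrix(truthset: TruthsetScores, config: CalibrationConfig) -> LogLRMatrix:
    """Bootstrap the class densities and form the log-LR matrix.

    Each resample draws |P| pathogenic and |B| benign rescaled labelled
    scores with replacement from a seeded stream, estimates both class
    densities, projects them to the common [0, 1] grid, floors them at
    ``config.density_floor`` and takes the difference of logs.  A resample
    whose bandwidth selection fails (zero spread after resampling) is
    redrawn from the same substream; more than ``max_redraw_fraction`` of
    redraws aborts the run.  Deterministic for a fixed seed.
    """
    truthset.check()
    lmin, lmax = truthset.labelled_range()
    p = clamp_and_rescale(truthset.pathogenic_scores, lmin, lmax)
    b = clamp_and_rescale(truthset.benign_scores, lmin, lmax)
    grid = np.linspace(0.0, 1.0, config.grid_size)

    fixed_hp = fixed_hb = None
    if not config.reselect_bandwidth:
        fixed_hp = select_bandwidth(p, config.selector)
        fixed_hb = select_bandwidth(b, config.selector)

    values = np.empty((config.n_resamples, config.grid_size))
    max_redraws = max(1, int(config.max_redraw_fraction * config.n_resamples))
    redraws = 0
    children = np.random.SeedSequence(config.seed).spawn(config.n_resamples)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        while True:
            try:
                fp = _resample_density(rng, p, config, fixed_hp, grid)
                fb = _resample_density(rng, b, config, fixed_hb, grid)
            except DegenerateSampleError:
                redraws += 1
                logger.warning("degenerate resample %d redrawn (%d redraws so far)", r, redraws)
                if redraws > max_redraws:
                    raise RuntimeError(
                        f"more than {config.max_redraw_fraction:.0%} of resamples were "
                        "degenerate; the truthset is too sparse to calibrate"
                    ) from None
                continue
            break
        np.maximum(fp, config.density_floor, out=fp)
        np.maximum(fb, config.density_floor, out=fb)
        values[r] = np.log(fp) - np.log(fb)
    return LogLRMatrix(values=values, common_grid=grid)


def mad_profile(m: LogLRMatrix, scale: float = MAD_SCALE) -> np.ndarray:
    """Per-column median absolute deviation of the log-LRs."""
    med = np.median(m.values, axis=0)
    return scale * np.median(np.abs(m.values - med), axis=0)


def adaptive_lambda(mads) -> np.ndarray:
    """Adaptive regularization weights from the MAD profile.

    lambda_i = (MAD_i / max_j MAD_j) * sqrt(sum_j (MAD_{j+1} - MAD_j)^2) / sum_j MAD_j

    The first factor localizes the penalty to high-variability columns; the
    second is a global roughness measure over lagged differences.  Both
    factors are invariant to a uniform rescaling of the MADs, so the MAD
    scale constant is immaterial.  An all-zero profile yields all-zero
    weights.
    """
    mads = np.asarray(mads, dtype=float)
    if mads.size < 2:
        raise ValueError("need at least 2 MAD entries")
    if np.any(mads < 0):
        raise ValueError("MAD values must be non-negative")
    top = mads.max()
    if top == 0:
        return np.zeros_like(mads)
    roughness = math.sqrt(float(np.sum(np.diff(mads) ** 2))) / float(mads.sum())
    return (mads / top) * roughness


def shrink_loglr(m: LogLRMatrix, lambdas) -> LogLRMatrix:
    """Shrink each column toward log-LR = 0 by the factor 1/(1 + lambda_i).

    The identity where lambda is zero; sign-preserving and bounded
    elsewhere, so regularized estimates move toward LR = 1 (no evidence).
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size != m.values.shape[1]:
        raise ValueError("lambda vector length must equal grid_size")
    if np.any(lam < 0):
        raise ValueError("lambda weights must be non-negative")
    return LogLRMatrix(values=m.values / (1.0 + lam), common_grid=m.common_grid)


def direction_of_monotonicity(m: LogLRMatrix) -> int:
    """Sign of the Spearman correlation of column-mean log-LRs with score.

    +1 means higher (rescaled) scores carry higher log-LRs.  The common
    grid stands in for the scores: the score-to-grid mapping is monotone,
    so the rank correlation sign is identical.
    """
    col_means = m.values.mean(axis=0)
    if np.allclose(col_means, col_means[0]):
        raise ValueError(
            "column means of the log-LR matrix are constant; the direction of "
            "monotonicity is undefined - inspect the input data"
        )
    rho = spearmanr(col_means, m.common_grid).statistic
    if not np.isfinite(rho) or rho == 0:
        raise ValueError(
            "Spearman correlation between log-LRs and scores is exactly zero; "
            "the direction of monotonicity is undefined - inspect the input data"
        )
    return 1 if rho > 0 else -1


def monotonize(m: LogLRMatrix, direction: int) -> LogLRMatrix:
    """Replace each row by its least-squares monotone fit (PAVA).

    Rows are treated independently with uniform weights; rows already
    monotone in the requested direction are unchanged.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    out = np.empty_like(m.values)
    increasing = direction == 1
    for r in range(m.values.shape[0]):
        out[r] = isotonic_regression(m.values[r], increasing=increasing)
    return LogLRMatrix(values=out, common_grid=m.common_grid)


def sign_test_ci_ranks(n: int, level: float = 0.95) -> tuple[int, int]:
    """Order-statistic ranks of a distribution-free CI for the median.

    Inverts the sign test with the exact Binomial(n, 1/2) distribution:
    ``lo_rank`` is the largest k with P(X <= k-1) <= (1-level)/2 and
    ``hi_rank = n + 1 - lo_rank``, guaranteeing coverage >= level.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    alpha = (1.0 - level) / 2.0
    # cdf[k-1] = P(X <= k-1) for k = 1..n
    cdf = binom.cdf(np.arange(n), n, 0.5)
    ok = np.nonzero(cdf <= alpha)[0]
    if ok.size == 0:
        raise ValueError(
            f"n={n} is too small for a two-sided {level:.0%} sign-test interval"
        )
    lo_rank = int(ok[-1]) + 1
    return lo_rank, n + 1 - lo_rank


def _assert_monotone(v: np.ndarray, direction: int, what: str) -> None:
    d = np.diff(v) * direction
    if np.any(d < -1e-9):
        raise AssertionError(f"{what} curve is not monotone in direction {direction:+d}")


def summarize_curve(m: LogLRMatrix, config: CalibrationConfig, direction: int) -> CalibrationCurve:
    """Median log-LR per column with sign-test confidence bounds.

    The bounds are the order statistics of each sorted column at the ranks
    from :func:`sign_test_ci_ranks`.  Because every row is monotone, order
    statistics are taken over monotone curves and the median and both
    bounds inherit monotonicity; this is asserted, not assumed.
    """
    n = m.values.shape[0]
    lo_rank, hi_rank = sign_test_ci_ranks(n, config.ci_level)
    sorted_cols = np.sort(m.values, axis=0)
    lower = sorted_cols[lo_rank - 1]
    upper = sorted_cols[hi_rank - 1]
    median = np.median(m.values, axis=0)
    for what, v in (("median", median), ("lower", lower), ("upper", upper)):
        _assert_monotone(v, direction, what)
    if np.any(lower > median) or np.any(median > upper):
        raise AssertionError("confidence bounds do not bracket the median")
    return CalibrationCurve(
        median_loglr=median,
        lower_loglr=lower,
        upper_loglr=upper,
        direction=direction,
        common_grid=m.common_grid,
    )


def map_to_scores(curve: CalibrationCurve, rescaled_scores) -> np.ndarray:
    """Per-variant (lr_lower, lr, lr_upper) triples from the curve.

    Each rescaled score is assigned its nearest common-grid index (ties
    resolved toward the lower index) and the triple is the exponentiated
    (lower, median, upper) log-LR there.  NaN scores yield NaN triples;
    finite scores outside [0, 1] are an upstream clamping bug and raise.
    """
    s = np.asarray(rescaled_scores, dtype=float)
    finite = np.isfinite(s)
    if np.any((s[finite] < 0) | (s[finite] > 1)):
        raise ValueError("rescaled scores must lie in [0, 1]; clamp upstream")
    n_grid = curve.common_grid.size
    pos = s[finite] * (n_grid - 1)
    idx = np.floor(pos + 0.5)
    tie = (pos % 1.0) == 0.5
    idx[tie] = np.floor(pos[tie])
    idx = idx.astype(int)
    out = np.full((s.size, 3), np.nan)
    out[finite, 0] = np.exp(curve.lower_loglr[idx])
    out[finite, 1] = np.exp(curve.median_loglr[idx])
    out[finite, 2] = np.exp(curve.upper_loglr[idx])
    return out
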
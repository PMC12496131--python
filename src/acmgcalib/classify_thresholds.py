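"""Evidence labels and per-level score thresholds from a calibrated curve.

Classification is deliberately conservative: a variant reaches a
pathogenic level only when the *lower* confidence bound of its LR clears
the level's likelihood point (point estimate above one), and a benign
level only when the *upper* bound drops below it (point estimate below
one).  Score thresholds per evidence level are the grid coordinates where
the relevant bound curve crosses the level's likelihood point, linearly
interpolated in log-LR space on the common grid and mapped back to
original score units.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .calibration_core import CalibrationCurve
from .evidence_model import EvidenceScale

__all__ = [
    "EVIDENCE_LEVELS",
    "INDETERMINATE",
    "assign_evidence",
    "score_thresholds",
]

INDETERMINATE = "indeterminate"

#: All assignable labels, strongest pathogenic first.
EVIDENCE_LEVELS = (
    "pathogenic_very_strong",
    "pathogenic_strong",
    "pathogenic_moderate",
    "pathogenic_supporting",
    INDETERMINATE,
    "benign_supporting",
    "benign_moderate",
    "benign_strong",
    "benign_very_strong",
)


def assign_evidence(lr_lower: float, lr: float, lr_upper: float, scale: EvidenceScale) -> str:
    """Evidence label for one variant from its LR triple.

    If the point estimate exceeds one, the strongest pathogenic level whose
    likelihood point is reached by ``lr_lower`` is assigned; if it falls
    below one, the strongest benign level reached by ``lr_upper``.  A triple
    reaching no level, or a point estimate of exactly one, is indeterminate.
    """
    for v in (lr_lower, lr, lr_upper):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"LR values must be finite and positive; got {v!r}")
    if not (lr_lower <= lr <= lr_upper):
        raise ValueError("LR triple must satisfy lower <= point <= upper")
    if lr > 1.0:
        for level, point in scale.pathogenic_points():
            if lr_lower >= point:
                return level
    elif lr < 1.0:
        for level, point in scale.benign_points():
            if lr_upper <= point:
                return level
    return INDETERMINATE


def _cross_toward_high(y: np.ndarray, g: np.ndarray, target: float):
    """First upward crossing of ``target`` on a non-decreasing curve.

    Returns the interpolated grid coordinate, or None when the curve never
    reaches the target.  A plateau exactly at the target resolves to its
    last node (the end nearest the stronger-evidence side), keeping the
    attributed stronger-evidence region as small as possible.
    """
    reached = np.nonzero(y >= target)[0]
    if reached.size == 0:
        return None
    i = int(reached[0])
    if y[i] == target:
        j = i
        while j + 1 < y.size and y[j + 1] == target:
            j += 1
        return float(g[j])
    if i == 0:
        return float(g[0])
    frac = (target - y[i - 1]) / (y[i] - y[i - 1])
    return float(g[i - 1] + frac * (g[i] - g[i - 1]))


def _cross_toward_low(y: np.ndarray, g: np.ndarray, target: float):
    """Last point where a non-decreasing curve is still at or below ``target``.

    Mirror image of :func:`_cross_toward_high` for the benign side; a
    plateau resolves to its first node (the stronger-benign end).
    """
    reached = np.nonzero(y <= target)[0]
    if reached.size == 0:
        return None
    i = int(reached[-1])
    if y[i] == target:
        j = i
        while j - 1 >= 0 and y[j - 1] == target:
            j -= 1
        return float(g[j])
    if i == y.size - 1:
        return float(g[-1])
    frac = (target - y[i]) / (y[i + 1] - y[i])
    return float(g[i] + frac * (g[i + 1] - g[i]))


def score_thresholds(
    curve: CalibrationCurve,
    scale: EvidenceScale,
    labelled_min: float,
    labelled_max: float,
) -> pd.DataFrame:
    """Score intervals per evidence level, in original score units.

    For each pathogenic level the lower confidence-bound curve is
    intersected with the level's likelihood point; for each benign level,
    the upper bound curve.  Interpolation is linear in log-LR space on the
    common-grid coordinates, which are then mapped back to score units via
    ``g * (labelled_max - labelled_min) + labelled_min``.  Levels whose
    bound curve never reaches the point are omitted.  The returned table
    has columns ``level``, ``score_lower``, ``score_upper``, ordered from
    pathogenic very strong down to benign very strong, and the intervals
    tile the labelled score range without overlap.
    """
    if not labelled_max > labelled_min:
        raise ValueError("labelled score range is degenerate (max <= min)")
    if curve.direction not in (1, -1):
        raise ValueError("curve direction must be +1 or -1")
    for name in ("lower_loglr", "upper_loglr"):
        v = getattr(curve, name)
        if np.any(np.diff(v) * curve.direction < -1e-9):
            raise ValueError("calibration curve is not monotone; cannot derive thresholds")

    g = curve.common_grid
    lower = curve.lower_loglr
    upper = curve.upper_loglr
    flipped = curve.direction == -1
    if flipped:
        # orient so evidence for pathogenicity increases with the grid
        g_oriented = g  # grid coordinates stay abstract; flip the curves
        lower = lower[::-1]
        upper = upper[::-1]
    else:
        g_oriented = g

    path_cross = {
        level: _cross_toward_high(lower, g_oriented, math.log(point))
        for level, point in scale.pathogenic_points()
    }
    benign_cross = {
        level: _cross_toward_low(upper, g_oriented, math.log(point))
        for level, point in scale.benign_points()
    }

    # assemble oriented intervals; stronger benign sits at low coordinates
    intervals: dict[str, tuple[float, float]] = {}
    start = 0.0
    # benign: walk strongest -> weakest
    for level, _ in scale.benign_points():
        c = benign_cross[level]
        if c is not None:
            intervals[level] = (start, c)
            start = c
    indeterminate_start = start
    end = 1.0
    # pathogenic: walk strongest -> weakest so each interval ends at the
    # next stronger level's crossing
    for level, _ in scale.pathogenic_points():
        c = path_cross[level]
        if c is not None:
            intervals[level] = (c, end)
            end = c
    intervals[INDETERMINATE] = (indeterminate_start, end)

    def to_scores(a: float, b: float) -> tuple[float, float]:
        if flipped:
            a, b = 1.0 - b, 1.0 - a
        span = labelled_max - labelled_min
        return labelled_min + a * span, labelled_min + b * span

    rows = []
    for level in EVIDENCE_LEVELS:
        if level not in intervals:
            continue
        lo, hi = to_scores(*intervals[level])
        rows.append({"level": level, "score_lower": lo, "score_upper": hi})
    return pd.DataFrame(rows, columns=["level", "score_lower", "score_upper"])
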
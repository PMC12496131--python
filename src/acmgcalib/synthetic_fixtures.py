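"""Synthetic truthsets with controlled structure, plus evaluation harnesses.

Real calibration studies draw truthsets from clinical databases; this
module emulates them with class-conditional score distributions of known
analytic form (Gaussian, Gaussian mixture, or skew-normal), so recovery of
the log density ratio can be checked against a closed form.  It also
implements the two evaluation harnesses used to stress the method: a
Monte-Carlo cross-validation of the minimum truthset size (calibrate on 10
variants per class, score the held-out rest, compare observed to assigned
evidence), and a bandwidth-selector comparison by mean confidence-interval
width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, skewnorm

from .calibration_core import CalibrationConfig
from .classify_thresholds import EVIDENCE_LEVELS
from .io_cli import calibrate

__all__ = [
    "DistributionSpec",
    "SyntheticTruthsetSpec",
    "SyntheticTruthset",
    "generate_truthset",
    "observed_lr",
    "mc_cross_validation",
    "selector_ci_width",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistributionSpec:
    """A class-conditional score distribution.

    Families: ``gaussian`` (mean, sd), ``gaussian-mixture``
    (weights, means, sds), ``skewed`` (skew-normal: loc, scale, alpha).
    """

    family: str
    params: dict = field(default_factory=dict)

    @classmethod
    def gaussian(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("gaussian", {"mean": mean, "sd": sd})

    @classmethod
    def mixture(cls, weights, means, sds) -> "DistributionSpec":
        w = np.asarray(weights, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        return cls(
            "gaussian-mixture",
            {"weights": tuple(weights), "means": tuple(means), "sds": tuple(sds)},
        )

    @classmethod
    def skewed(cls, loc: float, scale: float, alpha: float) -> "DistributionSpec":
        return cls("skewed", {"loc": loc, "scale": scale, "alpha": alpha})

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "gaussian":
            return norm.pdf(x, loc=p["mean"], scale=p["sd"])
        if self.family == "gaussian-mixture":
            out = np.zeros_like(x)
            for w, mu, sd in zip(p["weights"], p["means"], p["sds"]):
                out += w * norm.pdf(x, loc=mu, scale=sd)
            return out
        if self.family == "skewed":
            return skewnorm.pdf(x, p["alpha"], loc=p["loc"], scale=p["scale"])
        raise ValueError(f"unknown distribution family {self.family!r}")

    def rvs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "gaussian":
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.family == "gaussian-mixture":
            comp = rng.choice(len(p["weights"]), size=n, p=np.asarray(p["weights"]))
            means = np.asarray(p["means"])[comp]
            sds = np.asarray(p["sds"])[comp]
            return rng.normal(means, sds)
        if self.family == "skewed":
            return skewnorm.rvs(
                p["alpha"], loc=p["loc"], scale=p["scale"], size=n, random_state=rng
            )
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class SyntheticTruthsetSpec:
    """Recipe for a labelled truthset with known class densities.

    ``direction=+1`` means higher scores indicate pathogenicity; ``-1``
    mirrors the score axis.  Unlabelled variants are drawn from an even
    mixture of the two classes.
    """

    benign_dist: DistributionSpec
    pathogenic_dist: DistributionSpec
    n_benign: int = 10
    n_pathogenic: int = 10
    n_unlabelled: int = 0
    direction: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_benign, self.n_pathogenic, self.n_unlabelled) < 0:
            raise ValueError("counts must be non-negative")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class SyntheticTruthset:
    """A generated truthset together with its analytic log density ratio."""

    table: pd.DataFrame
    spec: SyntheticTruthsetSpec

    def log_density_ratio(self, scores) -> np.ndarray:
        """Analytic log(f_pathogenic / f_benign) on the stored score axis."""
        x = np.asarray(scores, dtype=float) * self.spec.direction
        return np.log(self.spec.pathogenic_dist.pdf(x)) - np.log(
            self.spec.benign_dist.pdf(x)
        )


def generate_truthset(spec: SyntheticTruthsetSpec) -> SyntheticTruthset:
    """Draw a labelled (and optionally unlabelled) truthset table.

    Deterministic per seed.  The table has columns ``score`` and ``class``
    ('P', 'B', or '' for unlabelled); unlabelled scores come from an even
    mixture of the two class distributions.
    """
    rng = np.random.default_rng(spec.seed)
    b = spec.benign_dist.rvs(rng, spec.n_benign)
    p = spec.pathogenic_dist.rvs(rng, spec.n_pathogenic)
    n_u = spec.n_unlabelled
    from_p = rng.random(n_u) < 0.5
    u = np.where(
        from_p,
        spec.pathogenic_dist.rvs(rng, n_u),
        spec.benign_dist.rvs(rng, n_u),
    )
    scores = np.concatenate([p, b, u]) * spec.direction
    labels = ["P"] * spec.n_pathogenic + ["B"] * spec.n_benign + [""] * n_u
    table = pd.DataFrame({"score": scores, "class": labels})
    return SyntheticTruthset(table=table, spec=spec)


def observed_lr(
    heldout_p_in_bin: int,
    heldout_b_in_bin: int,
    background_p: int,
    background_b: int,
) -> tuple[float, bool]:
    """Held-out pathogenic:benign ratio in a bin over the background ratio.

    Returns ``(value, undefined)``: with zero benign variants in the bin
    the ratio is reported as +inf and flagged undefined rather than
    continuity-corrected.
    """
    if background_p <= 0 or background_b <= 0:
        raise ValueError("background counts must be positive")
    if min(heldout_p_in_bin, heldout_b_in_bin) < 0:
        raise ValueError("bin counts must be non-negative")
    background = background_p / background_b
    if heldout_b_in_bin == 0:
        return float("inf"), True
    return (heldout_p_in_bin / heldout_b_in_bin) / background, False


def mc_cross_validation(
    pool: pd.DataFrame,
    trials: int,
    per_class_train: int = 10,
    prior: float = 0.1,
    config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo cross-validation of minimum-truthset calibration.

    Each trial samples ``per_class_train`` pathogenic and benign variants
    without replacement as the calibration truthset, calibrates, assigns
    evidence to the held-out labelled variants, and reports the observed LR
    per occupied evidence bin against the held-out background composition.
    Seeded from ``config.seed``; returns a table with columns
    ``trial``, ``level``, ``observed_lr``, ``undefined``, ``n_pathogenic``,
    ``n_benign``.
    """
    cfg = config if config is not None else CalibrationConfig()
    p_idx = pool.index[pool["class"] == "P"].to_numpy()
    b_idx = pool.index[pool["class"] == "B"].to_numpy()
    if len(p_idx) < 2 * per_class_train or len(b_idx) < 2 * per_class_train:
        raise ValueError(
            f"pool must hold at least {2 * per_class_train} variants per class"
        )
    rows = []
    children = np.random.SeedSequence(cfg.seed).spawn(trials)
    for trial, child in enumerate(children):
        rng = np.random.default_rng(child)
        train_p = rng.choice(p_idx, size=per_class_train, replace=False)
        train_b = rng.choice(b_idx, size=per_class_train, replace=False)
        train = set(train_p) | set(train_b)

        df = pool[["score", "class"]].copy()
        df["true_class"] = df["class"]
        heldout_mask = ~df.index.isin(train)
        # held-out variants enter as unlabelled: they get LRs and evidence
        # without contributing to the density estimates
        df.loc[heldout_mask, "class"] = ""
        result = calibrate(
            df.reset_index(drop=True),
            value="score",
            prior=prior,
            config=cfg,
        )
        lr_table = result.likelihood_ratios
        held = lr_table[lr_table["class"] == ""]
        held = held[held["true_class"].isin(["P", "B"])]
        bg_p = int((held["true_class"] == "P").sum())
        bg_b = int((held["true_class"] == "B").sum())
        for level in EVIDENCE_LEVELS:
            in_bin = held[held["score_evidence"] == level]
            if len(in_bin) == 0:
                continue
            n_p = int((in_bin["true_class"] == "P").sum())
            n_b = int((in_bin["true_class"] == "B").sum())
            value, undefined = observed_lr(n_p, n_b, bg_p, bg_b)
            rows.append(
                {
                    "trial": trial,
                    "level": level,
                    "observed_lr": value,
                    "undefined": undefined,
                    "n_pathogenic": n_p,
                    "n_benign": n_b,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["trial", "level", "observed_lr", "undefined", "n_pathogenic", "n_benign"],
    )


def selector_ci_width(
    truthset: pd.DataFrame,
    selectors: list[str],
    config: CalibrationConfig | None = None,
) -> pd.DataFrame:
    """Mean LR confidence-interval width over truthset variants per selector.

    Runs the full calibration once per bandwidth selector and averages
    ``lr_upper - lr_lower`` over the labelled variants.  A selector that
    fails on the data is recorded with a missing width.
    """
    cfg = config if config is not None else CalibrationConfig()
    rows = []
    for kind in selectors:
        try:
            result = calibrate(
                truthset, value="score", config=cfg.with_overrides(selector=kind)
            )
            lr = result.likelihood_ratios
            labelled = lr[lr["class"].isin(["P", "B"])]
            width = float((labelled["score_lr_upper"] - labelled["score_lr_lower"]).mean())
        except (ValueError, RuntimeError) as exc:
            logger.warning("selector %r failed: %s", kind, exc)
            width = float("nan")
        rows.append({"selector": kind, "mean_ci_width": width})
    return pd.DataFrame(rows, columns=["selector", "mean_ci_width"])
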
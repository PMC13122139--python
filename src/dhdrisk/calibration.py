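"""Probability calibration: Platt scaling and calibration diagnostics.

Platt scaling refits a univariate logistic model of the binary outcome on
the (logit-transformed) raw risk score; applied globally it is a monotone
map, so discrimination (AUC) is untouched while predicted probabilities move
toward the observed event rates.  Group-stratified Platt scaling — one map
per protected-group label — is the post-processing bias-mitigation step:
it aligns predicted risks with observed outcomes within each subgroup.

Diagnostics follow the logistic-recalibration framework: Brier score,
expected calibration error over equal-width probability bins, calibration
intercept (calibration-in-the-large: the intercept of an outcome model with
the score log-odds as a fixed offset) and calibration slope (the free-slope
coefficient of outcome on score log-odds).  Ideal values are 0 and 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from dhdrisk.containers import PredictionSet

#: probabilities are clipped here before the log-odds transform
_CLIP = 1e-6


def _logit_clipped(scores: np.ndarray) -> np.ndarray:
    return logit(np.clip(scores, _CLIP, 1.0 - _CLIP))


@dataclass
class Calibrator:
    """A fitted univariate logistic map from raw to calibrated probability.

    The covariate is the log-odds of the raw probability (clipped to
    [1e-6, 1 - 1e-6]); the map is sigmoid(intercept + slope * logit(s)),
    monotone nondecreasing on [0, 1] whenever slope >= 0.
    """

    intercept: float
    slope: float
    transform: str = "log-odds"
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.slope < 0:
            warnings.warn(
                "fitted Platt slope is negative: the map is not monotone "
                "nondecreasing (scores are anti-correlated with outcomes)",
                stacklevel=2,
            )

    def apply(self, scores: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        return expit(self.intercept + self.slope * _logit_clipped(s))


@dataclass
class GroupCalibrator:
    """One Platt map per protected-group label, with a global fallback."""

    calibrators: dict[str, Calibrator]
    attribute: str
    fallback: Calibrator

    def apply(self, scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        out = np.empty_like(s)
        seen = np.zeros(s.shape, dtype=bool)
        for g, cal in self.calibrators.items():
            mask = labels == g
            out[mask] = cal.apply(s[mask])
            seen |= mask
        if not seen.all():
            unseen = sorted(set(labels[~seen]))
            warnings.warn(
                f"unseen group labels {unseen} routed to the fallback "
                "calibrator",
                stacklevel=2,
            )
            out[~seen] = self.fallback.apply(s[~seen])
        return out


@dataclass
class CalibrationReport:
    """Brier / ECE / intercept / slope plus reliability-diagram bins."""

    brier: float
    ece: float
    calibration_intercept: float
    calibration_slope: float
    bins: pd.DataFrame = field(repr=False)
    n: int = 0

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "brier": self.brier,
            "ece": self.ece,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
            "n": self.n,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def fit_platt(scores: np.ndarray, outcomes: np.ndarray) -> Calibrator:
    """Maximum-likelihood Platt scaling of outcomes on score log-odds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and outcomes must have equal length")
    if s.size < 10:
        raise ValueError("need at least 10 observations to fit Platt scaling")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required to fit Platt scaling")
    lp = _logit_clipped(s)
    if np.ptp(lp) == 0:
        raise ValueError("constant scores: no variance to calibrate on")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            y, sm.add_constant(lp), family=sm.families.Binomial()
        ).fit()
    a, b = float(fit.params[0]), float(fit.params[1])
    return Calibrator(intercept=a, slope=b, n_fit=int(s.size))


def fit_groupwise_platt(
    predset: PredictionSet, attribute: str
) -> GroupCalibrator:
    """Fit one Platt map per group of a protected attribute.

    A group whose outcomes are single-class (or too small to fit) falls back
    to the global calibrator, with a warning.
    """
    if attribute not in predset.attributes:
        raise KeyError(f"attribute {attribute!r} not present in PredictionSet")
    labels = predset.attributes[attribute]
    fallback = fit_platt(predset.scores, predset.outcomes)
    calibrators: dict[str, Calibrator] = {}
    for g in np.unique(labels):
        mask = labels == g
        try:
            calibrators[str(g)] = fit_platt(
                predset.scores[mask], predset.outcomes[mask]
            )
        except ValueError as err:
            warnings.warn(
                f"group {g!r}: {err}; using the global calibrator",
                stacklevel=2,
            )
            calibrators[str(g)] = fallback
    return GroupCalibrator(
        calibrators=calibrators, attribute=attribute, fallback=fallback
    )


def _recalibration_fit(y: np.ndarray, lp: np.ndarray) -> tuple[float, float]:
    """(intercept | slope fixed at 1, slope | free) of logistic recalibration.

    Returns NaN for a component whose fit fails to converge (e.g. perfect
    separation of degenerate inputs).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            off = sm.GLM(
                y,
                np.ones((y.size, 1)),
                family=sm.families.Binomial(),
                offset=lp,
            ).fit()
            intercept = float(off.params[0])
        except Exception:
            intercept = float("nan")
        try:
            free = sm.GLM(
                y, sm.add_constant(lp), family=sm.families.Binomial()
            ).fit()
            slope = float(free.params[1])
        except Exception:
            slope = float("nan")
    return intercept, slope


def calibration_metrics(
    scores: np.ndarray, outcomes: np.ndarray, n_bins: int = 10
) -> CalibrationReport:
    """Brier, ECE (count-weighted, equal-width bins), intercept and slope.

    ECE = sum over bins b of (n_b / n) |mean score in b - event rate in b|,
    bins equal-width on [0, 1] with the right edge of the last bin closed.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")

    brier = float(np.mean((s - y) ** 2))
    idx = np.minimum((s * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sum_s = np.bincount(idx, weights=s, minlength=n_bins)
    sum_y = np.bincount(idx, weights=y, minlength=n_bins)
    nonzero = counts > 0
    mean_s = np.divide(sum_s, counts, out=np.zeros(n_bins), where=nonzero)
    rate = np.divide(sum_y, counts, out=np.zeros(n_bins), where=nonzero)
    ece = float(
        np.sum(counts[nonzero] / s.size * np.abs(mean_s - rate)[nonzero])
    )
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "mean_predicted": np.where(nonzero, mean_s, np.nan),
            "observed_rate": np.where(nonzero, rate, np.nan),
        }
    )
    intercept, slope = _recalibration_fit(y, _logit_clipped(s))
    return CalibrationReport(
        brier=brier,
        ece=ece,
        calibration_intercept=intercept,
        calibration_slope=slope,
        bins=bins,
        n=int(s.size),
    )
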
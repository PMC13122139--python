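"""Decision-curve analysis: net benefit against treat-all / treat-none.

Net benefit at a risk threshold t weighs true positives against false
positives at the exchange rate implied by the threshold odds:

    NB(t) = TP/n - (FP/n) * t / (1 - t)

where a positive classification means score >= t (ties act positive).  The
treat-all strategy classifies everyone positive, so its true-positive rate
is the event prevalence pi and its false-positive rate 1 - pi, giving the
closed form NB_all(t) = pi - (1 - pi) t / (1 - t), which decreases in t and
crosses zero exactly at t = pi.  Treat-none has NB = 0 at every threshold.
The standardized variant divides by pi, capping the achievable value at 1.0.
Both raw and standardized curves are always emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dhdrisk.containers import PredictionSet


@dataclass
class DecisionCurve:
    """Model / treat-all / treat-none net benefit over a threshold grid.

    ``table`` columns: threshold, nb_model, nb_all, nb_none, snb_model,
    snb_all (standardized = divided by prevalence ``pi``).
    """

    table: pd.DataFrame
    prevalence: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _validate_threshold(t: float) -> None:
    if not 0 < t < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")


def net_benefit(
    predset: PredictionSet, threshold: float, standardized: bool = False
) -> float:
    """Net benefit of classifying score >= threshold as positive."""
    _validate_threshold(threshold)
    y = predset.outcomes
    pos = predset.scores >= threshold
    n = y.size
    tp = float((pos & (y == 1)).sum())
    fp = float((pos & (y == 0)).sum())
    nb = tp / n - (fp / n) * threshold / (1.0 - threshold)
    if standardized:
        pi = float(y.mean())
        if pi == 0:
            raise ValueError("cannot standardize: prevalence is zero")
        nb /= pi
    return nb


def treat_all_net_benefit(
    prevalence: float, threshold: float, standardized: bool = False
) -> float:
    """Closed-form treat-all net benefit: pi - (1 - pi) t / (1 - t)."""
    _validate_threshold(threshold)
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    nb = prevalence - (1.0 - prevalence) * threshold / (1.0 - threshold)
    if standardized:
        if prevalence == 0:
            raise ValueError("cannot standardize: prevalence is zero")
        nb /= prevalence
    return nb


#: default grid covers thresholds 0.01-0.60 in steps of 0.01
DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 0.601, 0.01), 2)


def decision_curve(
    predset: PredictionSet, thresholds: np.ndarray | None = None
) -> DecisionCurve:
    """Evaluate the model's decision curve against both reference strategies.

    Treat-all is computed analytically from the prevalence; treat-none is
    identically zero.  The structural bounds NB <= pi and standardized
    NB <= 1 are asserted on every curve.
    """
    thresholds = np.asarray(
        DEFAULT_THRESHOLDS if thresholds is None else thresholds, dtype=float
    )
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    for t in thresholds:
        _validate_threshold(float(t))
    pi = float(predset.outcomes.mean())
    if pi == 0:
        raise ValueError("no events observed: decision curve is undefined")
    nb_model = np.array(
        [net_benefit(predset, float(t)) for t in thresholds]
    )
    nb_all = np.array(
        [treat_all_net_benefit(pi, float(t)) for t in thresholds]
    )
    if np.any(nb_model > pi + 1e-12):
        raise AssertionError("net benefit exceeded the prevalence bound")
    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "nb_model": nb_model,
            "nb_all": nb_all,
            "nb_none": np.zeros_like(thresholds),
            "snb_model": nb_model / pi,
            "snb_all": nb_all / pi,
        }
    )
    if np.any(table["snb_model"].to_numpy() > 1.0 + 1e-12):
        raise AssertionError("standardized net benefit exceeded 1.0")
    return DecisionCurve(table=table, prevalence=pi)
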
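"""Threshold-free fairness audit: AUC, xAUC and ECE parity ratios.

Risk scores in health care act as ranking and prioritization tools rather
than binary classifiers, so the audit avoids threshold-dependent criteria
entirely.  Three metrics are compared between an equity-seeking group and
its regular counterpart — within-group AUC (can the model rank each group's
own cases above its controls?), cross-group xAUC (is a random positive from
one group ranked above a random negative from the other?), and ECE (are
probabilities equally well calibrated?) — each expressed as the ratio
equity-seeking / regular, with 1.0 perfect parity.  Ratios are classified
into fairness bands at 10% and 20% deviation from 1.

Default equity-seeking groups: female (vs male), rural (vs urban), and the
most-marginalized residential-instability quintile Q5 (vs Q1-4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from dhdrisk.calibration import calibration_metrics
from dhdrisk.containers import PredictionSet

#: attribute -> (equity-seeking label, regular label)
DEFAULT_EQUITY_MAP: dict[str, tuple[str, str]] = {
    "sex": ("female", "male"),
    "residency": ("rural", "urban"),
    "instability": ("Q5", "Q1-4"),
}

_DIRECTIONS = ("equity_pos_vs_regular_neg", "regular_pos_vs_equity_neg")


def auc(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie).

    Computed from the rank statistic; exactly equal to brute-force pair
    enumeration with the half-tie convention.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes required to compute AUC")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _cross_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """P(positive-group score > negative-group score) + 1/2 ties."""
    s = np.concatenate([scores_pos, scores_neg])
    y = np.concatenate(
        [np.ones(scores_pos.size, int), np.zeros(scores_neg.size, int)]
    )
    return auc(s, y)


def _equity_labels(
    attribute: str, equity_map: dict[str, tuple[str, str]] | None
) -> tuple[str, str]:
    table = {**DEFAULT_EQUITY_MAP, **(equity_map or {})}
    if attribute not in table:
        raise KeyError(
            f"no equity/regular label pair known for attribute {attribute!r}"
        )
    return table[attribute]


def xauc(
    predset: PredictionSet,
    attribute: str,
    direction: str = "equity_pos_vs_regular_neg",
    equity_map: dict[str, tuple[str, str]] | None = None,
) -> float:
    """Cross-group ranking probability.

    ``equity_pos_vs_regular_neg`` ranks positives of the equity-seeking
    group against negatives of the regular group; the other direction swaps
    the roles.  Empty required (group, class) cells raise explicitly.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")
    if attribute not in predset.attributes:
        raise KeyError(f"attribute {attribute!r} not present in PredictionSet")
    equity, regular = _equity_labels(attribute, equity_map)
    labels = predset.attributes[attribute]
    if direction == "equity_pos_vs_regular_neg":
        pos_group, neg_group = equity, regular
    else:
        pos_group, neg_group = regular, equity
    pos = predset.scores[(labels == pos_group) & (predset.outcomes == 1)]
    neg = predset.scores[(labels == neg_group) & (predset.outcomes == 0)]
    if pos.size == 0:
        raise ValueError(f"empty cell: no positives in group {pos_group!r}")
    if neg.size == 0:
        raise ValueError(f"empty cell: no negatives in group {neg_group!r}")
    return _cross_auc(pos, neg)


def _band(ratio: float) -> str:
    if not np.isfinite(ratio):
        return "undefined"
    dev = abs(ratio - 1.0)
    if dev <= 0.1:
        return "within 10%"
    if dev <= 0.2:
        return "within 20%"
    return "outside"


@dataclass
class FairnessReport:
    """Per-attribute parity ratios with fairness-band labels.

    ``table`` has one row per attribute with the group-level metrics, the
    equity/regular parity ratios and a band label per ratio.  The xAUC
    parity convention — forward (equity positives vs regular negatives)
    divided by backward — is recorded in ``conventions``.
    """

    table: pd.DataFrame
    n_bins: int = 10
    conventions: dict[str, str] = field(
        default_factory=lambda: {
            "parity": "equity-seeking / regular",
            "xauc_parity": "forward (equity-pos vs regular-neg) / backward",
        }
    )

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "conventions": self.conventions,
            "n_bins": self.n_bins,
            "attributes": self.table.to_dict(orient="records"),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload

    def to_table(self, path: str | Path) -> None:
        """Flat delimited table: one row per attribute x metric."""
        rows = []
        for rec in self.table.to_dict(orient="records"):
            for metric in ("auc_parity", "xauc_parity", "ece_parity"):
                rows.append(
                    {
                        "attribute": rec["attribute"],
                        "metric": metric,
                        "ratio": rec[metric],
                        "band": rec[f"{metric}_band"],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def fairness_report(
    predset: PredictionSet,
    attributes: list[str] | None = None,
    n_bins: int = 10,
    equity_map: dict[str, tuple[str, str]] | None = None,
) -> FairnessReport:
    """Compute AUC / xAUC / ECE parity ratios for each protected attribute.

    A zero ECE in the regular group makes the ECE ratio undefined: it is
    reported as NaN with the band label "undefined".
    """
    attributes = list(attributes or predset.attributes)
    rows = []
    for attribute in attributes:
        equity, regular = _equity_labels(attribute, equity_map)
        labels = predset.attributes[attribute]
        groups = {}
        for side, label in (("equity", equity), ("regular", regular)):
            mask = labels == label
            if mask.sum() == 0:
                raise ValueError(
                    f"attribute {attribute!r}: no rows with label {label!r}"
                )
            sub = predset.subset(mask)
            groups[side] = {
                "auc": auc(sub.scores, sub.outcomes),
                "ece": calibration_metrics(
                    sub.scores, sub.outcomes, n_bins=n_bins
                ).ece,
            }
        fwd = xauc(predset, attribute, _DIRECTIONS[0], equity_map)
        bwd = xauc(predset, attribute, _DIRECTIONS[1], equity_map)
        auc_parity = groups["equity"]["auc"] / groups["regular"]["auc"]
        xauc_parity = fwd / bwd
        ece_reg = groups["regular"]["ece"]
        ece_parity = (
            groups["equity"]["ece"] / ece_reg if ece_reg > 0 else float("nan")
        )
        rows.append(
            {
                "attribute": attribute,
                "equity_label": equity,
                "regular_label": regular,
                "auc_equity": groups["equity"]["auc"],
                "auc_regular": groups["regular"]["auc"],
                "auc_parity": auc_parity,
                "auc_parity_band": _band(auc_parity),
                "xauc_forward": fwd,
                "xauc_backward": bwd,
                "xauc_parity": xauc_parity,
                "xauc_parity_band": _band(xauc_parity),
                "ece_equity": groups["equity"]["ece"],
                "ece_regular": ece_reg,
                "ece_parity": ece_parity,
                "ece_parity_band": _band(ece_parity),
            }
        )
    return FairnessReport(table=pd.DataFrame(rows), n_bins=n_bins)
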
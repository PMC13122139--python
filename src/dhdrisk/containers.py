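"""Core shared containers.

`PredictionSet` is the lingua franca between the calibration, fairness-audit
and clinical-utility stages: aligned vectors of risk scores in [0, 1], binary
outcomes, and per-row protected-attribute labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PredictionSet:
    """Aligned risk scores, binary outcomes and protected-attribute labels.

    Parameters
    ----------
    scores : array of float
        Predicted event probabilities in [0, 1].
    outcomes : array of int
        Binary observed outcomes (0/1).
    attributes : dict of str -> array of str
        Per-row group labels keyed by attribute name, e.g.
        ``{"sex": ["female", "male", ...]}``.  Each label array is aligned
        with ``scores``.
    """

    scores: np.ndarray
    outcomes: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if self.scores.ndim != 1 or self.outcomes.ndim != 1:
            raise ValueError("scores and outcomes must be 1-d")
        if self.scores.shape != self.outcomes.shape:
            raise ValueError("scores and outcomes must have equal length")
        if np.any(~np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be binary 0/1")
        self.attributes = {
            k: np.asarray(v) for k, v in self.attributes.items()
        }
        for name, labels in self.attributes.items():
            if labels.shape != self.scores.shape:
                raise ValueError(
                    f"attribute {name!r} length does not match scores"
                )

    def __len__(self) -> int:
        return self.scores.size

    def subset(self, mask: np.ndarray) -> "PredictionSet":
        """Return the row subset selected by a boolean mask."""
        return PredictionSet(
            scores=self.scores[mask],
            outcomes=self.outcomes[mask],
            attributes={k: v[mask] for k, v in self.attributes.items()},
        )

    def with_scores(self, scores: np.ndarray) -> "PredictionSet":
        """Return a copy with the score vector replaced (e.g. recalibrated)."""
        return PredictionSet(
            scores=np.asarray(scores, dtype=float),
            outcomes=self.outcomes.copy(),
            attributes={k: v.copy() for k, v in self.attributes.items()},
        )
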
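"""Model-agnostic explainability: global and local explanation operators.

Global view: permutation feature importance (drop in AUC when one feature
column is shuffled) and partial dependence profiles (population-average
prediction as one feature sweeps a grid).  Local view: Shapley attributions
(coalition averaging — order-invariant), breakdown attributions (sequential
conditioning — order-dependent), and ceteris-paribus profiles (one
instance's prediction path as a single feature varies).

Shapley and breakdown share one interventional value function

    v(S) = mean over background rows of f(row with features in S
           replaced by the instance's values)

so the two local methods are directly comparable.  Under this definition
v(all features) equals the instance's own prediction exactly, hence local
accuracy — baseline + sum of contributions = prediction — holds exactly for
breakdown, exact Shapley, *and* permutation-sampled Shapley (each sampled
permutation telescopes to the same total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from dhdrisk.cohort_prep import CohortMatrix
from dhdrisk.fairness_audit import auc
from dhdrisk.risk_models import RiskModel

_EXACT_FEATURE_LIMIT = 12


@dataclass
class AttributionRow:
    """Per-feature contributions to one prediction.

    ``baseline`` is the mean model prediction over the background sample;
    contributions satisfy baseline + sum = prediction (exactly for
    breakdown/exact Shapley, and by telescoping also for sampled Shapley).
    """

    instance_id: object
    baseline: float
    contributions: dict[str, float]
    prediction: float
    method: str

    def total(self) -> float:
        return self.baseline + sum(self.contributions.values())


@dataclass
class Profile:
    """Prediction profile of one feature over a grid.

    ``kind`` is "pdp" (population average) or "ceteris_paribus" (single
    instance, whose id is then set).
    """

    feature: str
    grid: np.ndarray
    predictions: np.ndarray
    kind: str
    instance_id: object = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        if np.any((self.predictions < 0) | (self.predictions > 1)):
            raise ValueError("profile predictions must lie in [0, 1]")


def _predict_matrix(model: RiskModel, x: np.ndarray) -> np.ndarray:
    """Fast prediction path on a raw feature matrix in training order."""
    p = np.asarray(model.estimator.predict_proba(x)[:, 1], dtype=np.float64)
    p = np.clip(p, 0.0, 1.0)
    if model.calibrator is not None:
        p = model.calibrator.apply(p)
    return p


def permutation_importance(
    model: RiskModel,
    data: CohortMatrix,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean AUC drop (with sd over repeats) when each feature is permuted.

    Returns a frame indexed by feature with columns ``importance`` (baseline
    AUC minus mean permuted AUC) and ``sd``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    rng = np.random.default_rng(seed)
    x = data.features[model.feature_names].to_numpy(dtype=float)
    y = data.outcome
    baseline = auc(_predict_matrix(model, x), y)
    rows = {}
    for j, name in enumerate(model.feature_names):
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(x.shape[0]), j]
            drops.append(baseline - auc(_predict_matrix(model, xp), y))
        rows[name] = {
            "importance": float(np.mean(drops)),
            "sd": float(np.std(drops, ddof=1)),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "feature"
    out.attrs["baseline_auc"] = baseline
    return out


def partial_dependence(
    model: RiskModel,
    data: CohortMatrix,
    feature: str,
    grid: np.ndarray,
) -> Profile:
    """Population-average prediction as ``feature`` sweeps ``grid``."""
    if len(data) == 0:
        raise ValueError("empty data")
    if feature not in model.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    x = data.features[model.feature_names].to_numpy(dtype=float)
    j = model.feature_names.index(feature)
    preds = []
    for g in np.asarray(grid, dtype=float):
        xg = x.copy()
        xg[:, j] = g
        preds.append(float(_predict_matrix(model, xg).mean()))
    return Profile(
        feature=feature, grid=grid, predictions=np.array(preds), kind="pdp"
    )


def ceteris_paribus(
    model: RiskModel,
    instance: pd.Series | pd.DataFrame,
    feature: str,
    grid: np.ndarray,
    instance_id: object = None,
) -> Profile:
    """One instance's prediction path as a single feature varies."""
    inst = _as_instance_vector(model, instance)
    if feature not in model.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = model.feature_names.index(feature)
    grid = np.asarray(grid, dtype=float)
    x = np.tile(inst, (grid.size, 1))
    x[:, j] = grid
    return Profile(
        feature=feature,
        grid=grid,
        predictions=_predict_matrix(model, x),
        kind="ceteris_paribus",
        instance_id=instance_id,
    )


def _as_instance_vector(
    model: RiskModel, instance: pd.Series | pd.DataFrame
) -> np.ndarray:
    if isinstance(instance, pd.DataFrame):
        if len(instance) != 1:
            raise ValueError("instance must be a single row")
        instance = instance.iloc[0]
    missing = set(model.feature_names) - set(instance.index)
    if missing:
        raise ValueError(f"instance lacks features: {sorted(missing)}")
    return instance[model.feature_names].to_numpy(dtype=float)


class _ValueFunction:
    """Interventional coalition value over a shared background sample."""

    def __init__(
        self,
        model: RiskModel,
        instance: pd.Series | pd.DataFrame,
        background: pd.DataFrame,
    ):
        if len(background) == 0:
            raise ValueError("background must be non-empty")
        self.model = model
        self.names = model.feature_names
        self.bg = background[self.names].to_numpy(dtype=float)
        self.inst = _as_instance_vector(model, instance)
        self._cache: dict[frozenset, float] = {}

    def value(self, fixed: frozenset[int]) -> float:
        if fixed not in self._cache:
            x = self.bg.copy()
            for j in fixed:
                x[:, j] = self.inst[j]
            self._cache[fixed] = float(_predict_matrix(self.model, x).mean())
        return self._cache[fixed]

    def walk(self, order: np.ndarray) -> np.ndarray:
        """Batched marginal contributions along one feature ordering."""
        k = len(order)
        x = np.tile(self.bg, (k + 1, 1))
        n_bg = self.bg.shape[0]
        for step, j in enumerate(order, start=1):
            # prefix of length `step` fixes features order[:step]
            x[step * n_bg :, j] = self.inst[j]
        v = _predict_matrix(self.model, x).reshape(k + 1, n_bg).mean(axis=1)
        return np.diff(v)


def shapley_attributions(
    model: RiskModel,
    instance: pd.Series | pd.DataFrame,
    background: pd.DataFrame,
    mode: str = "exact",
    n_samples: int = 200,
    seed: int = 0,
    instance_id: object = None,
) -> AttributionRow:
    """Shapley attribution of one prediction over the background marginal.

    ``exact`` enumerates all coalitions (feature count capped at 12);
    ``sampled`` averages marginal contributions over random feature
    orderings (permutation sampling), which keeps exact local accuracy while
    approximating the per-feature split.
    """
    vf = _ValueFunction(model, instance, background)
    names = model.feature_names
    d = len(names)
    baseline = vf.value(frozenset())
    prediction = vf.value(frozenset(range(d)))

    if mode == "exact":
        if d > _EXACT_FEATURE_LIMIT:
            raise ValueError(
                f"exact Shapley is limited to {_EXACT_FEATURE_LIMIT} "
                f"features (got {d}); use mode='sampled'"
            )
        phi = np.zeros(d)
        fact = [math.factorial(i) for i in range(d + 1)]
        others = list(range(d))
        for j in range(d):
            rest = [k for k in others if k != j]
            for size in range(d):
                weight = fact[size] * fact[d - size - 1] / fact[d]
                for s in combinations(rest, size):
                    fs = frozenset(s)
                    phi[j] += weight * (vf.value(fs | {j}) - vf.value(fs))
        contributions = dict(zip(names, phi.tolist()))
    elif mode == "sampled":
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        phi = np.zeros(d)
        for _ in range(n_samples):
            order = rng.permutation(d)
            deltas = vf.walk(order)
            phi[order] += deltas
        phi /= n_samples
        # telescoping leaves a tiny Monte-Carlo residual only through the
        # shared baseline/prediction estimates; close it exactly
        phi += (prediction - baseline - phi.sum()) / d
        contributions = dict(zip(names, phi.tolist()))
    else:
        raise ValueError("mode must be 'exact' or 'sampled'")

    return AttributionRow(
        instance_id=instance_id,
        baseline=baseline,
        contributions=contributions,
        prediction=prediction,
        method="shapley",
    )


def breakdown_attributions(
    model: RiskModel,
    instance: pd.Series | pd.DataFrame,
    background: pd.DataFrame,
    order: list[str] | str = "auto",
    instance_id: object = None,
) -> AttributionRow:
    """Sequential-conditioning (breakdown) attribution of one prediction.

    The k-th feature's contribution is E[f | first k fixed] minus
    E[f | first k-1 fixed], expectations over the background.  ``auto``
    orders features by decreasing absolute single-fix effect
    |v({j}) - v(empty)|, recomputed per instance.
    """
    vf = _ValueFunction(model, instance, background)
    names = model.feature_names
    baseline = vf.value(frozenset())
    if order == "auto":
        effects = [
            (abs(vf.value(frozenset({j})) - baseline), names[j], j)
            for j in range(len(names))
        ]
        ordered = [j for _, _, j in sorted(effects, key=lambda t: (-t[0], t[1]))]
    else:
        if len(set(order)) != len(order):
            raise ValueError("duplicate features in breakdown order")
        if set(order) != set(names):
            raise ValueError("breakdown order must cover all features")
        ordered = [names.index(f) for f in order]

    deltas = vf.walk(np.array(ordered))
    contributions = {names[j]: float(d) for j, d in zip(ordered, deltas)}
    prediction = baseline + float(deltas.sum())
    return AttributionRow(
        instance_id=instance_id,
        baseline=baseline,
        contributions=contributions,
        prediction=prediction,
        method="breakdown",
    )


def attributions_to_frame(rows: list[AttributionRow]) -> pd.DataFrame:
    """Long-format (instance, feature, value) table of attributions."""
    recs = []
    for row in rows:
        for feature, value in row.contributions.items():
            recs.append(
                {
                    "instance": row.instance_id,
                    "method": row.method,
                    "feature": feature,
                    "contribution": value,
                    "baseline": row.baseline,
                    "prediction": row.prediction,
                }
            )
    return pd.DataFrame(recs)
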
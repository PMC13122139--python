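"""Risk learners: logistic regression and gradient-boosted trees.

Hyperparameters are tuned by grouped, outcome-stratified 5-fold
cross-validation inside the training set — folds partition *patients*, not
admissions, so repeated admissions of one patient never straddle a fold
boundary — with mean out-of-fold AUC as the objective.  The winning setting
is refit from scratch on the full training data.  Ties between grid points
break toward the simpler model (fewer boosting rounds, then shallower
trees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedGroupKFold
from xgboost import XGBClassifier

from dhdrisk.cohort_prep import CohortMatrix
from dhdrisk.fairness_audit import auc

#: default search grid for the gradient-boosted learner; the objective and
#: grid are package choices (documented in the methods note), overridable
#: per call.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "GBT": {
        "max_depth": [2, 3],
        "learning_rate": [0.1, 0.3],
        "n_estimators": [100],
    },
    "LR": {},
}

#: fixed (non-tuned) settings per learner
_GBT_FIXED = dict(
    objective="binary:logistic",
    tree_method="hist",
    n_jobs=2,
    eval_metric="logloss",
)
_LR_FIXED = dict(C=np.inf, solver="lbfgs", max_iter=2000)  # unpenalized

#: ordering key used to break AUC ties toward the simpler model
_COMPLEXITY_KEYS = ("n_estimators", "max_depth", "learning_rate", "C")


@dataclass
class RiskModel:
    """A fitted learner plus its training metadata.

    ``calibrator`` may hold a fitted Platt map (see the calibration module);
    when attached, :func:`predict_risk` returns calibrated probabilities.
    """

    learner_kind: str
    estimator: object
    hyperparameters: dict
    feature_names: list[str]
    n_rows: int
    seed: int
    tuning_trace: list[dict] = field(default_factory=list)
    calibrator: object = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_risk(self, features)


def _make_estimator(learner_kind: str, params: dict, seed: int):
    if learner_kind == "GBT":
        return XGBClassifier(random_state=seed, **_GBT_FIXED, **params)
    if learner_kind == "LR":
        # a finite C in the grid turns on ridge; the default is unpenalized
        merged = {**_LR_FIXED, **params}
        return LogisticRegression(random_state=seed, **merged)
    raise ValueError(f"unknown learner_kind: {learner_kind!r}")


def _complexity_key(params: dict) -> tuple:
    return tuple(params.get(k, 0) for k in _COMPLEXITY_KEYS)


def tune_and_fit(
    train: CohortMatrix,
    learner_kind: str = "GBT",
    n_folds: int = 5,
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> RiskModel:
    """Grouped stratified CV hyperparameter search, then a full refit.

    An empty/omitted grid fits the learner's documented defaults directly.
    Degenerate single-class training data is rejected.
    """
    y = train.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both outcome classes")
    x = train.features.to_numpy(dtype=float)
    w = train.sample_weight
    grid = DEFAULT_GRIDS.get(learner_kind, {}) if grid is None else grid
    points = sorted(
        (dict(p) for p in ParameterGrid(grid)) if grid else [{}],
        key=_complexity_key,
    )

    trace: list[dict] = []
    if len(points) == 1:
        best_params = points[0]
    else:
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=seed
        )
        folds = list(splitter.split(x, y, groups=train.patient_id))
        for tr_idx, va_idx in folds:
            if len(np.unique(y[tr_idx])) < 2 or len(np.unique(y[va_idx])) < 2:
                raise ValueError(
                    "both outcome classes required in every CV fold"
                )
        best_params, best_score = None, -np.inf
        for params in points:
            scores = []
            for tr_idx, va_idx in folds:
                est = _make_estimator(learner_kind, params, seed)
                est.fit(
                    x[tr_idx],
                    y[tr_idx],
                    sample_weight=None if w is None else w[tr_idx],
                )
                pred = est.predict_proba(x[va_idx])[:, 1]
                scores.append(auc(pred, y[va_idx]))
            mean_auc = float(np.mean(scores))
            trace.append({"params": params, "mean_cv_auc": mean_auc})
            # strict improvement only: earlier (simpler) points win ties
            if mean_auc > best_score + 1e-12:
                best_params, best_score = params, mean_auc

    final = _make_estimator(learner_kind, best_params, seed)
    final.fit(x, y, sample_weight=w)
    return RiskModel(
        learner_kind=learner_kind,
        estimator=final,
        hyperparameters=dict(best_params),
        feature_names=list(train.features.columns),
        n_rows=len(train),
        seed=seed,
        tuning_trace=trace,
    )


def predict_risk(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted event probabilities in [0, 1] for a feature table.

    The feature-name set must equal the training set (order is normalized
    here); unknown or missing names are rejected explicitly.  An attached
    calibrator is applied to the raw probabilities.
    """
    got, want = set(features.columns), set(model.feature_names)
    if got != want:
        unknown, absent = sorted(got - want), sorted(want - got)
        raise ValueError(
            f"feature mismatch: unknown={unknown}, missing={absent}"
        )
    if len(features) == 0:
        return np.empty(0, dtype=float)
    x = features[model.feature_names].to_numpy(dtype=float)
    p = np.asarray(model.estimator.predict_proba(x)[:, 1], dtype=np.float64)
    p = np.clip(p, 0.0, 1.0)
    if model.calibrator is not None:
        p = model.calibrator.apply(p)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("non-finite predicted probabilities")
    return p


def save_model(model: RiskModel, path: str | Path) -> None:
    """Serialize model state to a versioned JSON file (LR: coefficients;
    GBT: the native booster JSON embedded as a string)."""
    payload = {
        "format_version": 1,
        "learner_kind": model.learner_kind,
        "hyperparameters": model.hyperparameters,
        "feature_names": model.feature_names,
        "n_rows": model.n_rows,
        "seed": model.seed,
    }
    if model.learner_kind == "LR":
        est: LogisticRegression = model.estimator
        payload["coef"] = est.coef_[0].tolist()
        payload["intercept"] = float(est.intercept_[0])
    else:
        payload["booster"] = json.loads(
            model.estimator.get_booster().save_raw("json").decode()
            if hasattr(model.estimator.get_booster(), "save_raw")
            else "{}"
        )
    Path(path).write_text(json.dumps(payload))
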
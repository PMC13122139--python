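import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from dhdrisk import (
    SyntheticConfig,
    apply_exclusions,
    build_lookback_features,
    generate_admissions,
)
from dhdrisk.risk_models import RiskModel


def make_lr_model(coefficients: dict[str, float], intercept: float) -> RiskModel:
    """A RiskModel wrapping a logistic predictor with fixed coefficients."""
    names = list(coefficients)
    est = LogisticRegression()
    est.classes_ = np.array([0, 1])
    est.coef_ = np.array([[coefficients[n] for n in names]], dtype=float)
    est.intercept_ = np.array([intercept], dtype=float)
    return RiskModel(
        learner_kind="LR",
        estimator=est,
        hyperparameters={},
        feature_names=names,
        n_rows=0,
        seed=0,
    )


class FunctionEstimator:
    """Duck-typed estimator computing probabilities from a callable."""

    def __init__(self, fn):
        self.fn = fn

    def predict_proba(self, x):
        p = np.clip(np.asarray(self.fn(np.asarray(x, float))), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


def make_function_model(fn, feature_names) -> RiskModel:
    return RiskModel(
        learner_kind="stub",
        estimator=FunctionEstimator(fn),
        hyperparameters={},
        feature_names=list(feature_names),
        n_rows=0,
        seed=0,
    )


def brute_force_auc(scores, outcomes) -> float:
    """O(n^2) pair enumeration with the half-tie convention."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


@pytest.fixture(scope="session")
def small_cohort():
    """A ~12k-admission synthetic cohort with its ground truth."""
    cfg = SyntheticConfig(n_patients=4000, seed=11)
    admissions, truth = generate_admissions(cfg)
    clean, _ = apply_exclusions(admissions)
    cohort = build_lookback_features(clean)
    return cohort, truth, clean


def make_admission_row(
    patient_id="P1",
    admission_date="2010-06-01",
    age=75.0,
    sex="female",
    region="Central",
    residency="urban",
    income_quintile=3,
    onmarg=(2, 3, 4, 1),
    flags=(),
    from_ltc=0,
    dhd=0,
):
    row = {
        "patient_id": patient_id,
        "admission_date": pd.Timestamp(admission_date),
        "age": age,
        "sex": sex,
        "region": region,
        "residency": residency,
        "income_quintile": income_quintile,
        "onmarg_ethnic": onmarg[0],
        "onmarg_dependency": onmarg[1],
        "onmarg_instability": onmarg[2],
        "onmarg_deprivation": onmarg[3],
        "from_ltc": from_ltc,
        "dhd_90d": dhd,
    }
    from dhdrisk.cohort_prep import RAW_FLAG_COLUMNS

    for f in RAW_FLAG_COLUMNS:
        row[f] = 1 if f in flags else 0
    return row
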
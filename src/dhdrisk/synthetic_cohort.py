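"""Synthetic admission-cohort simulator with known logistic ground truth.

The real study population — Ontario acute-care admissions of adults 65+,
2004-2022, with a delayed-discharge ("alternate level of care") outcome within
90 days — lives in administrative databases that cannot be shared.  This
module generates admission tables that emulate that cohort's structure so
every downstream stage (preparation, modelling, calibration, fairness,
utility, explanation) is testable against a known data-generating process:

* ~9% outcome prevalence (class imbalance), with the intercept solved
  numerically so the mean event probability hits the configured target;
* repeated admissions per patient, with patient-stable covariates (sex,
  region, residency, income, area-marginalization quintiles) and
  per-admission clinical flag occurrences driven by a shared patient frailty
  latent (logistic-normal), which induces mild positive correlation between
  history flags;
* subgroup prevalences matching the study's descriptive table (49% female,
  16% rural, 28% residential-instability Q5, ...);
* a logistic ground-truth outcome model over the SAME engineered look-back
  features the preparation stage constructs, so parameter recovery and
  Bayes-AUC comparisons are exact end-to-end;
* configurable group-specific calibration distortions (shift/scale on the
  logit scale) and contamination channels (under-65 patients, LTC-origin
  rows, missing marginalization quintiles) for exercising exclusions and
  bias-mitigation machinery;
* one designated pure-noise feature for permutation-importance null tests.

`generate_scored_set` skips the covariate layer entirely: it draws
logit-normal risk scores whose distribution is solved numerically to hit a
requested AUC and prevalence, then draws outcomes through per-group
logit-scale distortions — scores are perfectly calibrated in expectation
when the distortion is the identity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from dhdrisk.containers import PredictionSet
from dhdrisk.cohort_prep import (
    COMORBIDITY_FLAGS,
    EVENT_FLAGS,
    FEATURE_COLUMNS,
    NOISE_FLAG,
    RAW_FLAG_COLUMNS,
    REGIONS,
    engineer_features,
)

#: default ground-truth log-odds weights on the engineered features.
#: Mobility/disability and cognitive-decline features carry the largest
#: weights (care-support history, dementia, rehabilitation-discharge history,
#: fracture) with a linear age term, echoing the importance ordering the
#: analysis is expected to surface; the noise marker is exactly null.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "hist_care_support": 1.6,
    "com_dementia": 1.5,
    "hist_rehab_discharge": 1.2,
    "hist_fracture": 0.9,
    "hist_fall": 0.7,
    "hist_palliative": 0.8,
    "hist_mobility": 1.1,
    "com_chf": 0.45,
    "com_diabetes": 0.2,
    "com_cerebrovascular": 0.45,
    "age": 0.055,
    "female": 0.25,
    "rural": -0.1,
    "instability_q5": 0.35,
    "deprivation_q5": 0.2,
    "dependency_q5": 0.12,
    "income_q1": 0.2,
    "ethnic_q5": 0.0,
    "region_central": 0.12,
    "region_metropolitan": 0.05,
    "region_southwestern": 0.0,
    "region_northern": 0.3,
    "noise_marker": 0.0,
}

#: per-admission occurrence log-odds intercepts for the clinical flags and
#: the loading on the patient frailty latent (0 for the pure-noise marker).
_FLAG_INTERCEPTS: dict[str, float] = {
    "care_support": -2.4,
    "fall": -1.8,
    "fracture": -2.2,
    "rehab_discharge": -2.7,
    "palliative": -3.2,
    "mobility": -1.7,
    "dementia": -2.0,
    "chf": -1.9,
    "diabetes": -1.2,
    "cerebrovascular": -2.4,
    NOISE_FLAG: -1.0,
}
_FRAILTY_LOADING = 0.8

#: marginal distributions for patient-stable covariates (study Table-1-like)
_REGION_PROBS = (0.18, 0.32, 0.18, 0.22, 0.10)  # Eastern..Northern
_INCOME_PROBS = (0.21, 0.21, 0.20, 0.19, 0.19)  # Q1..Q5
_ONMARG_Q5 = {  # P(quintile == 5) per dimension
    "onmarg_ethnic": 0.16,
    "onmarg_dependency": 0.37,
    "onmarg_instability": 0.28,
    "onmarg_deprivation": 0.21,
}

_DEFAULT_SUBGROUPS = {"female": 0.49, "rural": 0.16, "instability_q5": 0.28}
_DEFAULT_CONTAMINATION = {"under_65": 0.05, "ltc": 0.02, "missing": 0.003}


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort draw.

    ``coefficient_map`` holds the ground-truth log-odds weights on engineered
    features; ``intercept`` may be left ``None`` to be solved numerically so
    the mean event probability over clean rows equals ``target_prevalence``.
    ``distortion_map`` maps a group label (``female``, ``male``, ``rural``,
    ``urban``, ``Q5``, ``Q1-4``) to a logit-scale ``(shift, scale)`` applied
    to that group's true outcome probability.  ``contamination_rates`` give
    the injection probabilities for under-65 patients, LTC-origin rows and
    missing marginalization quintiles.
    """

    n_patients: int = 10_000
    mean_admissions_per_patient: float = 3.0
    year_range: tuple[int, int] = (2004, 2022)
    target_prevalence: float = 0.089
    coefficient_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    intercept: float | None = None
    subgroup_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SUBGROUPS)
    )
    distortion_map: dict[str, tuple[float, float]] = field(default_factory=dict)
    contamination_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTAMINATION)
    )
    lookback_window_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.mean_admissions_per_patient <= 0:
            raise ValueError("mean_admissions_per_patient must be positive")
        if not 0 <= self.target_prevalence <= 1:
            raise ValueError("target_prevalence must lie in [0, 1]")
        if not self.coefficient_map:
            raise ValueError("coefficient_map must not be empty")
        for name, value in self.coefficient_map.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite coefficient for {name!r}")
        unknown = set(self.coefficient_map) - set(FEATURE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown coefficient features: {sorted(unknown)}")
        for p in self.subgroup_prevalences.values():
            if not 0 <= p <= 1:
                raise ValueError("subgroup prevalences must lie in [0, 1]")
        for p in self.contamination_rates.values():
            if not 0 <= p <= 1:
                raise ValueError("contamination rates must lie in [0, 1]")
        for g, (a, b) in self.distortion_map.items():
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ValueError(f"non-finite distortion for group {g!r}")
            if b <= 0:
                raise ValueError(f"distortion scale must be > 0 for {g!r}")


@dataclass
class GroundTruth:
    """The data-generating parameters plus realized summary quantities.

    ``bayes_auc`` is the discrimination of the true event probability itself
    — the ceiling no learner can beat in expectation; ``true_probability``
    is row-aligned with the emitted admission table (contaminated rows get
    the probability their covariates imply, but are excluded from the
    realized summaries).
    """

    coefficient_map: dict[str, float]
    intercept: float
    distortion_map: dict[str, tuple[float, float]]
    realized_prevalence: float
    bayes_auc: float
    contamination_counts: dict[str, int] = field(default_factory=dict)
    true_probability: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficient_map": self.coefficient_map,
            "intercept": self.intercept,
            "distortion_map": {
                k: list(v) for k, v in self.distortion_map.items()
            },
            "realized_prevalence": self.realized_prevalence,
            "bayes_auc": self.bayes_auc,
            "contamination_counts": self.contamination_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# numeric helpers


_HERM_X, _HERM_W = np.polynomial.hermite.hermgauss(80)


def mean_sigmoid(mu: float, sigma: float) -> float:
    """E[sigmoid(U)] for U ~ Normal(mu, sigma^2), by Gauss-Hermite quadrature."""
    z = mu + sigma * math.sqrt(2.0) * _HERM_X
    return float(np.sum(_HERM_W * expit(z)) / math.sqrt(math.pi))


def _solve_mu(prevalence: float, sigma: float) -> float:
    """Location of the logit-normal score law with a given mean probability."""
    return brentq(
        lambda m: mean_sigmoid(m, sigma) - prevalence, -30.0, 30.0, xtol=1e-12
    )


def _logit_normal_auc(mu: float, sigma: float) -> float:
    """AUC of a perfectly calibrated logit-normal score, by grid integration.

    With S = sigmoid(U), U ~ N(mu, sigma^2) and Y | S ~ Bernoulli(S),
    AUC = E[S_a (1 - S_b) 1{S_a > S_b}] / (pi (1 - pi)) over independent
    draws, pi = E[S].  Continuous law, so ties carry no mass.
    """
    u = np.linspace(mu - 10 * sigma, mu + 10 * sigma, 4001)
    f = np.exp(-0.5 * ((u - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    s = expit(u)
    pi = np.trapezoid(s * f, u)
    # C(u) = integral_{u' < u} (1 - s(u')) f(u') du'
    g = (1.0 - s) * f
    c = np.concatenate(
        ([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(u)))
    )
    num = np.trapezoid(s * f * c, u)
    return float(num / (pi * (1.0 - pi)))


def _solve_score_law(prevalence: float, base_auc: float) -> tuple[float, float]:
    """Solve (mu, sigma) of the logit-normal score law for (prevalence, AUC)."""

    def auc_gap(sig: float) -> float:
        return _logit_normal_auc(_solve_mu(prevalence, sig), sig) - base_auc

    sigma = brentq(auc_gap, 0.02, 12.0, xtol=1e-10)
    return _solve_mu(prevalence, sigma), sigma


def analytic_auc_of_probabilities(p: np.ndarray) -> float:
    """Bayes AUC of scoring by the true probability vector ``p``.

    AUC = sum over ordered pairs (a, b), a != b, of
    p_a (1 - p_b) [1{p_a > p_b} + 1/2 1{p_a = p_b}] / sum p_a (1 - p_b).
    Computed in O(n log n) via sorting; agrees exactly with brute-force pair
    enumeration.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    order = np.argsort(p, kind="mergesort")
    ps, qs = p[order], q[order]
    cum_q = np.concatenate(([0.0], np.cumsum(qs)))
    # strictly-less and tied q-mass per sorted position
    starts = np.searchsorted(ps, ps, side="left")
    ends = np.searchsorted(ps, ps, side="right")
    less_mass = cum_q[starts]
    tie_mass = cum_q[ends] - cum_q[starts] - qs
    num = float(np.sum(ps * (less_mass + 0.5 * tie_mass)))
    den = float(np.sum(p) * np.sum(q) - np.sum(p * q))
    if den <= 0:
        raise ValueError("degenerate probability vector (no class mass)")
    return num / den


def _apply_distortions(
    eta: np.ndarray,
    groups: dict[str, np.ndarray],
    distortion_map: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Apply logit-scale (shift, scale) distortions to matching group rows."""
    out = eta.copy()
    for label, (a, b) in distortion_map.items():
        matched = False
        for _, labels in groups.items():
            mask = labels == label
            if mask.any():
                out[mask] = a + b * eta[mask]
                matched = True
        if not matched:
            raise ValueError(f"distortion group {label!r} matches no rows")
    return out


# ---------------------------------------------------------------------------
# admission-table generation


def generate_admissions(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a longitudinal admission table and its generating ground truth.

    Outcomes are Bernoulli(sigmoid(intercept + X beta)) on the engineered
    look-back features, with optional per-group logit distortions.
    Contaminated rows (under-65 patients, LTC-origin, missing
    marginalization quintiles) are injected at the configured rates and
    tallied in ``GroundTruth.contamination_counts``; realized prevalence and
    Bayes AUC are computed over clean rows only.
    """
    rng = np.random.default_rng(config.seed)
    n_pat = config.n_patients

    # --- patient-stable covariates
    extra = max(config.mean_admissions_per_patient - 1.0, 0.0)
    n_adm = 1 + rng.poisson(extra, size=n_pat)
    total = int(n_adm.sum())
    pid = np.repeat(
        np.array([f"P{i:07d}" for i in range(n_pat)], dtype=object), n_adm
    )

    p_female = config.subgroup_prevalences.get("female", 0.49)
    p_rural = config.subgroup_prevalences.get("rural", 0.16)
    p_inst5 = config.subgroup_prevalences.get("instability_q5", 0.28)

    sex_p = np.where(rng.random(n_pat) < p_female, "female", "male")
    res_p = np.where(rng.random(n_pat) < p_rural, "rural", "urban")
    region_p = rng.choice(np.array(REGIONS, dtype=object), n_pat, p=_REGION_PROBS)
    income_p = rng.choice(np.arange(1, 6), n_pat, p=_INCOME_PROBS)

    def _onmarg(p5: float) -> np.ndarray:
        q5 = rng.random(n_pat) < p5
        return np.where(q5, 5, rng.integers(1, 5, size=n_pat)).astype(float)

    onmarg = {
        name: _onmarg(p_inst5 if name == "onmarg_instability" else p5)
        for name, p5 in _ONMARG_Q5.items()
    }

    rate_u65 = config.contamination_rates.get("under_65", 0.0)
    under65 = rng.random(n_pat) < rate_u65
    # truncated log-normal on [65, 105], median ~ 80
    age0 = 65.0 + np.minimum(rng.lognormal(math.log(15.0), 0.5, n_pat), 40.0)
    age0[under65] = rng.uniform(40.0, 64.5, int(under65.sum()))
    frailty = rng.normal(0.0, 1.0, n_pat)

    # --- admission dates (uniform in range, sorted within patient)
    start = np.datetime64(f"{config.year_range[0]}-01-01")
    end = np.datetime64(f"{config.year_range[1]}-12-31")
    span = int((end - start) / np.timedelta64(1, "D")) + 1
    day_offsets = np.concatenate(
        [np.sort(rng.integers(0, span, size=k)) for k in n_adm]
    )
    dates = start + day_offsets.astype("timedelta64[D]")
    first_offset = np.repeat(
        np.fromiter(
            (o[0] for o in np.split(day_offsets, np.cumsum(n_adm)[:-1]) if o.size),
            dtype=np.int64,
            count=n_pat,
        ),
        n_adm,
    )
    age = np.repeat(age0, n_adm) + (day_offsets - first_offset) / 365.25

    # --- per-admission clinical flag occurrences (frailty-correlated)
    frailty_row = np.repeat(frailty, n_adm)
    flags = {}
    for name, alpha in _FLAG_INTERCEPTS.items():
        loading = 0.0 if name == NOISE_FLAG else _FRAILTY_LOADING
        prob = expit(alpha + loading * frailty_row)
        flags[name] = (rng.random(total) < prob).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": pid,
            "admission_date": dates,
            "age": age,
            "sex": np.repeat(sex_p, n_adm),
            "region": np.repeat(region_p, n_adm),
            "residency": np.repeat(res_p, n_adm),
            "income_quintile": np.repeat(income_p, n_adm),
            **{k: np.repeat(v, n_adm) for k, v in onmarg.items()},
            **{k: flags[k] for k in RAW_FLAG_COLUMNS},
            "from_ltc": np.zeros(total, dtype=int),
        }
    )

    # --- contamination: LTC-origin rows and missing marginalization values
    ltc_mask = rng.random(total) < config.contamination_rates.get("ltc", 0.0)
    df.loc[ltc_mask, "from_ltc"] = 1
    miss_mask = rng.random(total) < config.contamination_rates.get("missing", 0.0)
    if miss_mask.any():
        dims = rng.choice(list(_ONMARG_Q5), size=int(miss_mask.sum()))
        rows = np.flatnonzero(miss_mask)
        for dim in _ONMARG_Q5:
            df.loc[rows[dims == dim], dim] = np.nan

    # --- ground-truth linear predictor on engineered look-back features
    feats = engineer_features(df, window_days=config.lookback_window_days)
    x = feats.fillna(0.0).to_numpy(dtype=float)
    beta = np.array(
        [config.coefficient_map.get(c, 0.0) for c in FEATURE_COLUMNS]
    )
    eta_x = x @ beta

    clean = (~ltc_mask) & (~miss_mask) & (df["age"].to_numpy() >= 65)
    if config.intercept is None:
        target = config.target_prevalence
        b0 = brentq(
            lambda b: float(np.mean(expit(b + eta_x[clean]))) - target,
            -40.0,
            40.0,
            xtol=1e-12,
        )
    else:
        b0 = float(config.intercept)

    eta = b0 + eta_x
    groups = {
        "sex": df["sex"].to_numpy(),
        "residency": df["residency"].to_numpy(),
        "instability": np.where(
            df["onmarg_instability"].to_numpy() == 5, "Q5", "Q1-4"
        ),
    }
    if config.distortion_map:
        eta = _apply_distortions(eta, groups, config.distortion_map)
    p_true = expit(eta)
    df["dhd_90d"] = (rng.random(total) < p_true).astype(int)

    truth = GroundTruth(
        coefficient_map=dict(config.coefficient_map),
        intercept=b0,
        distortion_map=dict(config.distortion_map),
        realized_prevalence=float(df.loc[clean, "dhd_90d"].mean()),
        bayes_auc=analytic_auc_of_probabilities(p_true[clean]),
        contamination_counts={
            "under_65": int((df["age"] < 65).sum()),
            "ltc": int((ltc_mask & (df["age"].to_numpy() >= 65)).sum()),
            "missing": int(
                (miss_mask & ~ltc_mask & (df["age"].to_numpy() >= 65)).sum()
            ),
        },
        true_probability=p_true,
    )
    return df, truth


# ---------------------------------------------------------------------------
# scored prediction sets


def generate_scored_set(
    n: int,
    base_auc: float = 0.82,
    group_fractions: dict[str, float] | None = None,
    distortion_map: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    prevalence: float = 0.089,
) -> tuple[PredictionSet, GroundTruth]:
    """Draw risk scores with known AUC/prevalence and per-group distortions.

    Scores are logit-normal with (mu, sigma) solved so that a perfectly
    calibrated outcome draw has the requested AUC and prevalence.  Outcomes
    are then drawn as Bernoulli(sigmoid(a_g + b_g logit(s))) per group, so
    ``(a_g, b_g) = (0, 1)`` gives calibrated-by-construction scores and any
    other setting a controlled miscalibration for that group.
    """
    if not 0.5 < base_auc < 1.0:
        raise ValueError("base_auc must lie in (0.5, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    group_fractions = dict(group_fractions or {"all": 1.0})
    if abs(sum(group_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("group fractions must sum to 1")
    distortion_map = dict(distortion_map or {})
    for g, (a, b) in distortion_map.items():
        if g not in group_fractions:
            raise ValueError(f"distortion for unknown group {g!r}")
        if not (math.isfinite(a) and math.isfinite(b)) or b <= 0:
            raise ValueError(f"invalid distortion for group {g!r}")

    rng = np.random.default_rng(seed)
    names = sorted(group_fractions)
    labels = rng.choice(
        np.array(names, dtype=object),
        size=n,
        p=[group_fractions[g] for g in names],
    )
    counts = {g: int((labels == g).sum()) for g in names}
    if min(counts.values()) < 2:
        raise ValueError(f"need n >= 2 per group, got {counts}")

    mu, sigma = _solve_score_law(prevalence, base_auc)
    u = rng.normal(mu, sigma, n)
    scores = expit(u)

    eta = u.copy()
    for g, (a, b) in distortion_map.items():
        mask = labels == g
        eta[mask] = a + b * u[mask]
    p_true = expit(eta)
    outcomes = (rng.random(n) < p_true).astype(int)

    truth = GroundTruth(
        coefficient_map={},
        intercept=mu,
        distortion_map=distortion_map,
        realized_prevalence=float(outcomes.mean()),
        bayes_auc=analytic_auc_of_probabilities(p_true),
        contamination_counts={},
        true_probability=p_true,
    )
    predset = PredictionSet(
        scores=scores, outcomes=outcomes, attributes={"group": labels}
    )
    return predset, truth


# ---------------------------------------------------------------------------
# text serialization


def write_admissions(df: pd.DataFrame, path: str | Path) -> None:
    """Write an admission table as CSV (header row, ISO dates, empty=missing)."""
    out = df.copy()
    out["admission_date"] = pd.to_datetime(out["admission_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, index=False, na_rep="")


def read_admissions(path: str | Path) -> pd.DataFrame:
    """Read an admission table written by :func:`write_admissions`."""
    df = pd.read_csv(path, parse_dates=["admission_date"])
    return df
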
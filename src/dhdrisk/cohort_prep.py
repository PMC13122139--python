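"""Cohort preparation: exclusions, look-back history features, splits.

The study design targets acute-care admissions of community-dwelling adults
aged 65+.  Preparation proceeds in fixed stages:

1. exclusions (age < 65, admitted-from-LTC, missing/invalid fields) applied
   complete-case, in that order, with an exact tally;
2. look-back feature construction — for each index admission, binary history
   flags are the union of flag occurrences on the same patient's admissions
   inside a 2-year window before the index date (comorbidity-type flags also
   count the index admission itself, as current-state conditions);
3. dichotomization of area-level marginalization quintiles (most-marginalized
   Q5 vs Q1-Q4);
4. train/test partitioning at the patient level — random-by-patient or
   temporal by each patient's first admission year — so that repeated
   admissions of one patient never straddle the split;
5. optional class rebalancing of the training side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: flags whose history is "an event occurred on a prior admission":
#: strictly before the index date, inside the look-back window.
EVENT_FLAGS = (
    "care_support",
    "fall",
    "fracture",
    "rehab_discharge",
    "palliative",
    "mobility",
)

#: chronic-condition flags: window union including the index admission
#: (a comorbidity recorded at the index admission is a current condition).
COMORBIDITY_FLAGS = ("dementia", "chf", "diabetes", "cerebrovascular")

#: pure-noise marker, carried through untouched for importance null tests.
NOISE_FLAG = "noise_marker"

RAW_FLAG_COLUMNS = EVENT_FLAGS + COMORBIDITY_FLAGS + (NOISE_FLAG,)

ONMARG_COLUMNS = (
    "onmarg_ethnic",
    "onmarg_dependency",
    "onmarg_instability",
    "onmarg_deprivation",
)

REGIONS = ("Eastern", "Central", "Metropolitan", "Southwestern", "Northern")

#: engineered model features, in canonical order
FEATURE_COLUMNS = (
    "age",
    "female",
    "rural",
    "income_q1",
    "ethnic_q5",
    "dependency_q5",
    "instability_q5",
    "deprivation_q5",
    "region_central",
    "region_metropolitan",
    "region_southwestern",
    "region_northern",
    "hist_care_support",
    "hist_fall",
    "hist_fracture",
    "hist_rehab_discharge",
    "hist_palliative",
    "hist_mobility",
    "com_dementia",
    "com_chf",
    "com_diabetes",
    "com_cerebrovascular",
    "noise_marker",
)

PROTECTED_ATTRIBUTES = ("sex", "residency", "instability")


@dataclass
class ExclusionTally:
    """Counts removed by each exclusion rule, applied in fixed order."""

    removed_age: int
    removed_ltc: int
    removed_missing: int
    retained: int

    @property
    def removed(self) -> int:
        return self.removed_age + self.removed_ltc + self.removed_missing


@dataclass
class CohortMatrix:
    """Analysis-ready design matrix with aligned outcome and metadata.

    All vectors are row-aligned: ``features`` holds binary flags plus age in
    years, ``outcome`` the binary delayed-discharge indicator, ``protected``
    the equity-audit labels (sex, residency, residential-instability group),
    ``patient_id`` and ``admission_date`` the longitudinal keys.
    """

    features: pd.DataFrame
    outcome: np.ndarray
    protected: pd.DataFrame
    patient_id: np.ndarray
    admission_date: np.ndarray
    sample_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.patient_id = np.asarray(self.patient_id)
        n = len(self.features)
        if not (
            self.outcome.size == n
            and len(self.protected) == n
            and self.patient_id.size == n
            and len(self.admission_date) == n
        ):
            raise ValueError("CohortMatrix components are not row-aligned")
        if self.features.isna().any().any():
            raise ValueError("CohortMatrix features contain missing values")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, mask: np.ndarray) -> "CohortMatrix":
        mask = np.asarray(mask)
        return CohortMatrix(
            features=self.features.loc[mask].reset_index(drop=True),
            outcome=self.outcome[mask],
            protected=self.protected.loc[mask].reset_index(drop=True),
            patient_id=self.patient_id[mask],
            admission_date=np.asarray(self.admission_date)[mask],
            sample_weight=None
            if self.sample_weight is None
            else self.sample_weight[mask],
        )


def dichotomize_onmarg(quintile: int | np.ndarray) -> int | np.ndarray:
    """Map a marginalization quintile to most-marginalized (Q5) vs rest.

    Returns 1 iff the quintile is 5, else 0.  Out-of-range values are
    rejected; NaN propagates (missingness is handled by the exclusion stage).
    """
    q = np.asarray(quintile, dtype=float)
    valid = np.isnan(q) | ((q >= 1) & (q <= 5) & (q == np.floor(q)))
    if not valid.all():
        raise ValueError("quintile values must be integers in 1..5")
    out = np.where(np.isnan(q), np.nan, (q == 5).astype(float))
    if np.isscalar(quintile) or np.ndim(quintile) == 0:
        return float(out) if np.isnan(out) else int(out)
    return out


def apply_exclusions(
    admissions: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the cohort exclusion rules and return the exact tally.

    Rules, in order (a row violating several is counted under the first):
    age < 65 -> admitted from LTC -> any missing/invalid required field.
    An empty input yields an empty output with a zero tally.
    """
    df = admissions.reset_index(drop=True)
    n = len(df)
    if n == 0:
        return df, ExclusionTally(0, 0, 0, 0)

    age_bad = df["age"].to_numpy(dtype=float) < 65
    ltc_bad = df["from_ltc"].to_numpy(dtype=float) == 1
    required = [
        c
        for c in df.columns
        if c not in ("dhd_90d",)  # outcome missingness is schema-invalid anyway
    ]
    missing_bad = df[required].isna().any(axis=1).to_numpy()

    first_rule = np.full(n, "", dtype=object)
    first_rule[missing_bad] = "missing"
    first_rule[ltc_bad] = "ltc"
    first_rule[age_bad] = "age"

    keep = first_rule == ""
    tally = ExclusionTally(
        removed_age=int((first_rule == "age").sum()),
        removed_ltc=int((first_rule == "ltc").sum()),
        removed_missing=int((first_rule == "missing").sum()),
        retained=int(keep.sum()),
    )
    return df.loc[keep].reset_index(drop=True), tally


def engineer_features(
    admissions: pd.DataFrame, window_days: int = 730
) -> pd.DataFrame:
    """Construct the engineered feature frame for every admission row.

    History flags use a half-open look-back window ``[index - window_days,
    index)`` over the same patient's admissions; comorbidity flags also count
    the index admission.  Result is row-aligned with the input (original
    order preserved).  Missing marginalization quintiles propagate as NaN.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    df = admissions.reset_index(drop=True)
    n = len(df)
    out = pd.DataFrame(index=df.index)

    out["age"] = df["age"].astype(float)
    out["female"] = (df["sex"] == "female").astype(int)
    out["rural"] = (df["residency"] == "rural").astype(int)
    out["income_q1"] = (df["income_quintile"] == 1).astype(int)
    out["ethnic_q5"] = dichotomize_onmarg(df["onmarg_ethnic"].to_numpy())
    out["dependency_q5"] = dichotomize_onmarg(df["onmarg_dependency"].to_numpy())
    out["instability_q5"] = dichotomize_onmarg(
        df["onmarg_instability"].to_numpy()
    )
    out["deprivation_q5"] = dichotomize_onmarg(
        df["onmarg_deprivation"].to_numpy()
    )
    for region in REGIONS[1:]:  # Eastern is the reference level
        out[f"region_{region.lower()}"] = (df["region"] == region).astype(int)

    dates = pd.to_datetime(df["admission_date"]).to_numpy()
    day = dates.astype("datetime64[D]").astype(np.int64)
    pid = df["patient_id"].to_numpy()

    order = np.lexsort((day, pid))
    hist = {f: np.zeros(n, dtype=int) for f in EVENT_FLAGS}
    com = {f: np.zeros(n, dtype=int) for f in COMORBIDITY_FLAGS}
    raw = {f: df[f].to_numpy(dtype=int) for f in EVENT_FLAGS + COMORBIDITY_FLAGS}

    # per-patient scan over date-sorted rows
    start = 0
    while start < n:
        stop = start
        p = pid[order[start]]
        while stop < n and pid[order[stop]] == p:
            stop += 1
        idx = order[start:stop]
        d = day[idx]
        lo = np.searchsorted(d, d - window_days, side="left")
        # strictly-earlier-DATE boundary: same-day admissions are not prior,
        # which keeps the result invariant to within-patient row order
        k = np.searchsorted(d, d, side="left")
        for f in EVENT_FLAGS:
            v = raw[f][idx]
            c = np.concatenate(([0], np.cumsum(v)))
            hist[f][idx] = (c[k] - c[lo] > 0).astype(int)
        for f in COMORBIDITY_FLAGS:
            v = raw[f][idx]
            c = np.concatenate(([0], np.cumsum(v)))
            # prior-window occurrences plus the index admission's own flag
            com[f][idx] = ((c[k] - c[lo] + v) > 0).astype(int)
        start = stop

    for f in EVENT_FLAGS:
        out[f"hist_{f}"] = hist[f]
    for f in COMORBIDITY_FLAGS:
        out[f"com_{f}"] = com[f]
    out[NOISE_FLAG] = df[NOISE_FLAG].astype(int)
    return out[list(FEATURE_COLUMNS)]


def build_lookback_features(
    admissions: pd.DataFrame, window_days: int = 730
) -> CohortMatrix:
    """Build the analysis matrix from an exclusion-clean admission table.

    Raises if rows violating the cohort invariants (age < 65, LTC origin,
    missing fields) are still present; run :func:`apply_exclusions` first.
    """
    df = admissions.reset_index(drop=True)
    if len(df) and (df["age"] < 65).any():
        raise ValueError("under-65 rows present; apply_exclusions first")
    if len(df) and (df["from_ltc"] == 1).any():
        raise ValueError("LTC-origin rows present; apply_exclusions first")
    features = engineer_features(df, window_days=window_days)
    if features.isna().any().any():
        raise ValueError("missing values present; apply_exclusions first")
    features = features.astype(
        {c: int for c in features.columns if c != "age"}
    )
    protected = pd.DataFrame(
        {
            "sex": df["sex"].to_numpy(),
            "residency": df["residency"].to_numpy(),
            "instability": np.where(
                features["instability_q5"].to_numpy() == 1, "Q5", "Q1-4"
            ),
        }
    )
    return CohortMatrix(
        features=features,
        outcome=df["dhd_90d"].to_numpy(dtype=int),
        protected=protected,
        patient_id=df["patient_id"].to_numpy(),
        admission_date=pd.to_datetime(df["admission_date"]).to_numpy(),
    )


def _split_masks_by_patients(
    patient_id: np.ndarray, test_patients: set
) -> tuple[np.ndarray, np.ndarray]:
    is_test = np.isin(patient_id, list(test_patients))
    return ~is_test, is_test


def split_by_patient(
    cohort: CohortMatrix, test_fraction: float = 0.10, seed: int = 0
) -> tuple[CohortMatrix, CohortMatrix]:
    """Random train/test split with all admissions of a patient on one side."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    patients = np.unique(cohort.patient_id)
    if patients.size < 2:
        raise ValueError("need at least 2 distinct patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(patients)
    n_test = max(1, int(round(test_fraction * patients.size)))
    test_set = set(perm[:n_test])
    train_mask, test_mask = _split_masks_by_patients(
        cohort.patient_id, test_set
    )
    train, test = cohort.subset(train_mask), cohort.subset(test_mask)
    _assert_patient_disjoint(train, test)
    return train, test


def temporal_split(
    cohort: CohortMatrix, cutoff_year: int = 2014
) -> tuple[CohortMatrix, CohortMatrix]:
    """Temporal validation split keyed on each patient's FIRST admission year.

    Patients whose first recorded admission falls in or before ``cutoff_year``
    go to training (with all their admissions); later first-admission years
    go to the temporal test set.
    """
    dates = pd.to_datetime(pd.Series(cohort.admission_date))
    years = dates.dt.year.to_numpy()
    first_year = (
        pd.DataFrame({"pid": cohort.patient_id, "year": years})
        .groupby("pid")["year"]
        .min()
    )
    test_patients = set(first_year.index[first_year > cutoff_year])
    train_mask, test_mask = _split_masks_by_patients(
        cohort.patient_id, test_patients
    )
    train, test = cohort.subset(train_mask), cohort.subset(test_mask)
    _assert_patient_disjoint(train, test)
    return train, test


def _assert_patient_disjoint(train: CohortMatrix, test: CohortMatrix) -> None:
    shared = set(train.patient_id) & set(test.patient_id)
    if shared:
        raise AssertionError(
            f"patient leakage across split: {sorted(shared)[:5]} ..."
        )


def rebalance_training(
    train: CohortMatrix,
    method: str = "class_weight",
    seed: int = 0,
) -> CohortMatrix:
    """Address class imbalance on the training side only.

    ``none``: identity.  ``downsample``: subsample the majority class to the
    minority count.  ``class_weight``: attach inverse-prevalence sample
    weights, leaving rows untouched (the default downstream, since it keeps
    the empirical outcome rate available to calibration).
    """
    if method == "none":
        return train
    y = train.outcome
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if method == "downsample":
        if n_pos == 0 or n_neg == 0:
            raise ValueError("downsample requires both classes present")
        rng = np.random.default_rng(seed)
        maj_label = int(n_pos > n_neg)
        maj_idx = np.flatnonzero(y == maj_label)
        min_idx = np.flatnonzero(y != maj_label)
        kept = rng.choice(maj_idx, size=min_idx.size, replace=False)
        mask = np.zeros(len(train), dtype=bool)
        mask[min_idx] = True
        mask[np.sort(kept)] = True
        return train.subset(mask)
    if method == "class_weight":
        if n_pos == 0 or n_neg == 0:
            raise ValueError("class_weight requires both classes present")
        n = y.size
        w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
        return CohortMatrix(
            features=train.features.copy(),
            outcome=y.copy(),
            protected=train.protected.copy(),
            patient_id=train.patient_id.copy(),
            admission_date=np.asarray(train.admission_date).copy(),
            sample_weight=w,
        )
    raise ValueError(f"unknown rebalancing method: {method!r}")
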
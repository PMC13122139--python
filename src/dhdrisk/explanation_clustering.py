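"""Clustering of local-explanation summaries over high-risk patients.

Local attributions for patients predicted high-risk (probability above 0.5)
are condensed into three per-feature metrics: (1) mean signed contribution
to the prediction, (2) mean rank when each patient's features are ordered
by decreasing absolute contribution (rank 1 = largest), and (3) prevalence —
the percentage of high-risk patients for whom the feature lands in the
top-k (default 10) contributors.  The feature-by-metric matrix is z-scored
column-wise and decomposed by PCA on the 3x3 correlation matrix; each
feature is then assigned one of four sign-quadrants from its PC1/PC2 scores
(Q1 = (+,+), Q2 = (-,+), Q3 = (-,-), Q4 = (+,-)), and quadrant composition
is reported over three a-priori feature categories (sociodemographic-
geographic, multimorbidity-health, mobility-disability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dhdrisk.explainability import AttributionRow

CATEGORIES = (
    "sociodemographic-geographic",
    "multimorbidity-health",
    "mobility-disability",
)

#: default feature -> category map for the synthetic cohort's feature set;
#: user cohorts supply their own (e.g. via a small YAML file).
DEFAULT_CATEGORY_MAP: dict[str, str] = {
    "age": "sociodemographic-geographic",
    "female": "sociodemographic-geographic",
    "rural": "sociodemographic-geographic",
    "income_q1": "sociodemographic-geographic",
    "ethnic_q5": "sociodemographic-geographic",
    "dependency_q5": "sociodemographic-geographic",
    "instability_q5": "sociodemographic-geographic",
    "deprivation_q5": "sociodemographic-geographic",
    "region_central": "sociodemographic-geographic",
    "region_metropolitan": "sociodemographic-geographic",
    "region_southwestern": "sociodemographic-geographic",
    "region_northern": "sociodemographic-geographic",
    "noise_marker": "sociodemographic-geographic",
    "com_dementia": "multimorbidity-health",
    "com_chf": "multimorbidity-health",
    "com_diabetes": "multimorbidity-health",
    "com_cerebrovascular": "multimorbidity-health",
    "hist_palliative": "multimorbidity-health",
    "hist_care_support": "mobility-disability",
    "hist_fall": "mobility-disability",
    "hist_fracture": "mobility-disability",
    "hist_rehab_discharge": "mobility-disability",
    "hist_mobility": "mobility-disability",
}

_METRICS = ("mean_contribution", "mean_rank", "prevalence")


@dataclass
class FeatureSummaryTable:
    """Per-feature (contribution, rank, prevalence) summary with category."""

    table: pd.DataFrame  # index: feature; columns: _METRICS + category
    n_high_risk: int
    top_k: int
    risk_threshold: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="feature")


@dataclass
class PCAResult:
    """PCA of the z-scored summary metrics with quadrant assignment."""

    standardized: pd.DataFrame
    loadings: pd.DataFrame  # index: metric; columns: PC1..PC3
    scores: pd.DataFrame  # index: feature; columns: PC1, PC2
    variance_fractions: np.ndarray
    quadrant: pd.Series
    composition: pd.DataFrame  # quadrant x category fractions

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "loadings": self.loadings.round(12).to_dict(),
            "variance_fractions": self.variance_fractions.tolist(),
            "quadrants": self.quadrant.to_dict(),
            "composition": self.composition.to_dict(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def summarize_attributions(
    attributions: list[AttributionRow],
    scores: np.ndarray | None = None,
    risk_threshold: float = 0.5,
    top_k: int = 10,
    category_map: dict[str, str] | None = None,
) -> FeatureSummaryTable:
    """Aggregate local attributions over high-risk instances.

    ``scores`` defaults to each attribution row's own prediction.  Within
    each instance, features are ranked by decreasing absolute contribution
    (rank 1 = largest; ties broken by feature name for determinism).
    Raises if no instance clears the risk threshold.
    """
    if not attributions:
        raise ValueError("no attributions supplied")
    if scores is None:
        scores = np.array([row.prediction for row in attributions])
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(attributions):
        raise ValueError("scores must align with attributions")
    high = [
        row for row, s in zip(attributions, scores) if s > risk_threshold
    ]
    if not high:
        raise ValueError(
            f"no high-risk instances (predicted probability > {risk_threshold})"
        )
    features = sorted(high[0].contributions)
    contrib = np.zeros((len(high), len(features)))
    ranks = np.zeros_like(contrib)
    for i, row in enumerate(high):
        if sorted(row.contributions) != features:
            raise ValueError("attribution rows cover different feature sets")
        c = np.array([row.contributions[f] for f in features])
        contrib[i] = c
        # rank 1 = largest |contribution|; lexicographic tie-break is
        # implied by the sorted feature order with a stable argsort
        order = np.argsort(-np.abs(c), kind="mergesort")
        r = np.empty(len(features))
        r[order] = np.arange(1, len(features) + 1)
        ranks[i] = r

    cmap = {**DEFAULT_CATEGORY_MAP, **(category_map or {})}
    table = pd.DataFrame(
        {
            "mean_contribution": contrib.mean(axis=0),
            "mean_rank": ranks.mean(axis=0),
            "prevalence": 100.0 * (ranks <= top_k).mean(axis=0),
            "category": [cmap.get(f, CATEGORIES[0]) for f in features],
        },
        index=pd.Index(features, name="feature"),
    )
    return FeatureSummaryTable(
        table=table,
        n_high_risk=len(high),
        top_k=top_k,
        risk_threshold=risk_threshold,
    )


def pca_quadrants(summary: FeatureSummaryTable) -> PCAResult:
    """PCA of z-scored summary metrics with sign-quadrant assignment.

    Columns are z-scored to mean 0 / sd 1; PCA comes from the
    eigendecomposition of the 3x3 correlation matrix.  Sign indeterminacy is
    resolved by forcing the contribution loading to be >= 0 on each
    component (falling back to the first nonzero loading if it is 0).
    """
    table = summary.table
    if len(table) < 3:
        raise ValueError("need at least 3 features for PCA")
    m = table[list(_METRICS)].to_numpy(dtype=float)
    sd = m.std(axis=0)
    for k, metric in enumerate(_METRICS):
        if sd[k] == 0:
            raise ValueError(f"metric column {metric!r} is constant")
    z = (m - m.mean(axis=0)) / sd
    corr = z.T @ z / len(table)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    for c in range(eigvec.shape[1]):
        pivot = eigvec[0, c]
        if pivot == 0:
            nz = np.flatnonzero(eigvec[:, c])
            pivot = eigvec[nz[0], c] if nz.size else 1.0
        if pivot < 0:
            eigvec[:, c] = -eigvec[:, c]

    comp_names = [f"PC{i + 1}" for i in range(len(_METRICS))]
    loadings = pd.DataFrame(
        eigvec, index=pd.Index(_METRICS, name="metric"), columns=comp_names
    )
    scores_all = z @ eigvec
    scores = pd.DataFrame(
        scores_all[:, :2], index=table.index, columns=["PC1", "PC2"]
    )
    signs1 = scores["PC1"].to_numpy() >= 0
    signs2 = scores["PC2"].to_numpy() >= 0
    quad = np.where(
        signs1 & signs2,
        "Q1",
        np.where(
            ~signs1 & signs2, "Q2", np.where(~signs1 & ~signs2, "Q3", "Q4")
        ),
    )
    quadrant = pd.Series(quad, index=table.index, name="quadrant")

    comp = (
        pd.crosstab(quadrant, table["category"], normalize="index")
        .reindex(columns=list(CATEGORIES), fill_value=0.0)
        .reindex(["Q1", "Q2", "Q3", "Q4"])
        .dropna(how="all")
    )
    standardized = pd.DataFrame(z, index=table.index, columns=list(_METRICS))
    return PCAResult(
        standardized=standardized,
        loadings=loadings,
        scores=scores,
        variance_fractions=eigval / eigval.sum(),
        quadrant=quadrant,
        composition=comp,
    )
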
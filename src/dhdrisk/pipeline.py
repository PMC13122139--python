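"""End-to-end orchestration: simulate -> prepare -> train -> calibrate ->
audit -> utility -> explain -> cluster -> report.

One `RunConfig` drives the whole analysis; every stage writes its
intermediate artifacts (delimited text / JSON) into the output directory,
and a manifest with content hashes plus a log of seeds and versions closes
the run.  Re-running with the same configuration reproduces all numbers
bit-for-bit: every random draw derives from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import dhdrisk
from dhdrisk.calibration import (
    calibration_metrics,
    fit_groupwise_platt,
    fit_platt,
)
from dhdrisk.clinical_utility import decision_curve
from dhdrisk.cohort_prep import (
    PROTECTED_ATTRIBUTES,
    apply_exclusions,
    build_lookback_features,
    rebalance_training,
    split_by_patient,
    temporal_split,
)
from dhdrisk.containers import PredictionSet
from dhdrisk.explainability import (
    attributions_to_frame,
    partial_dependence,
    permutation_importance,
    shapley_attributions,
)
from dhdrisk.explanation_clustering import pca_quadrants, summarize_attributions
from dhdrisk.fairness_audit import fairness_report
from dhdrisk.risk_models import predict_risk, tune_and_fit
from dhdrisk.synthetic_cohort import (
    SyntheticConfig,
    generate_admissions,
    write_admissions,
)

STAGES = (
    "simulate",
    "prepare",
    "train",
    "calibrate",
    "audit",
    "utility",
    "explain",
    "cluster",
    "report",
)

log = logging.getLogger("dhdrisk.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "dhdrisk_run"
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    input_admissions: str | None = None  # optional user-supplied table
    split_scheme: str = "random-by-patient"  # or "temporal"
    test_fraction: float = 0.10
    cutoff_year: int = 2014
    lookback_window_days: int = 730
    rebalance_method: str = "class_weight"
    learners: list[str] = field(default_factory=lambda: ["LR", "GBT"])
    calibration_scheme: str = "global"  # none | global | stratified:<attr>
    fairness_attributes: list[str] = field(
        default_factory=lambda: list(PROTECTED_ATTRIBUTES)
    )
    dca_thresholds: list[float] = field(
        default_factory=lambda: [round(t, 2) for t in np.arange(0.01, 0.601, 0.01)]
    )
    explain_subsample: float = 0.10
    explain_max_instances: int = 200
    explain_background: int = 100
    shap_samples: int = 20
    top_k: int = 10
    risk_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def validate(self) -> None:
        if self.split_scheme not in ("random-by-patient", "temporal"):
            raise ValueError(f"unknown split scheme {self.split_scheme!r}")
        scheme = self.calibration_scheme
        if scheme not in ("none", "global") and not scheme.startswith(
            "stratified:"
        ):
            raise ValueError(f"unknown calibration scheme {scheme!r}")
        if scheme.startswith("stratified:"):
            attr = scheme.split(":", 1)[1]
            if attr not in PROTECTED_ATTRIBUTES:
                raise ValueError(
                    f"calibration stratification attribute {attr!r} not in "
                    f"{PROTECTED_ATTRIBUTES}"
                )
        for attr in self.fairness_attributes:
            if attr not in PROTECTED_ATTRIBUTES:
                raise ValueError(f"unknown fairness attribute {attr!r}")


def _write(path: Path, writer, manifest: dict) -> None:
    writer(path)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest[path.name] = {"sha256": digest, "bytes": path.stat().st_size}


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the pipeline through the requested stages.

    Stages are sequential; requesting a later stage implies all earlier
    ones.  Returns the summary dictionary (also written as JSON).
    """
    config.validate()
    last = max(STAGES.index(s) for s in stages)
    active = STAGES[: last + 1]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    summary: dict = {"seed": config.seed, "stages": list(active)}

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, active, out, manifest, summary)
    except Exception as err:
        stage = summary.get("current_stage", "?")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config, active, out, manifest, summary) -> dict:
    log.info(
        "dhdrisk %s | numpy %s | pandas %s | seed %d",
        dhdrisk.__version__,
        np.__version__,
        pd.__version__,
        config.seed,
    )

    # ----- simulate
    summary["current_stage"] = "simulate"
    if config.input_admissions is not None:
        admissions = pd.read_csv(
            config.input_admissions, parse_dates=["admission_date"]
        )
        truth = None
        log.info("loaded %d admissions from %s", len(admissions), config.input_admissions)
    else:
        syn = SyntheticConfig(
            **{
                "seed": config.seed,
                "lookback_window_days": config.lookback_window_days,
                **config.synthetic,
            }
        )
        admissions, truth = generate_admissions(syn)
        _write(
            out / "admissions.csv",
            lambda p: write_admissions(admissions, p),
            manifest,
        )
        _write(out / "ground_truth.json", truth.to_json, manifest)
        summary["simulate"] = {
            "n_admissions": len(admissions),
            "realized_prevalence": truth.realized_prevalence,
            "bayes_auc": truth.bayes_auc,
        }
        log.info("simulated %d admissions", len(admissions))
    if "simulate" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- prepare
    summary["current_stage"] = "prepare"
    clean, tally = apply_exclusions(admissions)
    cohort = build_lookback_features(
        clean, window_days=config.lookback_window_days
    )
    if config.split_scheme == "temporal":
        train, test = temporal_split(cohort, cutoff_year=config.cutoff_year)
    else:
        train, test = split_by_patient(
            cohort, test_fraction=config.test_fraction, seed=config.seed + 1
        )
    train = rebalance_training(
        train, method=config.rebalance_method, seed=config.seed + 2
    )
    split_manifest = {
        "scheme": config.split_scheme,
        "seed": config.seed + 1,
        "train_patients": sorted(set(map(str, train.patient_id))),
        "test_patients": sorted(set(map(str, test.patient_id))),
    }
    _write(
        out / "split.json",
        lambda p: p.write_text(json.dumps(split_manifest)),
        manifest,
    )
    summary["prepare"] = {
        "excluded": {
            "age": tally.removed_age,
            "ltc": tally.removed_ltc,
            "missing": tally.removed_missing,
        },
        "retained": tally.retained,
        "n_train": len(train),
        "n_test": len(test),
        "test_prevalence": float(test.outcome.mean()),
    }
    log.info("prepared cohort: %d train / %d test rows", len(train), len(test))
    if "prepare" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- train
    summary["current_stage"] = "train"
    models: dict = {}
    raw_sets: dict[str, PredictionSet] = {}
    test_attrs = {
        a: test.protected[a].to_numpy() for a in PROTECTED_ATTRIBUTES
    }
    for kind in config.learners:
        model = tune_and_fit(train, learner_kind=kind, seed=config.seed + 3)
        models[kind] = model
        raw_sets[kind] = PredictionSet(
            scores=predict_risk(model, test.features),
            outcomes=test.outcome,
            attributes=test_attrs,
        )
        log.info("trained %s: %s", kind, model.hyperparameters)
    summary["train"] = {
        k: {"hyperparameters": m.hyperparameters} for k, m in models.items()
    }
    if "train" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- calibrate
    summary["current_stage"] = "calibrate"
    cal_sets: dict[str, PredictionSet] = {}
    perf_rows = []
    for kind in config.learners:
        raw = raw_sets[kind]
        train_scores = predict_risk(models[kind], train.features)
        base = calibration_metrics(raw.scores, raw.outcomes)
        perf_rows.append(_perf_row(f"{kind} model", raw, base))
        scheme = config.calibration_scheme
        if scheme == "none":
            cal_sets[kind] = raw
            continue
        if scheme == "global":
            cal = fit_platt(train_scores, train.outcome)
            cal_scores = cal.apply(raw.scores)
            label = f"{kind} + Platt scaling"
        else:
            attr = scheme.split(":", 1)[1]
            train_set = PredictionSet(
                scores=train_scores,
                outcomes=train.outcome,
                attributes={
                    attr: train.protected[attr].to_numpy()
                },
            )
            gcal = fit_groupwise_platt(train_set, attr)
            cal_scores = gcal.apply(raw.scores, raw.attributes[attr])
            label = f"{kind} + stratified Platt ({attr})"
        cal_sets[kind] = raw.with_scores(cal_scores)
        perf_rows.append(
            _perf_row(
                label,
                cal_sets[kind],
                calibration_metrics(cal_scores, raw.outcomes),
            )
        )
    perf = pd.DataFrame(perf_rows)
    _write(
        out / "performance.csv", lambda p: perf.to_csv(p, index=False), manifest
    )
    reliability = []
    for kind in config.learners:
        rep = calibration_metrics(
            cal_sets.get(kind, raw_sets[kind]).scores, test.outcome
        )
        bins = rep.bins.assign(model=kind)
        reliability.append(bins)
    _write(
        out / "reliability_bins.csv",
        lambda p: pd.concat(reliability).to_csv(p, index=False),
        manifest,
    )
    summary["calibrate"] = perf.to_dict(orient="records")
    if "calibrate" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- audit
    summary["current_stage"] = "audit"
    audit_rows = []
    for kind in config.learners:
        for tag, predset in (("raw", raw_sets[kind]), ("calibrated", cal_sets[kind])):
            if tag == "calibrated" and config.calibration_scheme == "none":
                continue
            rep = fairness_report(predset, config.fairness_attributes)
            audit_rows.append(rep.table.assign(model=kind, scores=tag))
    audit = pd.concat(audit_rows, ignore_index=True)
    _write(
        out / "fairness.csv", lambda p: audit.to_csv(p, index=False), manifest
    )
    summary["audit"] = audit[
        ["model", "scores", "attribute", "auc_parity", "xauc_parity", "ece_parity"]
    ].to_dict(orient="records")
    if "audit" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- utility
    summary["current_stage"] = "utility"
    curves = []
    for kind in config.learners:
        curve = decision_curve(
            cal_sets[kind], np.asarray(config.dca_thresholds)
        )
        curves.append(curve.table.assign(model=kind))
    _write(
        out / "decision_curves.csv",
        lambda p: pd.concat(curves).to_csv(p, index=False),
        manifest,
    )
    summary["utility"] = {"prevalence": float(test.outcome.mean())}
    if "utility" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- explain (on the better-discriminating model, default GBT if tied)
    summary["current_stage"] = "explain"
    from dhdrisk.fairness_audit import auc as _auc

    best = max(
        config.learners,
        key=lambda k: (_auc(raw_sets[k].scores, test.outcome), k == "GBT"),
    )
    # explanations address the raw model output: with balanced training the
    # uncalibrated score scale puts a meaningful stratum above the 0.5
    # high-risk threshold used by the clustering stage
    model = models[best]
    rng = np.random.default_rng(config.seed + 4)
    imp = permutation_importance(
        model, test, n_repeats=5, seed=config.seed + 5
    )
    _write(
        out / "permutation_importance.csv",
        lambda p: imp.to_csv(p),
        manifest,
    )
    pdp_rows = []
    top_feats = imp["importance"].sort_values(ascending=False).index[:8]
    for feat in top_feats:
        grid = (
            np.array([0.0, 1.0])
            if feat != "age"
            else np.linspace(65, 105, 9)
        )
        prof = partial_dependence(model, test, feat, grid)
        pdp_rows.append(
            pd.DataFrame(
                {"feature": feat, "grid": prof.grid, "prediction": prof.predictions}
            )
        )
    _write(
        out / "partial_dependence.csv",
        lambda p: pd.concat(pdp_rows).to_csv(p, index=False),
        manifest,
    )

    n_test = len(test)
    n_sub = min(
        config.explain_max_instances,
        max(1, int(round(config.explain_subsample * n_test))),
    )
    sub_idx = rng.choice(n_test, size=n_sub, replace=False)
    bg_idx = rng.choice(
        n_test, size=min(config.explain_background, n_test), replace=False
    )
    background = test.features.iloc[bg_idx]
    attributions = []
    for i in sub_idx:
        attributions.append(
            shapley_attributions(
                model,
                test.features.iloc[int(i)],
                background,
                mode="sampled",
                n_samples=config.shap_samples,
                seed=config.seed + 6 + int(i),
                instance_id=int(i),
            )
        )
    _write(
        out / "attributions.csv",
        lambda p: attributions_to_frame(attributions).to_csv(p, index=False),
        manifest,
    )
    summary["explain"] = {
        "model": best,
        "n_instances": n_sub,
        "noise_importance": float(imp.loc["noise_marker", "importance"]),
    }
    if "explain" == active[-1]:
        return _finish(out, manifest, summary)

    # ----- cluster
    summary["current_stage"] = "cluster"
    try:
        feat_summary = summarize_attributions(
            attributions,
            risk_threshold=config.risk_threshold,
            top_k=config.top_k,
        )
        pca = pca_quadrants(feat_summary)
        _write(out / "feature_summary.csv", feat_summary.to_csv, manifest)
        _write(out / "pca_clusters.json", lambda p: pca.to_json(p), manifest)
        summary["cluster"] = {
            "n_high_risk": feat_summary.n_high_risk,
            "variance_fractions": pca.variance_fractions.tolist(),
            "quadrant_counts": pca.quadrant.value_counts().to_dict(),
        }
    except ValueError as err:
        summary["cluster"] = {"skipped": str(err)}
        log.info("clustering skipped: %s", err)
    return _finish(out, manifest, summary)


def _perf_row(label: str, predset: PredictionSet, report) -> dict:
    from dhdrisk.fairness_audit import auc as _auc

    return {
        "model": label,
        "auc": _auc(predset.scores, predset.outcomes),
        "brier": report.brier,
        "ece": report.ece,
        "calibration_intercept": report.calibration_intercept,
        "calibration_slope": report.calibration_slope,
    }


def _finish(out: Path, manifest: dict, summary: dict) -> dict:
    summary.pop("current_stage", None)
    _write(
        out / "summary.json",
        lambda p: p.write_text(json.dumps(summary, indent=2, default=str)),
        manifest,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete: %d artifacts", len(manifest))
    return summary
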
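"""End-to-end orchestration: split -> tune -> eject -> prune -> stack -> report.

The run directory receives, for every completed stage, plain-text artifacts:
per-classifier test metrics (CSV), the removal trace (JSON), ROC points
(CSV), the importance table (CSV, plus an optional bar chart), and a run log
(JSON) recording seeds and decisions.  Both the pruned and the unpruned
ensembles are evaluated from the same tuned bank, so their contrast shares
all randomness upstream of the removal stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stackprune.cohort import (
    CohortTable,
    FeatureSchema,
    encode_features,
    load_cohort,
    split_cohort,
)
from stackprune.evaluation import evaluate_predictions
from stackprune.importance import build_importance_table
from stackprune.learners import (
    TuningConfig,
    collect_oof_predictions,
    default_registry,
    eject_invalid_learners,
    tune_bank,
)
from stackprune.removal import RemovalConfig, run_removal
from stackprune.stacking import fit_meta, predict_ensemble
from stackprune.synthetic import SyntheticConfig, default_signal_config, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_LEARNERS = (
    "lgr",
    "mars",
    "cart",
    "ctree",
    "evtree",
    "c50",
    "lmt",
    "rf",
    "bpnn",
    "svm",
)


@dataclass
class PipelineConfig:
    """One run's full recipe (YAML-serializable)."""

    data_csv: str | None = None
    schema: dict | None = None
    synthetic: dict | None = None
    learners: tuple[str, ...] = DEFAULT_LEARNERS
    m: int = 30
    k: int = 10
    repeats: int = 3
    train_frac: float = 0.6
    stratify: bool = True
    removal_threshold: float = 0.75
    classification_threshold: float = 0.5
    seed: int = 0
    outdir: str = "runs/latest"
    plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "learners" in raw:
            raw["learners"] = tuple(raw["learners"])
        return cls(**raw)


@dataclass
class RunResult:
    metrics: pd.DataFrame
    trace: "object"
    importance: "object"
    ensemble_with_removal: "object"
    ensemble_without_removal: "object"
    outdir: Path
    log: dict = field(default_factory=dict)


def _resolve_cohort(cfg: PipelineConfig) -> tuple[CohortTable, dict | None]:
    if cfg.data_csv is not None:
        if cfg.schema is None:
            raise ValueError("data_csv given without a schema")
        schema = FeatureSchema.from_mapping(cfg.schema)
        return load_cohort(cfg.data_csv, schema), None
    syn = dict(cfg.synthetic or {})
    if not syn or syn.pop("default_signal", False):
        sc = default_signal_config(
            n=syn.pop("n", 5000),
            prevalence=syn.pop("prevalence", 0.1226),
            seed=syn.pop("seed", cfg.seed),
        )
    else:
        syn.setdefault("seed", cfg.seed)
        sc = SyntheticConfig(**syn)
    cohort, truth = generate_cohort(sc)
    return cohort, truth


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Execute the full scheme and persist artifacts under ``cfg.outdir``.

    Any stage failure aborts with the stage name; artifacts from completed
    stages are left in place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": cfg.seed, "stages": []}
    stage = "setup"
    try:
        stage = "cohort"
        cohort, truth = _resolve_cohort(cfg)
        log["n"] = cohort.n
        log["class_counts"] = cohort.class_counts()
        if truth is not None:
            (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
        log["stages"].append(stage)

        stage = "split"
        split = split_cohort(
            cohort, train_frac=cfg.train_frac, seed=cfg.seed, stratify=cfg.stratify
        )
        split.to_frame().to_csv(outdir / "split.csv", index=False)
        train = cohort.subset(split.train_idx)
        test = cohort.subset(split.test_idx)
        log["n_train"], log["n_test"] = train.n, test.n
        log["stages"].append(stage)

        stage = "encode"
        X_train, encoder = encode_features(train)
        X_test = encoder.transform(test.records)
        log["stages"].append(stage)

        stage = "tune"
        registry = default_registry()
        unknown = [n for n in cfg.learners if n not in registry]
        if unknown:
            raise ValueError(f"unknown learners: {unknown}")
        tcfg = TuningConfig(m=cfg.m, k=cfg.k, repeats=cfg.repeats, seed=cfg.seed)
        tuned = tune_bank(registry, cfg.learners, X_train, train.labels, tcfg)
        candidate_log = {
            t.name: {"chosen_params": t.chosen_params, "cv_auc": t.cv_auc,
                     "candidates": t.candidates}
            for t in tuned
        }
        (outdir / "tuning.json").write_text(json.dumps(candidate_log, indent=2, default=str))
        log["stages"].append(stage)

        stage = "eject"
        valid, ejections = eject_invalid_learners(tuned)
        log["ejections"] = ejections
        log["stages"].append(stage)

        stage = "removal"
        oof = collect_oof_predictions(valid)
        names = [t.name for t in valid]
        cv_aucs = {t.name: t.cv_auc for t in valid}
        trace = run_removal(
            oof, names, RemovalConfig(threshold=cfg.removal_threshold), cv_aucs
        )
        (outdir / "removal_trace.json").write_text(trace.to_json())
        pd.DataFrame(
            np.corrcoef(oof, rowvar=False) if len(names) > 1 else [[1.0]],
            index=names,
            columns=names,
        ).to_csv(outdir / "oof_correlations.csv")
        log["survivors"] = trace.survivors
        log["stages"].append(stage)

        stage = "stack"
        base_models = {t.name: t.fitted_model for t in valid}
        surv_cols = [names.index(s) for s in trace.survivors]
        with_removal = fit_meta(
            oof[:, surv_cols], train.labels, trace.survivors,
            base_models={s: base_models[s] for s in trace.survivors},
        )
        without_removal = fit_meta(
            oof, train.labels, names, base_models=base_models
        )
        log["meta_weights_with_removal"] = with_removal.meta_weights
        log["meta_weights_without_removal"] = without_removal.meta_weights
        log["stages"].append(stage)

        stage = "evaluate"
        rows = {}
        roc_frames = []
        for t in valid:
            probs = t.fitted_model.predict_proba(np.asarray(X_test, dtype=float))[:, 1]
            rows[t.name] = evaluate_predictions(
                probs, test.labels, cfg.classification_threshold
            )
        for label, model in (
            ("ensemble_with_removal", with_removal),
            ("ensemble_without_removal", without_removal),
        ):
            probs = predict_ensemble(model, X_test)
            rows[label] = evaluate_predictions(
                probs, test.labels, cfg.classification_threshold
            )
        metrics = pd.DataFrame(
            {name: rep.rounded() for name, rep in rows.items()}
        ).T[["accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc"]]
        metrics.index.name = "classifier"
        metrics.to_csv(outdir / "metrics.csv")
        for name, rep in rows.items():
            df = pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"])
            df.insert(0, "classifier", name)
            roc_frames.append(df)
        pd.concat(roc_frames).to_csv(outdir / "roc_points.csv", index=False)
        log["stages"].append(stage)

        stage = "importance"
        survivors_tuned = [t for t in valid if t.name in trace.survivors]
        lgr = next((t for t in tuned if t.name == "lgr"), None)
        table = build_importance_table(
            survivors_tuned,
            with_removal.meta_weights,
            X_train,
            train.labels,
            encoder,
            cohort.schema,
            lgr_learner=lgr,
            seed=cfg.seed,
        )
        table.to_frame().to_csv(outdir / "importance.csv", index=False)
        if cfg.plot:
            import matplotlib

            matplotlib.use("Agg")
            ax = table.plot()
            ax.figure.savefig(outdir / "importance.png", bbox_inches="tight")
        log["knee_index"] = table.knee_index
        log["stages"].append(stage)
    except Exception as exc:
        log["failed_stage"] = stage
        log["error"] = str(exc)
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log["config"] = dataclasses.asdict(cfg)
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return RunResult(
        metrics=metrics,
        trace=trace,
        importance=table,
        ensemble_with_removal=with_removal,
        ensemble_without_removal=without_removal,
        outdir=outdir,
        log=log,
    )
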
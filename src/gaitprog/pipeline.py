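"""One-command end-to-end run: simulate/ingest -> preprocess -> screen ->
select -> compare models -> progression reports, with a reproducibility
manifest.

All randomness flows from one master seed through named sub-seeds
(simulation, cross-validation split, forest), so each stage is individually
reproducible. Every JSON artifact is written with sorted keys and no
timestamps; re-running with the same configuration reproduces them
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitprog import __version__
from gaitprog.cohort import ClinicalScoreTable, CohortTable, PreprocessedCohort
from gaitprog.io import log, read_cohort_dir, write_report
from gaitprog.models import default_model_specs
from gaitprog.preprocess import preprocess
from gaitprog.progression import ScoreSeries, compare_reports, progression_report
from gaitprog.selection import find_progressing_features, forward_select
from gaitprog.simulate import CohortConfig, generate_cohort, write_cohort
from gaitprog.validation import compare_models, make_cv_plan


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable, hashable, seedable."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None          # read this cohort instead of simulating
    max_consecutive_missing: int = 2
    impute_scores: bool = True
    alpha: float = 0.05
    consensus_k: int = 5
    min_improvement: float = 0.0
    variance_threshold: float = 0.90
    n_folds: int = 5
    split_unit: str = "row"
    fdr: float = 0.01
    n_estimators: int = 500
    pca_leakage_compat: bool = False
    seed: int = 0

    def subseeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        names = ["simulate", "cv_split", "forest", "estimate_split"]
        return {
            name: int(child.generate_state(1)[0] % 2**31)
            for name, child in zip(names, ss.spawn(len(names)))
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Summary of one pipeline run; identical inputs give identical manifests."""

    config_hash: str
    seeds: dict[str, int]
    package_version: str
    stage_counts: dict[str, int]
    winner_model_id: int
    earliest_significant_visit: dict[str, int | None]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage in order, writing all intermediate artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.subseeds()
    counts: dict[str, int] = {}

    def stage(name):
        t0 = time.perf_counter()

        def done(msg=""):
            log.info("stage %-12s %6.2fs %s", name, time.perf_counter() - t0, msg)

        return done

    # --- ingest or simulate -------------------------------------------------
    done = stage("cohort")
    try:
        if config.input_dir:
            cohort, scores = read_cohort_dir(config.input_dir)
            truth = None
        else:
            sim_cfg = dataclasses.replace(config.cohort, seed=seeds["simulate"])
            cohort, scores, truth = generate_cohort(sim_cfg)
        write_cohort(cohort, scores, truth, out / "cohort")
    except Exception as e:  # noqa: BLE001 - abort with stage context
        raise PipelineStageError("cohort", e) from e
    counts["participants_raw"] = len(cohort.metadata)
    counts["feature_rows_raw"] = len(cohort.features)
    done(f"{counts['participants_raw']} participants")

    # --- preprocess ---------------------------------------------------------
    done = stage("preprocess")
    try:
        pre, exclusion_log = preprocess(
            cohort,
            scores,
            max_consecutive_missing=config.max_consecutive_missing,
            impute_scores=config.impute_scores,
        )
    except Exception as e:
        raise PipelineStageError("preprocess", e) from e
    exclusion_log.to_csv(out / "exclusion_log.csv")
    counts["participants_retained"] = pre.values.index.get_level_values(
        "participant_id"
    ).nunique()
    counts["features"] = len(pre.feature_names)
    counts["rows"] = len(pre.values)
    done(f"{counts['participants_retained']} retained, {counts['features']} features")

    # --- progressing-feature screen -----------------------------------------
    done = stage("screen")
    try:
        report = find_progressing_features(pre, alpha=config.alpha)
    except Exception as e:
        raise PipelineStageError("screen", e) from e
    progressing = report.progressing
    # modeling needs at least two inputs; on a null cohort fall back to the
    # two lowest-p features so the comparison still runs
    model_pool = progressing if len(progressing) >= 2 else list(report.table.index[:2])
    counts["progressing_features"] = len(progressing)
    report.table.to_csv(out / "progressing_features.csv")
    done(f"{len(progressing)} progressing")

    # --- forward selection ---------------------------------------------------
    done = stage("select")
    try:
        rank = {f: i for i, f in enumerate(report.table.index)}
        fsel = forward_select(
            pre,
            candidates=model_pool,
            seed_feature=model_pool[0],  # lowest trend p-value (table is p-sorted)
            candidate_rank=rank,
            min_improvement=config.min_improvement,
            consensus_k=config.consensus_k,
        )
    except Exception as e:
        raise PipelineStageError("select", e) from e
    write_report(
        {
            "fold_features": {str(k): v for k, v in fsel.fold_features.items()},
            "fold_rmse_traces": {str(k): v for k, v in fsel.fold_rmse_traces.items()},
            "consensus_k": fsel.consensus_k,
            "consensus": fsel.consensus,
        },
        out / "forward_selection.json",
    )
    counts["consensus_features"] = len(fsel.consensus)
    done(f"consensus of {len(fsel.consensus)}")

    # --- model comparison ----------------------------------------------------
    done = stage("validate")
    try:
        specs = default_model_specs(
            progressing=model_pool,
            consensus=fsel.consensus,
            all_features=pre.feature_names,
            n_estimators=config.n_estimators,
            seed=seeds["forest"],
        )
        for s in specs:
            s.variance_threshold = (
                config.variance_threshold if s.input_kind == "pca_factors" else None
            )
        plan = make_cv_plan(
            pre, n_folds=config.n_folds, split_unit=config.split_unit,
            seed=seeds["cv_split"],
        )
        comparison = compare_models(
            pre, specs, plan, pca_leakage_compat=config.pca_leakage_compat
        )
    except Exception as e:
        raise PipelineStageError("validate", e) from e
    write_report(
        {
            "models": {
                str(mid): {
                    "label": row["label"],
                    "n_inputs": int(row["n_inputs"]),
                    "rmse_mean": float(row["rmse_mean"]),
                    "rmse_std": float(row["rmse_std"]),
                    "fold_rmses": comparison.fold_rmses[mid],
                }
                for mid, row in comparison.table.iterrows()
            },
            "winner_model_id": comparison.winner_id,
            "n_folds": plan.n_folds,
            "split_unit": plan.split_unit,
        },
        out / "model_comparison.json",
    )
    done(f"winner model {comparison.winner_id}")

    # --- progression reports --------------------------------------------------
    done = stage("progress")
    try:
        observed = ScoreSeries.from_long(
            pre.scores, "total_motor_score", "observed MDS-UPDRS-III"
        )
        gait = ScoreSeries.from_long(
            pre.scores, "gait_posture_aggregate", "gait & posture aggregate"
        )
        # estimated series: participant-level out-of-fold predictions of the
        # winning model, so every visit of a participant is scored by one
        # model that never saw that participant (keeps within-person
        # contrasts coherent and out-of-sample)
        winner_spec = next(s for s in specs if s.model_id == comparison.winner_id)
        est_plan = make_cv_plan(
            pre, n_folds=config.n_folds, split_unit="participant",
            seed=seeds["estimate_split"],
        )
        est_comp = compare_models(pre, [winner_spec], est_plan)
        estimated = ScoreSeries(
            matrix=est_comp.oof_predictions[comparison.winner_id].unstack("visit"),
            label=f"model-{comparison.winner_id} estimated score",
        )
        reports = {
            "observed": progression_report(observed, fdr=config.fdr),
            "gait_posture": progression_report(gait, fdr=config.fdr),
            "estimated": progression_report(estimated, fdr=config.fdr),
        }
    except Exception as e:
        raise PipelineStageError("progress", e) from e
    for name, rep in reports.items():
        write_report(rep.to_dict(), out / f"progression_{name}.json")
    write_report(
        compare_reports(reports["observed"], reports["estimated"]),
        out / "progression_contrast.json",
    )
    estimated.matrix.stack().rename("estimated_score").to_csv(
        out / "estimated_scores.csv"
    )
    done()

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seeds=seeds,
        package_version=__version__,
        stage_counts=counts,
        winner_model_id=comparison.winner_id,
        earliest_significant_visit={
            name: rep.earliest_significant_visit for name, rep in reports.items()
        },
    )
    write_report(manifest.to_dict(), out / "manifest.json")
    return manifest
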
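"""5-fold cross-validation harness and model comparison.

The default split follows the study design: all participant-visit rows are
pooled and split at random into five near-equal subsets, each serving once
as the validation set. Participant-level splitting (all visits of a
participant share a fold) is available and recommended when within-person
correlation must not leak across the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitprog.cohort import PreprocessedCohort
from gaitprog.models import FittedModel, ModelSpec, build_model


@dataclass
class CVPlan:
    """Fold assignment for every (participant, visit) row."""

    assignment: pd.Series  # row index -> fold id in 0..n_folds-1
    n_folds: int
    split_unit: str
    seed: int

    def folds(self):
        for k in range(self.n_folds):
            va = self.assignment == k
            yield k, self.assignment.index[~va], self.assignment.index[va]


def make_cv_plan(
    cohort: PreprocessedCohort,
    n_folds: int = 5,
    split_unit: str = "row",
    seed: int = 0,
) -> CVPlan:
    """Randomly partition rows (or participants) into near-equal folds.

    Fold sizes differ by at most one unit; with ``split_unit='participant'``
    every visit of a participant lands in the same fold.
    """
    if split_unit not in {"row", "participant"}:
        raise ValueError(f"unknown split unit {split_unit!r}")
    index = cohort.values.index
    rng = np.random.default_rng(seed)
    if split_unit == "row":
        units = np.arange(len(index))
        if len(units) < n_folds:
            raise ValueError(f"{len(units)} rows < {n_folds} folds")
        perm = rng.permutation(units)
        labels = np.empty(len(units), dtype=int)
        for k, chunk in enumerate(np.array_split(perm, n_folds)):
            labels[chunk] = k
        assignment = pd.Series(labels, index=index)
    else:
        participants = index.get_level_values("participant_id").unique().to_numpy()
        if len(participants) < n_folds:
            raise ValueError(f"{len(participants)} participants < {n_folds} folds")
        perm = rng.permutation(participants)
        fold_of = {}
        for k, chunk in enumerate(np.array_split(perm, n_folds)):
            for pid in chunk:
                fold_of[pid] = k
        assignment = pd.Series(
            [fold_of[p] for p in index.get_level_values("participant_id")], index=index
        )
    return CVPlan(assignment=assignment, n_folds=n_folds, split_unit=split_unit, seed=seed)


def rmse(estimates, targets) -> float:
    """Root mean square error between two equal-length, nonempty vectors."""
    a = np.asarray(estimates, dtype=float)
    b = np.asarray(targets, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("RMSE of empty vectors is undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ModelComparison:
    """Per-model cross-validated RMSE summary and the winning configuration.

    ``rmse_std`` is the sample standard deviation (ddof=1) over fold RMSEs.
    ``oof_predictions`` holds each model's out-of-fold estimate for every
    row — an honest, cross-validated score series.
    """

    table: pd.DataFrame  # index model_id; rmse_mean, rmse_std, label
    fold_rmses: dict[int, list[float]]
    oof_predictions: pd.DataFrame
    winner_id: int = field(init=False)

    def __post_init__(self) -> None:
        t = self.table.sort_values(
            ["rmse_mean", "rmse_std"], kind="mergesort"
        )  # stable: earlier model_id wins remaining ties
        self.winner_id = int(t.index[0])


def compare_models(
    cohort: PreprocessedCohort,
    specs: list[ModelSpec],
    plan: CVPlan,
    targets: pd.Series | None = None,
    pca_leakage_compat: bool = False,
) -> ModelComparison:
    """Train and score every configuration on every fold of the plan.

    Factor models for PCA-input configurations are fitted inside each
    training fold; ``pca_leakage_compat=True`` instead fits them once on all
    rows before splitting (mimicking a global factorisation).
    """
    values = cohort.values
    y = (targets if targets is not None else cohort.scores["total_motor_score"]).reindex(
        values.index
    )
    if y.isna().any():
        raise ValueError("targets missing for some rows")

    global_factors = {}
    if pca_leakage_compat:
        from gaitprog.selection import fit_pca

        for spec in specs:
            if spec.input_kind == "pca_factors":
                global_factors[spec.model_id] = fit_pca(
                    values, spec.features, spec.variance_threshold
                )

    fold_rmses: dict[int, list[float]] = {s.model_id: [] for s in specs}
    oof = pd.DataFrame(
        np.nan, index=values.index, columns=[s.model_id for s in specs]
    )
    for _, train_idx, val_idx in plan.folds():
        # leakage audit: fitting never sees validation rows
        assert len(train_idx.intersection(val_idx)) == 0
        X_tr, X_va = values.loc[train_idx], values.loc[val_idx]
        for spec in specs:
            fitted = build_model(
                spec, X_tr, y, factor_model=global_factors.get(spec.model_id)
            )
            pred = fitted.predict(X_va)
            fold_rmses[spec.model_id].append(rmse(pred, y.loc[val_idx]))
            oof.loc[val_idx, spec.model_id] = pred.to_numpy()
    table = pd.DataFrame(
        {
            "label": [s.label for s in specs],
            "n_inputs": [len(s.features) for s in specs],
            "rmse_mean": [float(np.mean(fold_rmses[s.model_id])) for s in specs],
            "rmse_std": [float(np.std(fold_rmses[s.model_id], ddof=1)) for s in specs],
        },
        index=pd.Index([s.model_id for s in specs], name="model_id"),
    )
    return ModelComparison(table=table, fold_rmses=fold_rmses, oof_predictions=oof)


def refit_winner(
    cohort: PreprocessedCohort,
    specs: list[ModelSpec],
    comparison: ModelComparison,
    targets: pd.Series | None = None,
) -> FittedModel:
    """Refit the winning configuration on the full dataset."""
    values = cohort.values
    y = (targets if targets is not None else cohort.scores["total_motor_score"]).reindex(
        values.index
    )
    spec = next(s for s in specs if s.model_id == comparison.winner_id)
    return build_model(spec, values, y)
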
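"""The seven clinical-score estimator configurations and univariate baselines.

Model inputs come from three routes (see :mod:`gaitprog.selection`):

1. linear regression on the two most significantly progressing features;
2. linear regression on the forward-selection consensus set;
3. random forest on all progressing features;
4. linear regression on PCA factors of the progressing set;
5. random forest on PCA factors of the progressing set;
6. linear regression on PCA factors of the full feature set;
7. random forest on PCA factors of the full feature set.

PCA factor models are fitted on the training rows only, inside each
cross-validation fold, unless leakage-compatible single-fit behaviour is
explicitly requested at the comparison level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from gaitprog.cohort import PreprocessedCohort
from gaitprog.selection import FactorModel, fit_pca

INPUT_KINDS = {"selected_features", "progressing_features", "pca_factors"}
ESTIMATOR_KINDS = {"linear", "random_forest"}


@dataclass
class ModelSpec:
    """One estimator configuration.

    ``features`` lists the direct input features, or — for ``pca_factors``
    input — the feature pool the factor model is fitted on.
    """

    model_id: int
    input_kind: str
    estimator_kind: str
    features: list[str]
    variance_threshold: float | None = None
    n_estimators: int = 500
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.input_kind not in INPUT_KINDS:
            raise ValueError(f"unknown input kind {self.input_kind!r}")
        if self.estimator_kind not in ESTIMATOR_KINDS:
            raise ValueError(f"unknown estimator kind {self.estimator_kind!r}")
        if self.input_kind == "pca_factors" and self.variance_threshold is None:
            self.variance_threshold = 0.90
        if not self.label:
            self.label = f"model {self.model_id}: {self.estimator_kind} on {self.input_kind}"


def default_model_specs(
    progressing: list[str],
    consensus: list[str],
    all_features: list[str],
    n_estimators: int = 500,
    seed: int = 0,
) -> list[ModelSpec]:
    """Build the seven standard configurations.

    ``progressing`` must be ordered by ascending trend p-value so that the
    first two entries seed model 1.
    """
    if len(progressing) < 2:
        raise ValueError("need at least two progressing features")
    return [
        ModelSpec(1, "selected_features", "linear", list(progressing[:2])),
        ModelSpec(2, "selected_features", "linear", list(consensus) or list(progressing[:2])),
        ModelSpec(3, "progressing_features", "random_forest", list(progressing),
                  n_estimators=n_estimators, seed=seed),
        ModelSpec(4, "pca_factors", "linear", list(progressing)),
        ModelSpec(5, "pca_factors", "random_forest", list(progressing),
                  n_estimators=n_estimators, seed=seed),
        ModelSpec(6, "pca_factors", "linear", list(all_features)),
        ModelSpec(7, "pca_factors", "random_forest", list(all_features),
                  n_estimators=n_estimators, seed=seed),
    ]


@dataclass
class FittedModel:
    """A trained configuration; ``predict`` is deterministic given this state."""

    spec: ModelSpec
    coef: np.ndarray | None = None          # linear: [intercept, betas...]
    forest: RandomForestRegressor | None = None
    factor_model: FactorModel | None = field(default=None, repr=False)
    training_rows: pd.Index | None = field(default=None, repr=False)

    @property
    def feature_importances(self) -> pd.Series:
        """Impurity-based importances of a fitted forest (sum to 1)."""
        if self.forest is None:
            raise ValueError("feature importances are defined for forests only")
        names = (
            [f"PC{i + 1}" for i in range(self.factor_model.n_components)]
            if self.factor_model is not None
            else self.spec.features
        )
        return pd.Series(self.forest.feature_importances_, index=names)

    def _design(self, rows: pd.DataFrame) -> np.ndarray:
        if self.factor_model is not None:
            return self.factor_model.transform(rows)
        missing = [f for f in self.spec.features if f not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing feature columns {missing}")
        return rows[self.spec.features].to_numpy(dtype=float)

    def predict(self, rows: pd.DataFrame) -> pd.Series:
        X = self._design(rows)
        if self.coef is not None:
            pred = np.column_stack([np.ones(len(X)), X]) @ self.coef
        else:
            pred = self.forest.predict(X)
        return pd.Series(pred, index=rows.index, name=f"model_{self.spec.model_id}")


def build_model(
    spec: ModelSpec,
    rows: pd.DataFrame,
    targets: pd.Series,
    factor_model: FactorModel | None = None,
) -> FittedModel:
    """Fit one configuration on training rows.

    For PCA input kinds the factor model is fitted on the training rows
    (pass ``factor_model`` to reuse a pre-fitted one, e.g. for
    leakage-compatible comparisons).
    """
    y = targets.reindex(rows.index)
    if y.isna().any():
        raise ValueError("targets missing for some training rows")
    fm = None
    if spec.input_kind == "pca_factors":
        fm = factor_model or fit_pca(rows, spec.features, spec.variance_threshold)
    model = FittedModel(spec=spec, factor_model=fm, training_rows=rows.index)
    X = model._design(rows)
    if spec.estimator_kind == "linear":
        A = np.column_stack([np.ones(len(X)), X])
        model.coef, *_ = np.linalg.lstsq(A, y.to_numpy(dtype=float), rcond=None)
    else:
        forest = RandomForestRegressor(
            n_estimators=spec.n_estimators,
            criterion="squared_error",
            random_state=spec.seed,
            n_jobs=1,
        )
        forest.fit(X, y.to_numpy(dtype=float))
        model.forest = forest
    return model


def univariate_baselines(
    cohort: PreprocessedCohort,
    features: list[str],
    plan,
    targets: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-validated RMSE of a one-feature linear regression, per feature.

    Uses the same fold plan as the model comparison; returns a table sorted
    ascending by mean RMSE.
    """
    from gaitprog.validation import rmse  # local import to avoid a cycle

    values = cohort.values
    y = (targets if targets is not None else cohort.scores["total_motor_score"]).reindex(
        values.index
    )
    rows = []
    for feat in features:
        fold_rmses = []
        for fold in range(plan.n_folds):
            tr = plan.assignment != fold
            va = ~tr
            spec = ModelSpec(0, "selected_features", "linear", [feat], label=feat)
            fitted = build_model(spec, values.loc[tr.to_numpy()], y[tr.to_numpy()])
            pred = fitted.predict(values.loc[va.to_numpy()])
            fold_rmses.append(rmse(pred.to_numpy(), y[va.to_numpy()].to_numpy()))
        rows.append((feat, float(np.mean(fold_rmses)), float(np.std(fold_rmses, ddof=1))))
    table = pd.DataFrame(rows, columns=["feature", "rmse_mean", "rmse_std"])
    return table.sort_values(["rmse_mean", "feature"], kind="mergesort").reset_index(drop=True)
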
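"""Dimensionality reduction: trend screening, greedy forward selection, PCA.

Three routes from the 122-feature space to a model input space:

* a progressing-feature screen — ordinary least squares of the visit-wise
  group mean of each feature on visit index, keeping features whose slope is
  significant at ``alpha``;
* greedy forward selection with early stopping, validated leave-one-visit-out
  and aggregated to a consensus set;
* PCA retaining the minimal number of components explaining a target share
  of variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from gaitprog.cohort import PreprocessedCohort


# ---------------------------------------------------------------------------
# progressing-feature screen
# ---------------------------------------------------------------------------

@dataclass
class ProgressingFeatureReport:
    """Per-feature trend slope and p-value, sorted ascending by p-value."""

    table: pd.DataFrame  # index feature; columns slope, p_value, passes_filter
    alpha: float

    @property
    def progressing(self) -> list[str]:
        return list(self.table.index[self.table["passes_filter"]])

    @property
    def seed_feature(self) -> str:
        """Feature with the most significant trend (forward-selection seed)."""
        return self.table.index[0]


def trend_test(means: np.ndarray, visits: np.ndarray) -> tuple[float, float]:
    """OLS slope of visit-wise means on visit index with its two-sided p-value.

    Degenerate fits use the convention: zero residual with zero slope -> p=1
    (a constant feature carries no trend); zero residual with nonzero slope
    -> p=0 (an exactly linear trend).
    """
    v = np.asarray(visits, dtype=float)
    y = np.asarray(means, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("trend test needs at least 3 visits")
    vc = v - v.mean()
    sxx = (vc**2).sum()
    slope = (vc * (y - y.mean())).sum() / sxx
    resid = y - y.mean() - slope * vc
    sse = float((resid**2).sum())
    if sse <= 0 or np.isclose(sse, 0.0, atol=1e-300):
        return slope, (1.0 if slope == 0 else 0.0)
    se = np.sqrt(sse / (n - 2) / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(slope), float(p)


def find_progressing_features(
    cohort: PreprocessedCohort | pd.DataFrame, alpha: float = 0.05
) -> ProgressingFeatureReport:
    """Screen features whose visit-wise group mean trends linearly with visit.

    For each feature the values are averaged across participants at each
    visit, an OLS line is fitted to the (visit, mean) points, and the feature
    passes when the two-sided slope p-value is below ``alpha``. Computed in
    closed form simultaneously for all features.
    """
    values = cohort.values if isinstance(cohort, PreprocessedCohort) else cohort
    means = values.groupby(level="visit").mean()  # visits x features
    visits = means.index.to_numpy(dtype=float)
    n = len(visits)
    if n < 3:
        raise ValueError("progressing-feature screen needs at least 3 visits")
    y = means.to_numpy()  # (V, F)
    vc = visits - visits.mean()
    sxx = (vc**2).sum()
    slope = vc @ (y - y.mean(axis=0)) / sxx
    resid = y - y.mean(axis=0) - np.outer(vc, slope)
    sse = (resid**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    degenerate = sse <= 1e-300
    p = np.where(degenerate, np.where(slope == 0, 1.0, 0.0), p)
    table = pd.DataFrame(
        {"slope": slope, "p_value": p, "passes_filter": p < alpha},
        index=means.columns.rename("feature"),
    )
    table = table.sort_values(["p_value", "feature"], kind="mergesort")
    return ProgressingFeatureReport(table=table, alpha=alpha)


# ---------------------------------------------------------------------------
# greedy forward selection, leave-one-visit-out
# ---------------------------------------------------------------------------

def _ols_val_rmse(
    X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray, y_val: np.ndarray
) -> float:
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    pred = np.column_stack([np.ones(len(X_val)), X_val]) @ coef
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


@dataclass
class ForwardSelectionResult:
    """Per-fold greedy selection paths and the consensus feature set."""

    fold_features: dict[int, list[str]]  # held-out visit -> accepted features, in order
    fold_rmse_traces: dict[int, list[float]]
    consensus_k: int
    consensus: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.consensus = self.consensus_at(self.consensus_k)

    def consensus_at(self, k: int) -> list[str]:
        """Features accepted in at least k of the leave-one-visit-out folds."""
        counts: dict[str, int] = {}
        for feats in self.fold_features.values():
            for f in feats:
                counts[f] = counts.get(f, 0) + 1
        return sorted(f for f, c in counts.items() if c >= k)


def forward_select(
    cohort: PreprocessedCohort,
    candidates: list[str],
    seed_feature: str,
    targets: pd.Series | None = None,
    candidate_rank: dict[str, int] | None = None,
    min_improvement: float = 0.0,
    consensus_k: int = 5,
) -> ForwardSelectionResult:
    """Greedy forward selection with early stopping, validated per held-out visit.

    For each visit v, the estimator (OLS with intercept) is trained on the
    rows of the other visits and scored on visit v. Starting from the seed
    feature, each step adds the candidate whose inclusion reduces the
    validation RMSE the most; selection stops when no candidate improves RMSE
    by more than ``min_improvement``. The consensus set collects features
    accepted in at least ``consensus_k`` folds. Ties in the greedy argmin are
    broken by the candidate's trend-p-value rank (``candidate_rank``), then
    by name.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    if seed_feature not in candidates:
        raise ValueError(f"seed feature {seed_feature!r} not among candidates")
    values = cohort.values
    y = (targets if targets is not None else cohort.scores["total_motor_score"]).reindex(
        values.index
    )
    if y.isna().any():
        raise ValueError("targets missing for some cohort rows")
    rank = candidate_rank or {f: i for i, f in enumerate(candidates)}
    visits = sorted(values.index.get_level_values("visit").unique())
    X = values[candidates].to_numpy()
    col = {f: i for i, f in enumerate(candidates)}
    yv = y.to_numpy(dtype=float)
    visit_of_row = values.index.get_level_values("visit").to_numpy()

    fold_features: dict[int, list[str]] = {}
    fold_traces: dict[int, list[float]] = {}
    for held_out in visits:
        val = visit_of_row == held_out
        tr = ~val
        selected = [seed_feature]
        idx = [col[seed_feature]]
        cur = _ols_val_rmse(X[tr][:, idx], yv[tr], X[val][:, idx], yv[val])
        trace = [cur]
        remaining = [f for f in candidates if f != seed_feature]
        while remaining:
            scores = []
            for f in remaining:
                cols = idx + [col[f]]
                r = _ols_val_rmse(X[tr][:, cols], yv[tr], X[val][:, cols], yv[val])
                scores.append((r, rank.get(f, len(rank)), f))
            best_rmse, _, best_feat = min(scores)
            # the epsilon guards against accepting pure float jitter when the
            # current fit is already (numerically) exact
            if cur - best_rmse <= min_improvement + 1e-12 * max(1.0, cur):
                break
            selected.append(best_feat)
            idx.append(col[best_feat])
            remaining.remove(best_feat)
            cur = best_rmse
            trace.append(cur)
        fold_features[int(held_out)] = selected
        fold_traces[int(held_out)] = trace
    return ForwardSelectionResult(
        fold_features=fold_features, fold_rmse_traces=fold_traces, consensus_k=consensus_k
    )


# ---------------------------------------------------------------------------
# PCA factorisation
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Z-scored PCA keeping the minimal components reaching a variance target.

    Features are standardised with training-set mean and SD before the
    decomposition (the feature set mixes units); components are ordered by
    explained variance and ``n_components`` is the smallest k whose
    cumulative explained-variance ratio reaches ``variance_threshold``.
    """

    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (k, n_features) retained loadings
    explained_variance_ratio: np.ndarray  # full spectrum
    n_components: int
    variance_threshold: float

    def transform(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in rows.columns]
        if missing:
            raise ValueError(f"rows are missing features {missing}")
        Z = (rows[self.feature_names].to_numpy() - self.center) / self.scale
        return Z @ self.components.T


def fit_pca(
    cohort: PreprocessedCohort | pd.DataFrame,
    feature_set: list[str] | None = None,
    variance_threshold: float = 0.90,
) -> FactorModel:
    """Fit the standardised PCA factor model on the given feature subset."""
    values = cohort.values if isinstance(cohort, PreprocessedCohort) else cohort
    feats = list(feature_set) if feature_set is not None else list(values.columns)
    X = values[feats].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.all(scale == 0):
        raise ValueError("zero-variance matrix: PCA undefined")
    scale = np.where(scale == 0, 1.0, scale)
    Z = (X - center) / scale
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    return FactorModel(
        feature_names=feats,
        center=center,
        scale=scale,
        components=pca.components_[:k],
        explained_variance_ratio=ratios,
        n_components=k,
        variance_threshold=variance_threshold,
    )
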
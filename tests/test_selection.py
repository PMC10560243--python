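"""Trend screen, forward selection and PCA factorisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitprog.cohort import PreprocessedCohort
from gaitprog.preprocess import preprocess
from gaitprog.selection import (
    find_progressing_features,
    fit_pca,
    forward_select,
    trend_test,
)
from gaitprog.simulate import CohortConfig, generate_cohort


def make_pre(values: pd.DataFrame, scores: pd.Series | None = None) -> PreprocessedCohort:
    score_df = pd.DataFrame(index=values.index)
    if scores is not None:
        score_df["total_motor_score"] = scores
    return PreprocessedCohort(
        values=values,
        imputed=values.astype(bool) & False,
        scores=score_df,
        metadata=pd.DataFrame(
            index=values.index.get_level_values("participant_id").unique()
        ),
        n_visits=int(values.index.get_level_values("visit").max()),
    )


def grid(n_participants, n_visits):
    return pd.MultiIndex.from_product(
        [[f"p{i}" for i in range(n_participants)], range(1, n_visits + 1)],
        names=["participant_id", "visit"],
    )


class TestTrendScreen:
    def test_constant_feature_has_p_one(self):
        idx = grid(5, 7)
        values = pd.DataFrame({"flat": 3.0}, index=idx)
        rep = find_progressing_features(make_pre(values))
        assert rep.table.loc["flat", "p_value"] == 1.0
        assert not rep.table.loc["flat", "passes_filter"]

    def test_exact_linear_feature_has_p_zero(self):
        idx = grid(5, 7)
        values = pd.DataFrame(
            {"ramp": idx.get_level_values("visit").astype(float)}, index=idx
        )
        rep = find_progressing_features(make_pre(values))
        assert rep.table.loc["ramp", "p_value"] == 0.0
        assert rep.table.loc["ramp", "passes_filter"]

    def test_matches_scipy_linregress_per_feature(self):
        rng = np.random.default_rng(3)
        idx = grid(12, 7)
        values = pd.DataFrame(
            rng.normal(size=(len(idx), 6)), index=idx,
            columns=[f"f{i}" for i in range(6)],
        )
        values["f0"] += 0.5 * idx.get_level_values("visit")
        rep = find_progressing_features(make_pre(values))
        means = values.groupby(level="visit").mean()
        for col in values.columns:
            lr = stats.linregress(means.index.to_numpy(dtype=float), means[col])
            assert rep.table.loc[col, "slope"] == pytest.approx(lr.slope, rel=1e-9)
            assert rep.table.loc[col, "p_value"] == pytest.approx(lr.pvalue, rel=1e-9)

    def test_noise_free_recovers_planted_set_exactly(self):
        cfg = CohortConfig.noise_free(
            n_participants=20, n_features=24, n_progressing=8, seed=6
        )
        cohort, scores, truth = generate_cohort(cfg)
        pre, _ = preprocess(cohort, scores)
        rep = find_progressing_features(pre)
        assert set(rep.progressing) == set(truth.progressing_features)

    def test_invariant_to_affine_feature_rescaling(self, small_preprocessed):
        pre, _ = small_preprocessed
        rep1 = find_progressing_features(pre)
        rescaled = pre.values * 3.7 - 11.0
        rep2 = find_progressing_features(make_pre(rescaled))
        np.testing.assert_allclose(
            rep1.table["p_value"].sort_index(),
            rep2.table["p_value"].sort_index(),
            rtol=1e-8,
        )

    def test_invariant_to_participant_relabeling(self, small_preprocessed):
        pre, _ = small_preprocessed
        rep1 = find_progressing_features(pre)
        renamed = pre.values.rename(
            index=lambda p: f"X{p}", level="participant_id"
        )
        rep2 = find_progressing_features(make_pre(renamed))
        pd.testing.assert_frame_equal(rep1.table, rep2.table)

    def test_fewer_than_three_visits_error(self):
        idx = grid(5, 2)
        with pytest.raises(ValueError, match="3 visits"):
            find_progressing_features(make_pre(pd.DataFrame({"f": 1.0}, index=idx)))

    def test_trend_test_hand_example(self):
        # means (1,2,3,4,5,6,8) on visits 1..7: positive slope, small p
        slope, p = trend_test(np.array([1, 2, 3, 4, 5, 6, 8.0]), np.arange(1, 8.0))
        lr = stats.linregress(np.arange(1, 8.0), [1, 2, 3, 4, 5, 6, 8.0])
        assert slope == pytest.approx(lr.slope)
        assert p == pytest.approx(lr.pvalue)


def brute_force_greedy(values, y, candidates, seed_feature, visits_held_out):
    """Independent re-implementation of one fold's greedy path (statsmodels OLS)."""
    import statsmodels.api as sm

    visit = values.index.get_level_values("visit").to_numpy()
    tr, va = visit != visits_held_out, visit == visits_held_out
    selected = [seed_feature]

    def val_rmse(feats):
        X_tr = sm.add_constant(values.loc[tr, feats].to_numpy(), has_constant="add")
        model = sm.OLS(y.to_numpy()[tr], X_tr).fit()
        X_va = sm.add_constant(values.loc[va, feats].to_numpy(), has_constant="add")
        resid = model.predict(X_va) - y.to_numpy()[va]
        return float(np.sqrt(np.mean(resid**2)))

    cur = val_rmse(selected)
    remaining = [c for c in candidates if c != seed_feature]
    while remaining:
        scores = sorted((val_rmse(selected + [c]), c) for c in remaining)
        best_rmse, best = scores[0]
        if cur - best_rmse <= 1e-12 * max(1.0, cur):
            break
        selected.append(best)
        remaining.remove(best)
        cur = best_rmse
    return selected


class TestForwardSelection:
    def test_perfect_predictor_selected_alone(self):
        idx = grid(8, 7)
        rng = np.random.default_rng(0)
        target = pd.Series(rng.normal(10, 3, len(idx)), index=idx)
        values = pd.DataFrame(
            {"exact": target, "noise": rng.normal(size=len(idx))}, index=idx
        )
        res = forward_select(
            make_pre(values, target), ["exact", "noise"], "exact"
        )
        for v, feats in res.fold_features.items():
            assert feats == ["exact"]
            assert res.fold_rmse_traces[v][-1] == pytest.approx(0.0, abs=1e-9)

    def test_greedy_path_matches_bruteforce_oracle(self):
        """Each fold's path equals an independent exhaustive per-step search."""
        cfg = CohortConfig(
            n_participants=16, n_features=16, n_progressing=8,
            n_collinear_blocks=4, seed=13,
        )
        cohort, scores, truth = generate_cohort(cfg)
        pre, _ = preprocess(cohort, scores)
        rep = find_progressing_features(pre)
        candidates = list(rep.table.index[:8])
        seed_feature = candidates[0]
        res = forward_select(pre, candidates, seed_feature)
        y = pre.scores["total_motor_score"]
        for v in res.fold_features:
            oracle = brute_force_greedy(pre.values, y, candidates, seed_feature, v)
            assert res.fold_features[v] == oracle

    def test_rmse_traces_strictly_decreasing(self, small_preprocessed):
        pre, _ = small_preprocessed
        rep = find_progressing_features(pre)
        pool = rep.progressing if len(rep.progressing) >= 2 else list(rep.table.index[:4])
        res = forward_select(pre, pool, pool[0])
        for trace in res.fold_rmse_traces.values():
            assert all(b < a for a, b in zip(trace, trace[1:]))
        for feats in res.fold_features.values():
            assert feats[0] == pool[0]

    def test_consensus_monotone_in_k(self, small_preprocessed):
        pre, _ = small_preprocessed
        rep = find_progressing_features(pre)
        pool = rep.progressing if len(rep.progressing) >= 2 else list(rep.table.index[:4])
        res = forward_select(pre, pool, pool[0])
        k7, k5, k1 = (set(res.consensus_at(k)) for k in (7, 5, 1))
        assert k7 <= k5 <= k1

    def test_empty_candidates_and_bad_seed_errors(self, small_preprocessed):
        pre, _ = small_preprocessed
        with pytest.raises(ValueError, match="empty"):
            forward_select(pre, [], "x")
        with pytest.raises(ValueError, match="seed feature"):
            forward_select(pre, list(pre.values.columns[:3]), "not_there")


class TestPCA:
    def test_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        X = pd.DataFrame(
            np.outer(t, [1.0, -2.0, 0.5]),
            index=grid(100, 2), columns=["a", "b", "c"],
        )
        fm = fit_pca(make_pre(X), variance_threshold=0.9)
        assert fm.n_components == 1

    def test_isotropic_gaussian_retains_nine_of_ten(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            rng.normal(size=(4000, 10)),
            index=grid(2000, 2), columns=[f"g{i}" for i in range(10)],
        )
        fm = fit_pca(make_pre(X), variance_threshold=0.90)
        assert fm.n_components == 9

    def test_reconstruction_error_matches_discarded_variance(self):
        """Truncated PCA residual equals (1 - cumulative ratio) of total variance."""
        rng = np.random.default_rng(4)
        base = rng.normal(size=(300, 3)) @ rng.normal(size=(3, 8))
        X = pd.DataFrame(
            base + 0.3 * rng.normal(size=(300, 8)),
            index=grid(150, 2), columns=[f"f{i}" for i in range(8)],
        )
        fm = fit_pca(make_pre(X), variance_threshold=0.90)
        Z = (X.to_numpy() - fm.center) / fm.scale
        scores_ = fm.transform(X)
        recon = scores_ @ fm.components
        resid_var = np.sum((Z - recon) ** 2) / len(Z)
        total_var = np.sum(Z**2) / len(Z)
        discarded = 1.0 - fm.explained_variance_ratio[: fm.n_components].sum()
        assert resid_var / total_var == pytest.approx(discarded, rel=1e-6)

    def test_zero_variance_matrix_error(self):
        X = pd.DataFrame(5.0, index=grid(10, 2), columns=["a", "b"])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pca(make_pre(X))

    def test_collinearity_reduces_retained_components(self):
        """Stronger block correlation needs fewer components for 90%."""
        counts = {}
        for rho in (0.0, 0.8):
            cfg = CohortConfig(
                n_participants=40, n_features=30, n_progressing=0,
                within_block_correlation=rho, n_collinear_blocks=5, seed=8,
                missing_visit_rate=0.0, artifact_rate=0.0,
            )
            cohort, scores, _ = generate_cohort(cfg)
            pre, _ = preprocess(cohort, scores)
            counts[rho] = fit_pca(pre).n_components
        assert counts[0.8] < counts[0.0]
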